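import numpy as np
import pytest

from clockspace import parse_newick
from clockspace.simulation import sim_birth_death_tree


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar5():
    # ultrametric rooted caterpillar on A..E
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


@pytest.fixture
def species12():
    return sim_birth_death_tree(n_tips=12, age=50.0, birth=0.5, death=0.1, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
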