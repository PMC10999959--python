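"""Simulation engine: birth-death species trees, multispecies-coalescent
gene trees, and white-noise clocks with locus clusters and accelerated
branches.

A simulated dataset is built in four layers:

1. a rooted ultrametric species tree from a constant-rate birth-death
   process conditioned on the number of surviving tips, rescaled to a fixed
   root age;
2. per-locus gene time-trees embedded in the species tree under the
   multispecies coalescent (one haploid sample per species, constant
   population-size parameter theta, pairwise coalescence rate 2/theta per
   time unit), simulated with msprime;
3. locus clusters: loci are assigned to k groups, each sharing one
   branch-multiplier vector (lognormal, median 1) — groups of loci with a
   common pattern of among-lineage rate variation;
4. a white-noise clock: each gene branch draws an independent gamma rate
   with mean = mean_rate x (multiplier of the species branch containing
   the gene branch's midpoint) and standard deviation rate_sd, converting
   time durations into substitutions-per-site lengths.  A chosen fraction
   of species branches is "accelerated" by a constant factor, composed
   multiplicatively with the cluster multipliers.

Everything downstream of a :class:`Scenario`'s seed is deterministic.
"""

from __future__ import annotations

import itertools
import random
import zlib
from dataclasses import dataclass, field, replace

import dendropy
import msprime
import numpy as np
from dendropy.model import birthdeath

from .clock_space import group_clocks, pca_clock_space, prepare_matrix
from .pacemaker_tests import run_pacemaker_tests
from .rate_collection import collect_clocks
from .trees_io import leafset_map, node_ages, tip_labels

__all__ = [
    "Scenario",
    "SimulatedDataset",
    "AccuracyReport",
    "DEFAULT_GRIDS",
    "sim_birth_death_tree",
    "sim_gene_trees_msc",
    "apply_clock",
    "assign_clusters",
    "accelerate_branches",
    "expand_design",
    "simulate_dataset",
    "run_scenario_and_score",
]

# factor levels of the factorial study design
DEFAULT_GRIDS = {
    "theta": (0.02, 0.5, 1.0),
    "mean_rate": (0.01, 0.05, 0.1),
    "rate_sd": (0.005, 0.05, 0.5),
    "n_loci": (100, 500, 1000),
    "k_clusters": (1, 3, 5),
    "accel_fraction": (0.0, 0.02, 0.10),
}


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial design (plus a replicate index)."""

    theta: float
    mean_rate: float
    rate_sd: float
    n_loci: int
    k_clusters: int
    accel_fraction: float
    accel_factor: float = 5.0
    replicate: int = 0
    seed: int = 0


def derive_seed(*parts) -> int:
    """Stable 31-bit seed from a tuple of scenario coordinates."""
    text = "|".join(repr(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def expand_design(grids=None, replicates=10, base_seed=0) -> list:
    """Full Cartesian product of factor levels x replicate indices, each
    scenario with a deterministic derived seed."""
    grids = dict(DEFAULT_GRIDS if grids is None else grids)
    names = list(grids)
    out = []
    for combo in itertools.product(*(grids[n] for n in names)):
        kw = dict(zip(names, combo))
        for rep in range(replicates):
            seed = derive_seed(base_seed, rep, *combo)
            out.append(Scenario(replicate=rep, seed=seed, **kw))
    return out


# ---------------------------------------------------------------------------
# species tree

def sim_birth_death_tree(n_tips=50, age=50.0, birth=0.5, death=0.1, seed=0):
    """Constant-rate birth-death tree conditioned on ``n_tips`` survivors
    (extinct lineages pruned), with node times rescaled so the root age is
    exactly ``age``."""
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    if not age > 0:
        raise ValueError("need age > 0")
    attempt = 0
    while True:
        rng = random.Random(derive_seed("bd", seed, attempt))
        try:
            # GSA sampling: grow beyond the target and sample a moment when
            # exactly n_tips lineages existed -> strictly positive pendants
            tree = birthdeath.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                gsa_ntax=2 * n_tips,
                rng=rng,
            )
            break
        except (birthdeath.TreeSimTotalExtinctionException, TypeError):
            # TypeError: rare dendropy GSA edge case (pruning at the
            # implicit root); treat like total extinction and redraw
            attempt += 1
    # relabel tips deterministically and rescale to the target root age
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    factor = age / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# gene trees under the multispecies coalescent

def sim_gene_trees_msc(species_tree, theta, n_loci, seed=0) -> list:
    """Gene time-trees embedded in the species tree under the MSC.

    One haploid lineage is sampled per species; within every species-tree
    branch, j lineages coalesce at rate C(j,2) * 2/theta per time unit
    (implemented via msprime with haploid population size theta/2).  The
    returned trees are ultrametric time-trees in species-tree time units.
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    node_ages(species_tree)  # raises if not ultrametric
    nwk = species_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=True,
        real_value_format_specifier=".12g",
    ).strip()
    demography = msprime.Demography.from_species_tree(
        nwk, initial_size=theta / 2.0
    )
    leaf_names = sorted(tip_labels(species_tree))
    samples = {name: 1 for name in leaf_names}
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        num_replicates=n_loci,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    pop_name = {p.id: p.name for p in demography.populations}
    taxon_namespace = species_tree.taxon_namespace
    taxa = {t.label: t for t in taxon_namespace}
    out = []
    for ts in replicates:
        tskit_tree = ts.first()
        root = tskit_tree.root
        tree = dendropy.Tree(taxon_namespace=taxon_namespace)

        def build(u, node):
            for v in tskit_tree.children(u):
                child = dendropy.Node()
                child.edge.length = ts.node(u).time - ts.node(v).time
                node.add_child(child)
                build(v, child)
            if tskit_tree.is_leaf(u):
                node.taxon = taxa[pop_name[ts.node(u).population]]

        build(root, tree.seed_node)
        out.append(tree)
    return out


# ---------------------------------------------------------------------------
# clocks, clusters, accelerations

def _species_index(species_tree):
    """Precomputed lookup for midpoint containment: per-node clade sets,
    ages, and parents."""
    ages = node_ages(species_tree)
    below = leafset_map(species_tree)
    leaf_node = {
        lf.taxon.label: lf for lf in species_tree.leaf_node_iter()
    }
    return ages, below, leaf_node


def _containing_branch(clade, midpoint, ages, below, leaf_node, root):
    """Species-tree branch (keyed by its rooted descendant clade) whose
    time interval contains ``midpoint`` on the lineage ancestral to
    ``clade``; None above the species root."""
    node = leaf_node[min(clade)]
    while node is not root:
        parent = node.parent_node
        if clade <= below[node] and ages[parent] > midpoint:
            return below[node]
        node = parent
    return None


def apply_clock(
    gene_time_tree,
    species_tree,
    mean_rate,
    rate_sd=0.0,
    branch_multipliers=None,
    seed=0,
):
    """Convert a gene time-tree into a phylogram under a white-noise clock.

    Each gene branch draws an i.i.d. gamma rate with mean
    ``mean_rate x multiplier`` and standard deviation ``rate_sd``, where the
    multiplier belongs to the species branch containing the gene branch's
    midpoint (1 above the species root); ``rate_sd = 0`` degenerates to a
    strict clock.  Branch length = rate x time duration.
    """
    if not mean_rate > 0:
        raise ValueError("mean_rate must be > 0")
    if rate_sd < 0:
        raise ValueError("rate_sd must be >= 0")
    multipliers = branch_multipliers or {}
    ages_s, below_s, leaf_s = _species_index(species_tree)
    root_s = species_tree.seed_node
    rng = np.random.default_rng(seed)
    tree = gene_time_tree.clone(depth=1)
    ages_g = node_ages(tree)
    below_g = leafset_map(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t_child = ages_g[node]
        t_parent = ages_g[node.parent_node]
        midpoint = 0.5 * (t_child + t_parent)
        key = _containing_branch(
            below_g[node], midpoint, ages_s, below_s, leaf_s, root_s
        )
        mult = multipliers.get(key, 1.0) if key is not None else 1.0
        mu = mean_rate * mult
        if rate_sd == 0:
            rate = mu
        else:
            shape = (mu / rate_sd) ** 2
            scale = rate_sd**2 / mu
            rate = rng.gamma(shape, scale)
        node.edge.length = rate * (t_parent - t_child)
    return tree


def species_branch_keys(species_tree) -> list:
    """Rooted species-tree branches as descendant-clade frozensets, in a
    deterministic (sorted) order.  Excludes the root edge."""
    below = leafset_map(species_tree)
    keys = [
        below[n]
        for n in species_tree.preorder_node_iter()
        if n is not species_tree.seed_node
    ]
    return sorted(keys, key=lambda c: (len(c), sorted(c)))


def assign_clusters(n_loci, k, species_tree, rate_sd_between=1.0, seed=0):
    """Assign loci to k near-equal blocks and draw one branch-multiplier
    vector per cluster (i.i.d. lognormal per species branch, median 1,
    log-scale sd ``rate_sd_between``); k = 1 gives all-ones multipliers."""
    if k < 1 or n_loci < k:
        raise ValueError("need 1 <= k <= n_loci")
    base, rem = divmod(n_loci, k)
    labels = np.concatenate(
        [np.full(base + (1 if c < rem else 0), c, dtype=int) for c in range(k)]
    )
    keys = species_branch_keys(species_tree)
    rng = np.random.default_rng(seed)
    if k == 1:
        vectors = [{key: 1.0 for key in keys}]
    else:
        vectors = [
            {
                key: float(m)
                for key, m in zip(
                    keys, np.exp(rng.normal(0.0, rate_sd_between, len(keys)))
                )
            }
            for _ in range(k)
        ]
    return labels, vectors


def accelerate_branches(species_tree, fraction, factor=5.0, seed=0):
    """Sample round(fraction x branch count) species branches uniformly
    without replacement and mark them for a ``factor``-fold acceleration.

    Returns ``(multipliers, flags)`` — a branch->factor map and the set of
    flagged branch keys (rooted descendant clades).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if not factor > 0:
        raise ValueError("factor must be > 0")
    keys = species_branch_keys(species_tree)
    n_flag = round(fraction * len(keys))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(keys), size=n_flag, replace=False)
    flags = {keys[i] for i in chosen}
    return {key: factor for key in flags}, flags


# ---------------------------------------------------------------------------
# full datasets and scoring

@dataclass
class SimulatedDataset:
    """A species tree, its gene-tree phylograms, and the ground truth."""

    scenario: Scenario
    species_tree: dendropy.Tree
    gene_trees: list
    accel_flags: set  # species branch keys simulated as accelerated
    cluster_labels: np.ndarray
    cluster_multipliers: list  # one branch->multiplier dict per cluster


def simulate_dataset(
    scenario: Scenario,
    n_tips=50,
    age=50.0,
    birth=0.5,
    death=0.1,
    rate_sd_between=1.0,
) -> SimulatedDataset:
    """Generate one full dataset for a scenario; deterministic in its seed."""
    s = scenario
    species = sim_birth_death_tree(
        n_tips=n_tips, age=age, birth=birth, death=death,
        seed=derive_seed("species", s.seed),
    )
    gene_time_trees = sim_gene_trees_msc(
        species, s.theta, s.n_loci, seed=derive_seed("msc", s.seed)
    )
    labels, vectors = assign_clusters(
        s.n_loci, s.k_clusters, species,
        rate_sd_between=rate_sd_between, seed=derive_seed("clusters", s.seed),
    )
    accel, flags = accelerate_branches(
        species, s.accel_fraction, s.accel_factor,
        seed=derive_seed("accel", s.seed),
    )
    gene_trees = []
    for i, gt in enumerate(gene_time_trees):
        mult = dict(vectors[labels[i]])
        for key, f in accel.items():
            mult[key] = mult.get(key, 1.0) * f
        gene_trees.append(
            apply_clock(
                gt, species, s.mean_rate, s.rate_sd,
                branch_multipliers=mult,
                seed=derive_seed("clock", s.seed, i),
            )
        )
    return SimulatedDataset(
        scenario=s,
        species_tree=species,
        gene_trees=gene_trees,
        accel_flags=flags,
        cluster_labels=labels,
        cluster_multipliers=vectors,
    )


@dataclass
class AccuracyReport:
    """Per-scenario scoring of the full analysis pipeline."""

    scenario: Scenario
    pPhi: float
    pPsi: float
    reject_degenerate: bool
    n_significant_pcs: int
    k_true: int
    k_hat: int | None
    sensitivity: float | None  # None when no branch was accelerated
    specificity: float
    n_true_branches: int
    missing_fraction: float
    failed: str | None = None
    # ROC-style: fraction of truth branches ranked (by min pIL across
    # significant PCs) above the cutoff that keeps specificity at 0.95
    sensitivity_at_spec: float | None = None


def run_scenario_and_score(
    scenario: Scenario,
    alpha=0.05,
    n_perm=100,
    k_max=8,
    do_clustering=True,
    dataset: SimulatedDataset = None,
    **sim_kwargs,
) -> AccuracyReport:
    """Generate (or take) a dataset, run the whole pipeline, and score it.

    A truth-flagged branch counts as recovered when its minimum loading
    p-value across significant PCs is below ``alpha``.
    """
    s = scenario
    try:
        if dataset is None:
            dataset = simulate_dataset(s, **sim_kwargs)
        matrix = collect_clocks(
            dataset.species_tree, dataset.gene_trees, mode="rates"
        )
        missing = float(matrix.values.isna().to_numpy().mean())
        prepared = prepare_matrix(matrix, log_transform=True)
        result = run_pacemaker_tests(
            prepared, n_perm=n_perm, seed=derive_seed("perm", s.seed)
        )
        space = pca_clock_space(prepared)
        k_hat = None
        if do_clustering:
            k_hat = group_clocks(
                space.scores.iloc[:, :2], k_max=k_max, B=50,
                seed=derive_seed("gap", s.seed),
            ).k_selected
        # map rooted truth branches onto retained matrix columns
        clade_to_col = {}
        for bid, key in matrix.branches.items():
            for clade in key.clades:
                clade_to_col[clade] = bid
        retained = set(prepared.branch_ids)
        true_cols = {
            clade_to_col[c]
            for c in dataset.accel_flags
            if clade_to_col.get(c) in retained
        }
        sig_pcs = list(result.pPCs.index[result.pPCs < alpha])
        if sig_pcs:
            called = set(
                result.pIL.index[(result.pIL[sig_pcs] < alpha).any(axis=1)]
            )
        else:
            called = set()
        negatives = retained - true_cols
        sensitivity = (
            len(called & true_cols) / len(true_cols) if true_cols else None
        )
        specificity = (
            len(negatives - called) / len(negatives) if negatives else 1.0
        )
        sens_at_spec = None
        if true_cols:
            # rank branches by loading p-value (ties: larger |loading|
            # first) and take hits before the 5% false-positive budget
            rank_pcs = sig_pcs or ["PC1"]
            pmin = result.pIL[rank_pcs].min(axis=1)
            strength = space.loadings[rank_pcs].abs().max(axis=1)
            order = sorted(
                pmin.index, key=lambda b: (pmin[b], -strength[b], str(b))
            )
            budget = int(np.floor(0.05 * len(negatives)))
            hits = fp = 0
            for b in order:
                if b in true_cols:
                    hits += 1
                else:
                    fp += 1
                    if fp > budget:
                        break
            sens_at_spec = hits / len(true_cols)
        return AccuracyReport(
            scenario=s,
            pPhi=result.pPhi,
            pPsi=result.pPsi,
            reject_degenerate=(result.pPhi < alpha or result.pPsi < alpha),
            n_significant_pcs=result.n_significant_pcs(alpha),
            k_true=s.k_clusters,
            k_hat=k_hat,
            sensitivity=sensitivity,
            specificity=specificity,
            sensitivity_at_spec=sens_at_spec,
            n_true_branches=len(true_cols),
            missing_fraction=missing,
        )
    except Exception as exc:  # a failed stage records, not drops, the run
        return AccuracyReport(
            scenario=s,
            pPhi=float("nan"),
            pPsi=float("nan"),
            reject_degenerate=False,
            n_significant_pcs=0,
            k_true=s.k_clusters,
            k_hat=None,
            sensitivity=None,
            specificity=float("nan"),
            n_true_branches=0,
            missing_fraction=float("nan"),
            failed=f"{type(exc).__name__}: {exc}",
        )
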