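"""Newick I/O, bipartition (split) enumeration, and tree checks.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package.  Species trees are rooted ultrametric time-trees (branch lengths in
time units); gene trees are unrooted phylograms (branch lengths in expected
substitutions per site).  This module adds the split machinery needed for
concordance-based branch matching: every edge of a tree defines a
bipartition of the taxon set, and two edges of two different trees are
comparable through their bipartitions restricted to the shared taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = [
    "Split",
    "TreeError",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "bipartition_set",
    "tip_labels",
    "is_ultrametric",
    "root_age",
    "node_ages",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass(frozen=True)
class Split:
    """An unrooted bipartition of a taxon set, canonicalized for equality.

    ``side_a`` is the side containing the lexicographically smallest label,
    so that ``Split.of(x, y) == Split.of(y, x)``.
    """

    side_a: frozenset
    side_b: frozenset

    @staticmethod
    def of(x, y) -> "Split":
        x, y = frozenset(x), frozenset(y)
        if not x or not y:
            raise TreeError("both sides of a split must be non-empty")
        if x & y:
            raise TreeError("split sides must be disjoint")
        if min(x) > min(y):
            x, y = y, x
        return Split(x, y)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    def restricted(self, taxa) -> "Split | None":
        """Intersect both sides with ``taxa``; None if a side empties."""
        taxa = frozenset(taxa)
        a, b = self.side_a & taxa, self.side_b & taxa
        if not a or not b:
            return None
        return Split.of(a, b)

    def __str__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side_a)}|{fmt(self.side_b)}"


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick statement into a tree.

    Branch lengths are mandatory on all edges except the root edge (a root
    edge length is ignored).  Internal-node labels (e.g. support values) are
    kept.  Raises :class:`TreeError` on malformed input, duplicate tip
    labels, or missing/negative branch lengths.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick statement must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    _validate(tree)
    return tree


def parse_newick_file(path) -> list:
    """Parse every Newick statement in a file (one tree per line or file)."""
    with open(path) as fh:
        content = fh.read()
    trees = []
    for chunk in content.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    if not trees:
        raise TreeError(f"no trees found in {path}")
    return trees


def _validate(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    tree.suppress_unifurcations()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise TreeError(
                f"missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'an internal node'}"
            )
        if not (node.edge.length >= 0) or node.edge.length != node.edge.length:
            raise TreeError(f"invalid branch length {node.edge.length}")


def is_rooted(tree: dendropy.Tree) -> bool:
    """A tree is treated as rooted iff its root has exactly two children."""
    return tree.seed_node.num_child_nodes() == 2


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to Newick with 10 significant digits on branch lengths."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
    )


def tip_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def leafset_map(tree: dendropy.Tree) -> dict:
    """Map each non-root node to the frozenset of tip labels below it."""
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= below[ch]
            below[node] = s
    return below


def bipartition_set(tree: dendropy.Tree, restrict_to=None) -> set:
    """All splits of a tree, one per edge (trivial pendant splits included,
    distinguishable via ``Split.is_trivial``).

    With ``restrict_to``, each split is intersected with that taxon set;
    splits that lose a side are dropped.  The two edges incident to a root
    collapse to a single split, as do edges collapsed by the restriction.
    """
    taxa = tip_labels(tree)
    if restrict_to is not None:
        restrict_to = frozenset(restrict_to)
        if not restrict_to <= taxa:
            raise TreeError("restrict_to contains labels not in the tree")
    below = leafset_map(tree)
    splits = set()
    for node, under in below.items():
        if node is tree.seed_node:
            continue
        other = taxa - under
        if not other:
            continue
        sp = Split.of(under, other)
        if restrict_to is not None:
            sp = sp.restricted(restrict_to)
            if sp is None:
                continue
        splits.add(sp)
    return splits


def node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> dict:
    """Node ages (time before present) of an ultrametric tree.

    Raises :class:`TreeError` if tip depths differ by more than ``tol``
    relative to the root height.
    """
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    tips = [d for n, d in depth.items() if n.is_leaf()]
    height = max(tips)
    if height > 0 and (max(tips) - min(tips)) > tol * height:
        raise TreeError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(tips):.6g}, {max(tips):.6g}]"
        )
    return {n: height - d for n, d in depth.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    try:
        node_ages(tree, tol=tol)
        return True
    except TreeError:
        return False


def root_age(tree: dendropy.Tree, tol: float = 1e-6) -> float:
    """Height of the root of an ultrametric tree, in its time units."""
    ages = node_ages(tree, tol=tol)
    return ages[tree.seed_node]
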