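"""Concordance-based collection of per-branch rates from gene trees.

Each gene tree contributes one row to an n-loci x p-branches matrix.  A
gene-tree branch is used only when its bipartition, restricted to the taxa
shared with the species tree, maps uniquely onto a species-tree branch and
does not conflict with the species-tree topology.  With a rooted ultrametric
species tree, gene branch lengths (substitutions/site) are divided by the
matching species branch durations (time) to give rates; with an unrooted
species tree, raw lengths are collected instead.

An unrooted gene tree cannot distinguish the two species-tree branches
incident to the root, so those two branches form a single matrix column
whose time duration is their sum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees_io import (
    Split,
    TreeError,
    bipartition_set,
    is_rooted,
    leafset_map,
    node_ages,
    tip_labels,
)

__all__ = [
    "BranchKey",
    "RateMatrix",
    "LongBranchReport",
    "LocusSkip",
    "match_branches",
    "collect_clocks",
    "flag_long_branches",
    "mask_long_branches",
]


class LocusSkip(TreeError):
    """A gene tree shares fewer than 4 taxa with the species tree."""


@dataclass(frozen=True)
class BranchKey:
    """Stable identifier for one usable species-tree branch (matrix column).

    ``clades`` holds the rooted descendant tip sets of the species-tree
    edges merged into this column (two for the root-incident pair, one
    otherwise); ``duration`` is their summed time span, or None for an
    unrooted species tree.
    """

    branch_id: str
    split: Split
    duration: float | None
    clades: tuple

    @property
    def is_pendant(self) -> bool:
        return self.split.is_trivial


def species_branch_table(species_tree, with_durations: bool) -> dict:
    """One BranchKey per unrooted split of the species tree.

    Returns ``{Split: BranchKey}``.  The two root-incident edges of a rooted
    tree share a split and are merged (durations summed).
    """
    taxa = tip_labels(species_tree)
    below = leafset_map(species_tree)
    by_split: dict[Split, list] = {}
    for node, under in below.items():
        if node is species_tree.seed_node or under == taxa:
            continue
        sp = Split.of(under, taxa - under)
        by_split.setdefault(sp, []).append((under, node.edge.length))
    table = {}
    for sp, members in by_split.items():
        # id = smaller split side (ties: lexicographically first string)
        a, b = ",".join(sorted(sp.side_a)), ",".join(sorted(sp.side_b))
        if (len(sp.side_a), a) <= (len(sp.side_b), b):
            branch_id = a
        else:
            branch_id = b
        duration = None
        if with_durations:
            duration = float(sum(length or 0.0 for _, length in members))
        table[sp] = BranchKey(
            branch_id=branch_id,
            split=sp,
            duration=duration,
            clades=tuple(sorted((u for u, _ in members), key=sorted)),
        )
    return table


def _logical_edges(gene_tree) -> dict:
    """Gene-tree edges keyed by unrooted split, root pair merged (summed)."""
    taxa = tip_labels(gene_tree)
    below = leafset_map(gene_tree)
    edges: dict[Split, float] = {}
    for node, under in below.items():
        if node is gene_tree.seed_node or under == taxa:
            continue
        sp = Split.of(under, taxa - under)
        edges[sp] = edges.get(sp, 0.0) + (node.edge.length or 0.0)
    return edges


def _compatible(sp: Split, others) -> bool:
    """Split compatibility: some pairwise side intersection must be empty."""
    for ot in others:
        if not (
            not (sp.side_a & ot.side_a)
            or not (sp.side_a & ot.side_b)
            or not (sp.side_b & ot.side_a)
            or not (sp.side_b & ot.side_b)
        ):
            return False
    return True


def match_branches(species_tree, gene_tree, table=None):
    """Classify every (logical) gene-tree edge against the species tree.

    Returns ``(matches, lengths, counts)`` where ``matches`` maps each gene
    split to ``("matched", branch_id)``, ``("ambiguous", ids)``,
    ``("conflicting", None)`` or ``("compatible", None)`` — the last for
    splits that resolve a species polytomy without conflicting; ``lengths``
    maps gene splits to branch lengths (root pair summed); ``counts`` is a
    per-category tally.
    """
    sp_taxa = tip_labels(species_tree)
    g_taxa = tip_labels(gene_tree)
    extra = g_taxa - sp_taxa
    if extra:
        raise TreeError(f"gene-tree tips absent from species tree: {sorted(extra)}")
    shared = g_taxa & sp_taxa
    if len(shared) < 4:
        raise LocusSkip(f"only {len(shared)} taxa shared with the species tree")

    if table is None:
        table = species_branch_table(species_tree, with_durations=False)
    restricted: dict[Split, list] = {}
    for sp, key in table.items():
        r = sp.restricted(shared)
        if r is not None:
            restricted.setdefault(r, []).append(key.branch_id)
    nontrivial_species = [s for s in restricted if not s.is_trivial]

    lengths = _logical_edges(gene_tree)
    matches = {}
    counts = {"matched": 0, "ambiguous": 0, "conflicting": 0, "compatible": 0}
    for gsp in lengths:
        cands = restricted.get(gsp, [])
        if len(cands) == 1:
            matches[gsp] = ("matched", cands[0])
            counts["matched"] += 1
        elif len(cands) > 1:
            matches[gsp] = ("ambiguous", tuple(sorted(cands)))
            counts["ambiguous"] += 1
        elif _compatible(gsp, nontrivial_species):
            matches[gsp] = ("compatible", None)
            counts["compatible"] += 1
        else:
            matches[gsp] = ("conflicting", None)
            counts["conflicting"] += 1
    return matches, lengths, counts


@dataclass
class RateMatrix:
    """n loci x p species-tree branches of rates or raw lengths.

    ``values`` is a DataFrame (rows = locus ids, columns = branch ids, NaN
    for entries lost to discordance or absent taxa).  ``mode`` is ``"rates"``
    (substitutions/site/time) or ``"lengths"`` (substitutions/site).
    """

    values: pd.DataFrame
    mode: str
    branches: dict = field(default_factory=dict)
    match_log: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)

    @property
    def loci(self) -> list:
        return list(self.values.index)

    @property
    def branch_ids(self) -> list:
        return list(self.values.columns)

    def to_tsv(self, path, sidecar=None) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="locus")
        if sidecar is not None:
            meta = {
                "mode": self.mode,
                "skipped_loci": self.skipped,
                "durations": {
                    bid: key.duration for bid, key in self.branches.items()
                },
                "match_log": (
                    self.match_log.to_dict(orient="index")
                    if self.match_log is not None
                    else None
                ),
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=1)

    @staticmethod
    def from_tsv(path, mode="rates") -> "RateMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus", na_values="NA")
        return RateMatrix(values=df, mode=mode)


def collect_clocks(
    species_tree, gene_trees, mode="rates", locus_ids=None, internal_only=False
) -> RateMatrix:
    """Build the rate (or length) matrix from a species tree and gene trees.

    ``mode="rates"`` requires a rooted ultrametric species time-tree;
    ``mode="lengths"`` accepts an unrooted species tree and records raw
    gene-tree branch lengths.  Loci sharing fewer than 4 taxa with the
    species tree are skipped with a warning.  Zero-length gene branches are
    recorded as 0 (the log transform downstream maps them to missing).
    Pendant branches are collected by default; ``internal_only=True``
    restricts the columns to internal species-tree branches.
    """
    if mode not in ("rates", "lengths"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "rates":
        if not is_rooted(species_tree):
            raise TreeError("mode 'rates' requires a rooted species tree")
        node_ages(species_tree)  # raises if not ultrametric
    table = species_branch_table(species_tree, with_durations=(mode == "rates"))
    if internal_only:
        table = {sp: k for sp, k in table.items() if not k.is_pendant}
    order = sorted(table.values(), key=lambda k: k.branch_id)
    col_ids = [k.branch_id for k in order]
    durations = {k.branch_id: k.duration for k in order}

    if locus_ids is None:
        width = max(4, len(str(len(gene_trees))))
        locus_ids = [f"locus_{i:0{width}d}" for i in range(len(gene_trees))]

    rows, kept_ids, log_rows, skipped = [], [], [], []
    for lid, gt in zip(locus_ids, gene_trees):
        try:
            matches, lengths, counts = match_branches(species_tree, gt, table=table)
        except LocusSkip as exc:
            warnings.warn(f"skipping {lid}: {exc}")
            skipped.append(lid)
            continue
        row = dict.fromkeys(col_ids, np.nan)
        for gsp, (status, target) in matches.items():
            if status != "matched":
                continue
            value = lengths[gsp]
            if mode == "rates":
                dur = durations[target]
                if not dur or dur <= 0:
                    continue
                value = value / dur
            row[target] = value
        rows.append(row)
        kept_ids.append(lid)
        log_rows.append(counts)
    if not rows:
        raise TreeError("no usable loci (all gene trees skipped)")
    values = pd.DataFrame(rows, index=kept_ids, columns=col_ids)
    match_log = pd.DataFrame(log_rows, index=kept_ids)
    return RateMatrix(
        values=values,
        mode=mode,
        branches={k.branch_id: k for k in order},
        match_log=match_log,
        skipped=skipped,
    )


@dataclass
class LongBranchReport:
    """Exponential-tail screen for unusually long branches/rates.

    Pooled non-missing values are fitted with an exponential by maximum
    likelihood (rate = 1/mean); entries whose upper-tail probability
    exp(-x/mean) falls below ``alpha`` are flagged.
    """

    mean: float
    alpha: float
    n_examined: int
    flags: list  # (locus_id, branch_id, tail_probability)


def flag_long_branches(matrix, alpha=0.01) -> LongBranchReport:
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    if isinstance(matrix, RateMatrix):
        df = matrix.values
    else:
        df = pd.DataFrame(np.atleast_2d(np.asarray(matrix, dtype=float)))
    vals = df.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    n = int(finite.sum())
    if n < 10:
        raise ValueError(f"need >= 10 non-missing values, got {n}")
    mean = float(vals[finite].mean())
    flags = []
    if mean > 0:
        with np.errstate(over="ignore"):
            tail = np.exp(-vals / mean)
        hit = finite & (tail < alpha)
        for i, j in zip(*np.nonzero(hit)):
            flags.append((df.index[i], df.columns[j], float(tail[i, j])))
    return LongBranchReport(mean=mean, alpha=alpha, n_examined=n, flags=flags)


def mask_long_branches(matrix: RateMatrix, report: LongBranchReport) -> RateMatrix:
    """Copy of ``matrix`` with flagged entries set to missing."""
    values = matrix.values.copy()
    for locus, branch, _ in report.flags:
        values.loc[locus, branch] = np.nan
    return RateMatrix(
        values=values,
        mode=matrix.mode,
        branches=matrix.branches,
        match_log=matrix.match_log,
        skipped=matrix.skipped,
    )
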