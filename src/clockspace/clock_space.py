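"""The Euclidean space of evolutionary rates.

The preferred representation is a principal component analysis of the
n-loci x p-branches rate matrix: loci are samples, species-tree branches are
variables, and PCs are candidate "pacemakers" — axes of correlated rate
variation.  A legacy pathway maps gene trees into two dimensions by
classical multidimensional scaling of pairwise scale-free branch-score
distances (sBSDmin), and loci can be grouped by PAM (k-medoids) with the
gap statistic selecting the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_collection import RateMatrix, match_branches
from .trees_io import TreeError

__all__ = [
    "ClockSpace",
    "ClusterResult",
    "prepare_matrix",
    "pca_clock_space",
    "sbsd_min",
    "mds_embed",
    "pam",
    "group_clocks",
    "annotate_space",
]


# ---------------------------------------------------------------------------
# matrix preparation

@dataclass
class PreparedMatrix:
    """Complete, column-standardized matrix ready for PCA.

    ``data`` rows are loci, columns the retained branch ids; each column has
    mean 0 and unit variance (ddof=1).  ``transform_log`` records the
    log-transform, drops, and imputations applied.
    """

    data: pd.DataFrame
    transform_log: dict

    @property
    def loci(self):
        return list(self.data.index)

    @property
    def branch_ids(self):
        return list(self.data.columns)


def prepare_matrix(
    matrix,
    log_transform=True,
    max_missing_col=0.5,
    max_missing_row=0.5,
) -> PreparedMatrix:
    """Impute and standardize a rate matrix for PCA.

    Steps: optional natural-log transform (zeros become missing first);
    drop columns then rows whose missing fraction exceeds the thresholds;
    impute remaining missing cells with the column mean; center and scale
    each column to unit variance; drop zero-variance columns.
    """
    df = matrix.values.copy() if isinstance(matrix, RateMatrix) else pd.DataFrame(matrix).copy()
    log: dict = {"log_transform": bool(log_transform)}
    if log_transform:
        df = df.where(df > 0)  # zeros/negatives -> NaN
        df = np.log(df)
    col_missing = df.isna().mean(axis=0)
    drop_cols = list(df.columns[col_missing > max_missing_col])
    df = df.drop(columns=drop_cols)
    row_missing = df.isna().mean(axis=1)
    drop_rows = list(df.index[row_missing > max_missing_row])
    df = df.drop(index=drop_rows)
    log["dropped_columns"] = drop_cols
    log["dropped_rows"] = drop_rows
    log["n_imputed"] = int(df.isna().to_numpy().sum())
    df = df.fillna(df.mean(axis=0))
    sd = df.std(axis=0, ddof=1)
    const = list(df.columns[~(sd > 0)])
    df = df.drop(columns=const)
    sd = sd.drop(index=const)
    log["dropped_constant_columns"] = const
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise ValueError(
            f"too little data after filtering: {df.shape[0]} loci x "
            f"{df.shape[1]} branches (need >= 3 of each)"
        )
    df = (df - df.mean(axis=0)) / sd
    return PreparedMatrix(data=df, transform_log=log)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class ClockSpace:
    """PCA of the prepared rate matrix.

    ``scores``: loci x PCs projections; ``loadings``: branches x PCs
    eigenvectors of the branch correlation matrix; ``eigenvalues`` sum to
    the number of retained branches p'.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    transform_log: dict = field(default_factory=dict)

    @property
    def retained_branch_ids(self):
        return list(self.loadings.index)


def _eig_correlation(X: np.ndarray):
    """Eigendecomposition of the correlation matrix of standardized X.

    Returns (eigenvalues descending, eigenvectors as columns) with the sign
    of each eigenvector fixed so its largest-magnitude entry is positive.
    """
    n = X.shape[0]
    R = (X.T @ X) / (n - 1)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    return vals, vecs * flip


def pca_clock_space(prepared: PreparedMatrix) -> ClockSpace:
    """Correlation-scaled PCA: eigendecomposition of the branch-branch
    correlation matrix; scores are locus projections onto the eigenvectors."""
    X = prepared.data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("prepared matrix contains non-finite entries")
    n, p = X.shape
    if n < 3 or p < 3:
        raise ValueError("need at least 3 loci and 3 branches")
    vals, vecs = _eig_correlation(X)
    pcs = [f"PC{i + 1}" for i in range(p)]
    scores = pd.DataFrame(X @ vecs, index=prepared.data.index, columns=pcs)
    loadings = pd.DataFrame(vecs, index=prepared.data.columns, columns=pcs)
    total = vals.sum()
    return ClockSpace(
        scores=scores,
        loadings=loadings,
        eigenvalues=vals,
        variance_proportions=vals / total,
        transform_log=dict(prepared.transform_log),
    )


# ---------------------------------------------------------------------------
# legacy tree-distance pathway

def _restricted_edge_lengths(tree, shared):
    """Map restricted splits to the list of logical edge lengths falling
    onto each, after intersecting every split with ``shared``."""
    from .rate_collection import _logical_edges

    out: dict = {}
    for sp, length in _logical_edges(tree).items():
        r = sp.restricted(shared)
        if r is not None:
            out.setdefault(r, []).append(length)
    return out


def sbsd_min(tree_a, tree_b) -> float:
    """Scale-free minimum branch-score distance between two phylograms.

    Branch lengths are compared only on branches uniquely matched between
    the two trees (restricted-split concordance on the shared taxa).  For
    matched vectors a, b the directed distance is ||a - s* b|| / ||a|| with
    the least-squares scaling s* = (a.b)/(b.b); the minimum over both
    directions is returned, so the distance is 0 whenever one tree is a
    rescaling of the other.
    """
    from .trees_io import tip_labels

    shared = tip_labels(tree_a) & tip_labels(tree_b)
    if len(shared) < 4:
        raise TreeError(f"trees share only {len(shared)} taxa (need >= 4)")
    la = _restricted_edge_lengths(tree_a, shared)
    lb = _restricted_edge_lengths(tree_b, shared)
    pairs = [
        (la[sp][0], lb[sp][0])
        for sp in sorted(la.keys() & lb.keys(), key=str)
        if len(la[sp]) == 1 and len(lb[sp]) == 1
    ]
    if len(pairs) < 3:
        raise TreeError(f"only {len(pairs)} matched branches (need >= 3)")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)

    def directed(u, v):
        s = (u @ v) / (v @ v)
        return float(np.linalg.norm(u - s * v) / np.linalg.norm(u))

    return min(directed(a, b), directed(b, a))


def sbsd_matrix(gene_trees) -> np.ndarray:
    """Symmetric matrix of pairwise sbsd_min distances."""
    n = len(gene_trees)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sbsd_min(gene_trees[i], gene_trees[j])
    return D


def mds_embed(distances, n_components=2) -> np.ndarray:
    """Classical (Torgerson) metric MDS.

    Double-centers the squared distance matrix and embeds on the top
    eigenvectors; negative eigenvalues are truncated at zero.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > 1e-8:
        raise ValueError("distance matrix is not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


# ---------------------------------------------------------------------------
# PAM + gap statistic

def pam(D: np.ndarray, k: int) -> tuple:
    """Deterministic PAM (k-medoids) on a precomputed distance matrix.

    Greedy build phase then full swap phase; all ties broken by lowest
    index.  Returns (medoid indices, assignments).
    """
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n} points")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dm = D[:, med]
        nearest = np.argmin(dm, axis=1)
        d1 = dm[np.arange(n), nearest]
        dm2 = dm.copy()
        dm2[np.arange(n), nearest] = np.inf
        d2 = dm2.min(axis=1) if k > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best = (0.0, None)
        non_med = np.setdiff1d(np.arange(n), med)
        for mi, m in enumerate(med):
            base = np.where(nearest == mi, d2, d1)
            new_costs = np.minimum(D[non_med], base[None, :]).sum(axis=1)
            ci = int(np.argmin(new_costs))
            delta = new_costs[ci] - cost
            if delta < best[0] - 1e-12:
                best = (delta, (m, int(non_med[ci])))
        if best[1] is None:
            break
        m_out, h_in = best[1]
        medoids = sorted(set(medoids) - {m_out} | {h_in})
    med = np.array(medoids)
    assignments = med[np.argmin(D[:, med], axis=1)]
    return medoids, assignments


def _within_dispersion(D2: np.ndarray, assignments: np.ndarray) -> float:
    """W_k = sum over clusters of (pairwise squared distances) / (2 n_r)."""
    w = 0.0
    for c in np.unique(assignments):
        idx = np.nonzero(assignments == c)[0]
        w += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return w


@dataclass
class ClusterResult:
    """PAM clustering with gap-statistic selection of k."""

    k_selected: int
    assignments: pd.Series
    gap_curve: pd.DataFrame  # columns: k, gap, s_k
    medoids: list


def group_clocks(coordinates, k_max=10, B=50, seed=0) -> ClusterResult:
    """Cluster loci in an embedding and pick k by the gap statistic.

    PAM is run for k = 1..k_max on Euclidean distances; B reference
    datasets are drawn uniformly over the data's bounding box; gap(k) is
    the mean log reference dispersion minus the observed log dispersion,
    and the selected k is the smallest with gap(k) >= gap(k+1) - s_{k+1}.
    """
    if isinstance(coordinates, pd.DataFrame):
        index = coordinates.index
        X = coordinates.to_numpy(dtype=float)
    else:
        X = np.asarray(coordinates, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if k_max < 1 or n < k_max + 1:
        raise ValueError("need at least k_max + 1 points")
    rng = np.random.default_rng(seed)

    def dispersions(Y):
        diff = Y[:, None, :] - Y[None, :, :]
        D2 = np.einsum("ijk,ijk->ij", diff, diff)
        D = np.sqrt(np.clip(D2, 0.0, None))
        out, assign = [], []
        for k in range(1, k_max + 1):
            _, a = pam(D, k)
            out.append(_within_dispersion(D2, a))
            assign.append(a)
        return np.array(out), assign

    W_obs, assigns = dispersions(X)
    lo, hi = X.min(axis=0), X.max(axis=0)
    logW_ref = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        W_ref, _ = dispersions(ref)
        logW_ref[b] = np.log(np.maximum(W_ref, 1e-300))
    gap = logW_ref.mean(axis=0) - np.log(np.maximum(W_obs, 1e-300))
    s = logW_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    k_selected = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            k_selected = k
            break
    medoids, a = pam(
        np.sqrt(
            np.clip(
                ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0, None
            )
        ),
        k_selected,
    )
    # relabel clusters 0..k-1 in order of first appearance
    _, labels = np.unique(a, return_inverse=True)
    gap_curve = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "gap": gap, "s_k": s}
    )
    return ClusterResult(
        k_selected=int(k_selected),
        assignments=pd.Series(labels, index=index, name="cluster"),
        gap_curve=gap_curve,
        medoids=[index[m] for m in medoids],
    )


# ---------------------------------------------------------------------------
# annotation

def mean_branch_support(gene_tree) -> float:
    """Arithmetic mean of internal-node labels interpretable as numbers."""
    vals = []
    for node in gene_tree.preorder_internal_node_iter():
        if node is gene_tree.seed_node:
            continue
        label = node.label
        if label is None:
            continue
        try:
            vals.append(float(label))
        except ValueError:
            continue
    return float(np.mean(vals)) if vals else np.nan


def annotate_space(
    space: ClockSpace,
    clusters: ClusterResult = None,
    matrix: RateMatrix = None,
    gene_trees: dict = None,
    user_table: pd.DataFrame = None,
    mds_coords: pd.DataFrame = None,
) -> pd.DataFrame:
    """Per-locus table joining PC1/PC2 coordinates with correlate metrics:
    cluster label, overall locus rate (mean of non-missing row entries),
    mean branch support, and arbitrary user columns."""
    out = space.scores[["PC1", "PC2"]].copy()
    if mds_coords is not None:
        out = out.join(mds_coords, how="left")
    if clusters is not None:
        out = out.join(clusters.assignments, how="left")
    if matrix is not None:
        out = out.join(
            matrix.values.mean(axis=1, skipna=True).rename("mean_rate"),
            how="left",
        )
    if gene_trees is not None:
        supports = pd.Series(
            {lid: mean_branch_support(t) for lid, t in gene_trees.items()},
            name="mean_support",
        )
        out = out.join(supports, how="left")
    if user_table is not None:
        if user_table.index.has_duplicates:
            raise ValueError("user table has duplicate locus ids")
        out = out.join(user_table, how="left")
    return out


def filter_extreme_loci(space: ClockSpace, quantile=0.8, n_pcs=2) -> list:
    """Loci whose absolute score on any of the first ``n_pcs`` PCs exceeds
    that PC's ``quantile`` of absolute scores — a sensitivity filter for
    down-weighting loci at the extremes of the space."""
    keep = pd.Series(True, index=space.scores.index)
    for pc in space.scores.columns[:n_pcs]:
        a = space.scores[pc].abs()
        keep &= a <= a.quantile(quantile)
    return list(space.scores.index[keep])
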