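"""Permutation tests of pacemaker hypotheses of genome-wide rate variation.

Three tests share a common null distribution obtained by independently
permuting the locus rates within each branch (column) of the prepared
matrix, which destroys any correlation between branches while preserving
each branch's marginal distribution:

* a test of the *degenerate multiple pacemaker* model (fully independent
  rates) via the eigenvalue-dispersion statistics phi and psi of the
  branch correlation matrix;
* a per-PC test of how many axes ("pacemakers") describe significantly
  more variance than expected under permutation;
* a per-branch, per-PC test of whether a branch's loading magnitude is
  larger than under permutation — evidence for *local* pacemakers.

All p-values use the add-one convention p = (1 + #{null >= obs}) / (1 + N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .clock_space import PreparedMatrix, _eig_correlation

__all__ = [
    "EigStats",
    "PacemakerResult",
    "phi_psi",
    "permute_within_branches",
    "permutation_pvalue",
    "run_pacemaker_tests",
    "test_degenerate_pacemaker",
    "test_significant_pcs",
    "test_branch_loadings",
    "classify_pacemaker_model",
]


@dataclass(frozen=True)
class EigStats:
    """Eigenvalue-dispersion summary of a correlation matrix.

    phi in [0, 1] rescales the eigenvalue variance so that 0 means all
    eigenvalues equal 1 (mutually uncorrelated variables) and 1 means a
    single eigenvalue carries everything (perfect correlation).  psi is the
    unscaled dispersion sum((lambda - 1)^2), ranging 0 .. p'(p'-1).
    """

    phi: float
    psi: float
    eigenvalues: tuple
    p_prime: int


def phi_psi(eigenvalues, p_prime: int) -> EigStats:
    lam = np.asarray(eigenvalues, dtype=float)
    if p_prime < 2:
        raise ValueError("need at least 2 variables")
    if (lam < -1e-9).any():
        raise ValueError("eigenvalues must be non-negative")
    if abs(lam.sum() - p_prime) > 1e-6 * max(1.0, p_prime):
        raise ValueError(
            f"eigenvalues sum to {lam.sum():.8g}, expected p'={p_prime} "
            "(correlation-matrix eigenvalues required)"
        )
    sq = float((lam ** 2).sum())
    psi = sq - 2.0 * float(lam.sum()) + p_prime  # = sum((lam-1)^2)
    phi = float(np.sqrt(max(sq - p_prime, 0.0) / (p_prime * (p_prime - 1))))
    return EigStats(phi=phi, psi=psi, eigenvalues=tuple(lam), p_prime=p_prime)


def permute_within_branches(matrix: np.ndarray, rng) -> np.ndarray:
    """Independently shuffle each column; every column keeps its multiset
    of values while the joint (row) structure is destroyed."""
    X = np.asarray(matrix)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(X.shape[0]), j]
    return out


def permutation_pvalue(observed: float, permuted) -> float:
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("empty permutation distribution")
    return float((1 + (permuted >= observed).sum()) / (1 + permuted.size))


@dataclass
class PacemakerResult:
    """Joint result of the three permutation tests."""

    pPhi: float
    pPsi: float
    pPCs: pd.Series  # index PC1..PCm
    pIL: pd.DataFrame  # branches x PCs
    observed: EigStats
    n_permutations: int
    seed: int
    pIL_adjusted: pd.DataFrame | None = None
    variance_proportions: np.ndarray = field(default=None)

    def n_significant_pcs(self, alpha=0.05) -> int:
        return int((self.pPCs < alpha).sum())


def _restandardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def run_pacemaker_tests(
    prepared: PreparedMatrix,
    n_perm: int = 100,
    seed: int = 0,
    adjust: str = "none",
) -> PacemakerResult:
    """Run all three tests on one shared permutation set.

    The observed statistics pass through the identical code path as the
    permuted replicates (re-standardization then eigendecomposition), so
    any preprocessing asymmetry would cancel.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    X = prepared.data.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    def stats(M):
        Z = _restandardize(M)
        vals, vecs = _eig_correlation(Z)
        es = phi_psi(vals, p)
        props = vals / vals.sum()
        return es, props, np.abs(vecs)

    obs, obs_props, obs_absload = stats(X)
    perm_phi = np.empty(n_perm)
    perm_psi = np.empty(n_perm)
    perm_props = np.empty((n_perm, p))
    perm_absload = np.empty((n_perm, p, p))
    for b in range(n_perm):
        es, props, absload = stats(permute_within_branches(X, rng))
        perm_phi[b] = es.phi
        perm_psi[b] = es.psi
        perm_props[b] = props
        perm_absload[b] = absload

    pcs = [f"PC{i + 1}" for i in range(p)]
    p_phi = permutation_pvalue(obs.phi, perm_phi)
    p_psi = permutation_pvalue(obs.psi, perm_psi)
    p_pcs = pd.Series(
        (1 + (perm_props >= obs_props[None, :]).sum(axis=0)) / (1 + n_perm),
        index=pcs,
        name="pPC",
    )
    pil = pd.DataFrame(
        (1 + (perm_absload >= obs_absload[None, :, :]).sum(axis=0))
        / (1 + n_perm),
        index=prepared.data.columns,
        columns=pcs,
    )
    pil_adj = None
    if adjust == "BH":
        pil_adj = pil.copy()
        for pc in pcs:
            pil_adj[pc] = multipletests(pil[pc].to_numpy(), method="fdr_bh")[1]
    return PacemakerResult(
        pPhi=p_phi,
        pPsi=p_psi,
        pPCs=p_pcs,
        pIL=pil,
        observed=obs,
        n_permutations=n_perm,
        seed=seed,
        pIL_adjusted=pil_adj,
        variance_proportions=obs_props,
    )


def test_degenerate_pacemaker(prepared, n_perm=100, seed=0):
    """p-values of phi and psi against the within-branch permutation null.
    A significant result rejects the degenerate multiple pacemaker model."""
    res = run_pacemaker_tests(prepared, n_perm=n_perm, seed=seed)
    return res.pPhi, res.pPsi


def test_significant_pcs(prepared, n_perm=100, seed=0):
    """Per-PC p-values of the variance proportion at each rank; the count
    of significant PCs estimates the number of pacemakers."""
    return run_pacemaker_tests(prepared, n_perm=n_perm, seed=seed).pPCs


def test_branch_loadings(prepared, n_perm=100, seed=0, adjust="none"):
    """Per-branch, per-PC p-values of |loading| versus permutation; small
    values point to branches driving an axis (local pacemakers)."""
    res = run_pacemaker_tests(prepared, n_perm=n_perm, seed=seed, adjust=adjust)
    return res.pIL_adjusted if adjust == "BH" else res.pIL


def classify_pacemaker_model(result: PacemakerResult, alpha=0.05) -> str:
    """Qualitative reading of the joint test results."""
    if result.pPhi >= alpha and result.pPsi >= alpha:
        return "degenerate"
    n_sig = result.n_significant_pcs(alpha)
    sig_pcs = list(result.pPCs.index[result.pPCs < alpha])
    local = (
        (result.pIL[sig_pcs] < alpha).any(axis=1).sum() if sig_pcs else 0
    )
    if n_sig <= 1:
        return "universal"
    if local and local < len(result.pIL):
        return "multiple local"
    return "multiple"
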