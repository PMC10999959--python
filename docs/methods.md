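# Methods

## Rate collection

The unit of analysis is the `n × p` matrix of per-branch evolutionary
rates: `n` loci (gene trees) by `p` species-tree branches. A gene-tree
branch is compared with the species tree through its bipartition restricted
to the shared taxon set. The branch contributes a value only when exactly
one species-tree branch restricts to the same bipartition; when taxon
absence collapses a species-tree path onto a single restricted bipartition
the match is *ambiguous* and recorded as missing (we do not apportion the
gene branch's length over the path), and bipartitions incompatible with the
restricted species tree are *conflicting* and likewise missing. This
applies uniformly to pendant branches: a tip branch matches the species
pendant branch of the same taxon unless missing taxa have collapsed
internal branches onto it, in which case it too is ambiguous — dividing a
gene pendant length by only the pendant's duration would otherwise
overestimate the rate. Bipartitions that resolve a polytomy of the species
tree without conflicting are recorded separately (`compatible`) and are
also missing.

Because an unrooted gene tree cannot separate the two species-tree branches
incident to the root, those two branches form a single matrix column whose
time duration is the sum of the two; the two root-incident gene branches
are likewise merged by their shared bipartition. A rooted binary species
tree with `N` tips therefore yields `p = 2N − 3` columns. Pendant branches
are included by default — terminal branches carry most of the rate signal
in shallow trees.

In `rates` mode (rooted ultrametric species time-tree) a matched value is
gene branch length divided by species branch duration
(substitutions/site/time); in `lengths` mode raw gene branch lengths are
collected. Zero-length gene branches are kept as rate 0 at collection; the
log transform downstream turns them into missing values. Loci sharing
fewer than 4 taxa with the species tree are skipped with a warning.

An optional screen for unusually long branches fits a single exponential to
all pooled non-missing values by maximum likelihood (rate = 1/mean) and
flags entries with upper-tail probability `exp(−x/mean)` below a chosen
`alpha` (default 0.01); flagged entries can be masked to missing.

## The clock space

Preparation: optional natural-log transform (default on for rates, which
are right-skewed and whose biologically interesting effects are
multiplicative); columns then rows with more than a configurable fraction
of missing entries (default 0.5) are dropped; remaining gaps are imputed
with the column mean — neutral under the subsequent centering — and each
column is centered and scaled to unit variance (ddof = 1). PCA is the
eigendecomposition of the resulting branch–branch correlation matrix, so
the eigenvalues sum to the number of retained branches `p′`. Eigenvector
signs are fixed so each loading column's largest-magnitude entry is
positive, making output independent of the eigensolver. Correlation (not
covariance) scaling is deliberate: the dispersion statistics below are
defined on correlation-matrix eigenvalues, and branch durations vary over
orders of magnitude.

The legacy pathway computes, for each tree pair, the scale-free minimum
branch-score distance: with branch-length vectors `a, b` on uniquely
matched branches, `d(a→b) = ‖a − s*b‖/‖a‖` with the closed-form
least-squares scaling `s* = (a·b)/(b·b)`, minimized over both directions —
zero whenever one tree is a rescaling of the other. Classical Torgerson
MDS (double-centered squared distances, top-2 eigenvectors, negative
eigenvalues truncated at zero) maps loci to the plane.

Clustering is deterministic PAM: greedy build phase, then a full swap
phase with ties broken by lowest index. The number of clusters is selected
with the gap statistic: `W_k` is the sum over clusters of mean pairwise
squared distances (the `D_r/(2n_r)` form), reference sets are drawn
uniformly over the data's bounding box, `s_k = sd_B(log W*) √(1 + 1/B)`,
and the selected `k` is the smallest with `gap(k) ≥ gap(k+1) − s_{k+1}`
(`k_max` if none qualifies).

## Pacemaker tests

All three tests share one permutation null: locus values are permuted
independently within each branch, destroying inter-branch correlation while
preserving marginals. Observed and permuted datasets pass through the
identical code path (re-standardization, then eigendecomposition) so no
preprocessing asymmetry can leak into the comparison. One seeded
permutation set is reused across the three tests. P-values use the add-one
convention `p = (1 + #{null ≥ obs}) / (1 + N)`, so the smallest attainable
p-value is `1/(N+1)` and ties count against significance. Defaults:
`n_perm = 100`.

- **Degenerate-model test.** `psi = Σ(λ−1)²` and
  `phi = sqrt((Σλ² − p′)/(p′(p′−1)))` measure eigenvalue dispersion; both
  are 0 for mutually uncorrelated branches and maximal (`p′(p′−1)` and 1)
  under perfect correlation. Significant values reject fully independent
  rates.
- **Significant PCs.** Each PC rank's variance proportion is compared with
  the permutation distribution of the same rank; the count of significant
  PCs estimates the number of pacemakers.
- **Branch loadings.** `pIL[j, i]` compares |loading| of branch `j` on PC
  rank `i` against the permutation distribution for the same branch and
  rank. Comparison is by rank, accepting rank-swapping noise under the
  null; this avoids eigenvector-matching heuristics. Benjamini–Hochberg
  adjustment across branches within each PC is available but off by
  default; raw p-values are always reported.

## Simulation engine

The factorial design crosses six factors at three levels each (729 cells):
`θ ∈ {0.02, 0.5, 1}`, mean rate ∈ {0.01, 0.05, 0.1} substitutions/site/
time, white-noise sd ∈ {0.005, 0.05, 0.5}, loci ∈ {100, 500, 1000},
clusters k ∈ {1, 3, 5}, and accelerated-branch fraction ∈ {0, 0.02, 0.10}
(factor 5). Scenario seeds are CRC-32 hashes of the factor tuple and
replicate index, so any cell is reproducible in isolation.

*Species trees* come from a constant-rate birth–death process (defaults:
50 tips, birth 0.5, death 0.1) conditioned on the number of surviving tips
via the general sampling approach (grow to twice the target, sample a
moment when exactly the target number of lineages existed), then rescaled
so the root age is exactly 50 time units.

*Gene trees* are simulated under the multispecies coalescent with msprime:
one haploid sample per species, constant population-size parameter θ on
every branch (haploid size θ/2, giving pairwise coalescence rate 2/θ per
time unit).

*Clocks*: every gene branch draws an independent gamma rate with mean
`mean_rate × multiplier` and standard deviation `rate_sd` (shape (μ/σ)²,
scale σ²/μ); `rate_sd = 0` collapses to a strict clock. The multiplier
belongs to the species branch containing the gene branch's midpoint (1
above the species root). Holding the sd fixed rather than proportional to
the mean means accelerated branches have a higher signal-to-noise ratio on
shared axes — which is what makes them detectable after per-branch
standardization, since a pure multiplicative column constant is removed by
centering and scaling.

*Clusters*: loci are assigned to k near-equal blocks; each cluster shares
one branch-multiplier vector drawn i.i.d. lognormal per species branch
with median 1 and log-scale sd 1.0 (chosen once as a spread that makes
cluster patterns distinct but overlapping; k = 1 uses all-ones
multipliers). *Accelerations* select `round(fraction × branch count)`
species branches uniformly without replacement, fixed per dataset, and
multiply their rates by 5, composed multiplicatively with cluster
multipliers.

Scoring an end-to-end run: the degenerate model's rejection, the number of
significant PCs, the gap-statistic `k̂` against the true k, and branch
identification — a truth-flagged branch counts as recovered if its minimum
`pIL` across significant PCs is below α; sensitivity is reported as
missing when no branch was accelerated, and specificity over the
non-accelerated branches. Because the α-threshold rule yields different
specificities in different conditions, a second, ROC-style measure ranks
branches by minimum `pIL` (ties broken by loading magnitude) and reports
the sensitivity attained while holding specificity at 0.95 — the right
quantity for comparing recovery difficulty across conditions.

## What the simulations do and do not emulate

The generator produces gene trees directly (no sequence simulation or
gene-tree estimation error), uses one sample per species, constant θ, no
migration or hybridization, and uncorrelated (white-noise) branch rates.
Passing tests therefore demonstrate correctness of the collection,
embedding, and testing machinery under coalescent discordance and known
rate structure — not robustness to estimation error, rate autocorrelation,
or model misspecification in real data.

## Problem sizes and numerical choices

The validation suite uses scaled-down but representative sizes chosen for
quick iteration: type-I calibration on 500 i.i.d. 200×10 matrices with 99
permutations; power runs on 50 replicates of 500 loci over 50-tip trees;
local-pacemaker sensitivity on 12 replicates per condition at 49
permutations. Ultrametricity tolerance is 1e-6 relative to root height;
eigenvalue/loading identities are asserted at 1e-8; the PC sign convention
and PAM tie-breaking make all outputs bitwise reproducible given a seed.
Degenerate inputs: zero-variance columns are dropped before PCA; matrices
with fewer than 3 rows or columns after filtering are rejected; duplicate
tip labels and missing branch lengths are parse errors.

## Known limitations

Ambiguous (path-collapsed) matches discard signal that a length-apportioning
scheme might retain; imputation by column mean shrinks locus contrasts when
missingness is high; the per-rank reading of `pIL` can dilute signal when
eigenvalue ranks swap under the null; the gap statistic's uniform reference
is conservative for elongated clouds (consistent with the overall finding
that cluster-number recovery is the hardest task in this pipeline).
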