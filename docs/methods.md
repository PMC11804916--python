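# Methods

This note documents the statistical procedures implemented in `symptomnet`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter.

## Preprocessing

**Missingness filter.** Subject rows or item columns with more than 30%
missing entries are removed (`row_max = col_max = 0.3`, strict inequality).
Removal is *iterative*: after each removal the missing fractions are
recomputed, and the single worst row-or-column is removed next (rows win
ties, then the lowest index), until a fixed point. Iterating is the
conservative reading of a one-step rule — a deleted row can push a column
over the bound — and the procedure is deterministic and idempotent. If an
entire axis would be deleted, the filter fails loudly with the surviving
dimensions.

**Probabilistic-PCA imputation.** Remaining holes are imputed under the
probabilistic PCA model `x = μ + W t + ε`, `t ~ N(0, I_k)`,
`ε ~ N(0, σ² I)`, fitted by EM with the missing coordinates treated as
latent variables alongside `t`. The E-step computes, per missingness
pattern, the posterior of `(t, x_miss)` given `x_obs`; the M-step is the
exact joint regression of `E[x]` on `[1, t]` followed by the closed-form
σ² update, so the observed-data log-likelihood is non-decreasing (checked
to 1e-8 relative slack in the tests). Convergence: relative change of the
observed-data log-likelihood below `tol = 1e-6`, or `max_iter = 500` with a
warning (the model is still returned, flagged). σ² is floored at 1e-12 so
exactly low-rank data cannot produce a singular model.

The rank `k` is not dictated by the data format; by default it is the
smallest k whose leading eigenvalues of the pairwise-complete covariance
capture ≥ 80% of total variance, capped at min(10, M−1). It is a logged,
configurable parameter (`PipelineConfig.ppca_k`), not a claim about any
particular dataset. Missing entries are replaced by their conditional
expectation given the row's observed entries; observed entries are never
modified. This is single imputation: no uncertainty is propagated, and the
MCAR/ignorable-missingness assumption is inherited by everything
downstream.

**Quantile normalization.** Each item is independently mapped to z-scores
by the rank-based inverse-normal transform with Blom plotting positions,
`z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4))`, average ranks for ties. This is the
"z-scores by quantile normalization" reading appropriate for item-level
psychometric data — *not* the cross-column distribution matching used for
expression arrays, which would destroy item identities. A constant column
is normalized to zeros with a warning. For n ≥ 100 without heavy ties the
transformed columns have mean within ±0.05 and SD within [0.9, 1.1].

**Polarity.** Cognition and function scores (higher = better) are negated
*after* normalization, which for a rank-symmetric transform is equivalent
to inverting the raw scores first. Item metadata is updated so the
operation is effectively idempotent on an oriented dataset.

## Network construction

Edges are pairwise Pearson correlations across patients, computed on the
complete, normalized, oriented matrix; the diagonal is zeroed.
Coefficients with **|r| < 0.2** are set to zero (configurable threshold;
strict inequality, so r = 0.2 survives). Thresholding is on the absolute
value by default, preserving the sign of surviving negative edges: the
stated purpose of the rule is to remove *weak* correlations, and the
global-strength statistic sums absolute weights. A `signed` mode that
zeroes every r < threshold (discarding all negatives) is available for
sensitivity analyses. Items whose every correlation fell below the
threshold are dropped from the network (logged).

Summaries: **global strength** = Σ|w| over unordered pairs; **density** =
fraction of possible unordered pairs with a nonzero edge (the definition
consistent with densities reported on a 0–1 scale).

## Community detection

Newman spectral community detection on the generalized modularity matrix

    B_ij = A_ij − γ k_i k_j / 2m,   A = |W|, k = node strength,

with resolution **γ = 0.4** by default. The algorithm recursively bisects
by the sign of the leading eigenvector of the subgraph-corrected matrix
`B^(g)`, refines each bisection with Kernighan–Lin-style single-node moves
(greedy best-improvement until no move raises Q), and recurses while a
split improves Q by more than 1e-10. The eigenvector sign is anchored so
the lowest-index node of a group lands on the positive side, making the
procedure fully deterministic; the `seed` argument exists only for
interface symmetry. On every ≤ 8-node network in the test fixture suite
the procedure attains the global maximum-Q partition found by exhaustive
search over all set partitions; this is an empirical property of those
fixtures, not a general guarantee of spectral bisection.

Negative correlations enter community detection and path-based measures as
absolute values (`negative_edges = "absolute"`), since shortest-path
lengths and the configuration null model are undefined for negative
weights; `"discard"` drops them instead.

## Centrality

Edge lengths are 1/|w|. **Betweenness** is Brandes' algorithm over
weighted shortest paths, unordered pairs, fractional credit across tied
geodesics, unnormalized. **Degree** is the raw count of incident edges
("number of connections"); weighted strength is available but not the
default. **Closeness** uses the Wasserman–Faust component correction
`((R_v−1)/(M−1)) · ((R_v−1)/Σd)` with `R_v` the size of v's component, so
values remain comparable across disconnected networks and are 0 for
isolates. Hub summaries report each network's top-k items per measure
(k = 3 by default, configurable; ties broken alphabetically so reports are
reproducible) and, across networks, the number of networks in which an
item ranks top-k. Cross-network consistency of a centrality measure is
the Pearson correlation over shared items; with fewer than 3 shared items
or zero variance it raises a typed error rather than returning a silent
number.

## Group comparison

`split_by_item` divides subjects by endorsement of a raw (pre-
normalization) item, default cutoff "> 0" matching yes/no worry items;
the cutoff is configurable for ordinal scales. The splitting item is
excluded from both groups' networks: conditioning on it truncates its
variance and would create selection artifacts.

The **network comparison test** compares the groups' thresholded networks
on global strength, `S = |GS(A) − GS(B)|`. Preprocessing is performed
once on the pooled data and only the group labels are permuted (n_perm =
1000 by default), which keeps the null exchangeable and avoids re-imputing
per permutation; the p-value uses the plus-one estimator
`p = (1 + #{S_perm ≥ S_obs}) / (1 + n_perm)`, one-sided upper tail (S is a
nonnegative discrepancy), so p is never exactly 0. Permuted networks keep
all items so density always has the same denominator. Internally the
pooled rows are put in a canonical order so the result is invariant to
swapping the two arguments. Groups smaller than 10 are refused.

Domain totals (per-subject sums of oriented z-scores over a domain's
items, splitting item excluded) are contrasted with one-way fixed-effects
ANOVA; the effect size is partial eta squared,
ηp² = SS_between/(SS_between + SS_within).

## Synthetic cohorts

The generator emulates the *statistical* structure the pipeline assumes:
items loading on six correlated latent domain factors (depression,
anxiety, apathy, fatigue, cognition, ADL); a worry item that cross-loads
on every factor and therefore bridges all modules; binary (yes/no
depression-scale style), likert (ordinal apathy/fatigue/ADL style) and
continuous (harmonized cognition style) response types, discretized at
fixed population quantiles so the latent ordering survives attenuated;
MCAR missingness; and a `connectivity_scale` multiplier on the off-diagonal
factor correlations that makes worry+-style groups denser than
worry−-style groups.

Defaults, chosen once: primary loadings 0.7 and noise SD 0.7 (within-module
item correlations ≈ 0.5 on the continuous scale), factor correlations 0.3
among psychiatric domains and 0.15 with cognition/ADL, missingness 5%,
n = 500. For two-group simulations the base world is uniform factor
correlation 0.35 with dense/sparse scales 1.0/0.4 and n = 400 per group
(`worry_contrast_spec`): since no effect size links worry status to
connectivity in published stroke data, these scales are free parameters
calibrated once so that between-module correlations straddle the 0.2
threshold and the resulting densities (~0.26 vs ~0.14) reproduce the
reported dense-vs-sparse ordering (0.23 vs 0.12 in the motivating
cohorts); they were not tuned further.

What a green test does *not* establish: the generator has no lesion
locations, demographics, cohort-specific item catalogs, longitudinal
structure, non-ignorable missingness, or realistic marginal distributions
beyond the three response types — so passing tests validate the pipeline's
statistical machinery, not any clinical claim. Published per-cohort test
statistics (permutation S/p values, ANOVA F/ηp² on consortium data) cannot
be reproduced without the original patient-level data and are treated as
structural anchors only.

## Numerical choices and degenerate inputs

- Strict inequalities throughout match the stated rules: ">30% missing"
  removes, "|r| < 0.2" zeroes.
- Filter ties: rows before columns, then lowest index.
- Hub ties: lexicographic by label.
- Spectral recursion stops at ΔQ ≤ 1e-10; KL moves likewise.
- EM: σ² floored at 1e-12; non-convergence warns but returns.
- Constant columns: normalization warns and emits zeros; correlation
  construction rejects them by name (they should not reach it).
- Degenerate ANOVA (zero within-group variance, equal means) raises; with
  unequal means F = ∞, p = 0 is returned.
- Permutation p never 0 by construction (plus-one estimator).
- All stochastic steps take explicit seeds; pipeline runs are reproducible
  byte-for-byte given a config.

## Known limitations

Single imputation only; Pearson correlations on ordinal items (no
polychoric option); no regularized partial-correlation (graphical lasso)
estimation; no bootstrapped centrality stability intervals; no edge-level
or centrality-invariance variants of the permutation comparison; no
cross-cohort meta-analytic pooling beyond running the pipeline on
concatenated harmonized tables.
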