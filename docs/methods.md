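# Methods

This note documents the models, rules and numerical choices behind
`immunopanel`, in the order the pipeline runs them, together with the
design decisions that were genuinely open and the limitations a user
should know.

## Scope and response variable

All classification stages use vital status at end of follow-up
(1 = dead, 0 = alive) as the binary response, ignoring follow-up time
once a patient is dichotomized. This mirrors the discovery procedure the
package implements; it is statistically naive — a patient censored early
counts as "alive" — and the Kaplan-Meier/log-rank stages are the only
time-aware components. Cox regression, time-dependent ROC and competing
risks are deliberate non-goals.

All reported AUCs are **in-sample**: each logistic model is fit and
evaluated on the same cohort. This matches the procedure being
reproduced but is optimistic, increasingly so for larger gene subsets;
artifacts are labeled `evaluation=in-sample`.

## Synthetic cohorts

The generator emulates a bulk tumor cohort with matched adjacent-normal
tissue:

* **Immune fractions.** Each patient belongs to one of `n_clusters`
  latent clusters (default 5, equal weights). Fractions over
  `n_celltypes` (default 22, named after the standard leukocyte
  deconvolution panel) are Dirichlet draws with concentration
  `fraction_concentration × profile` (default concentration 60, chosen
  so within-cluster spread is realistic but clusters remain separable).
  `plant_separable_clusters` builds profiles with mass `separation`
  (default 0.5) on one dominant cell type per cluster, giving pairwise
  L1 distance `2 × separation`; it errors when more clusters than cell
  types are requested.
* **Expression.** Log-normal around per-gene baselines (log-normal
  baseline, median 20 FPKM, log-sd 1.2); multiplicative noise
  `exp(σZ − σ²/2)` has unit mean so the tumor mean is exactly
  `baseline × FC` for planted fold changes (all ≥ 1, upregulated in
  tumor). Default noise σ = 0.6 on the log scale. Cluster marker genes
  (25 per cluster by default) receive an extra `exp(1.0)` tumor-mean
  shift in their cluster, giving the expression view a recoverable
  cluster structure aligned with the immune view.
* **Survival.** Exponential event times with per-patient hazard
  `baseline_hazard × cluster_multiplier × exp(Σ β_g z_g)`, where `z_g`
  is the patient's standardized log tumor expression of signal gene g.
  Defaults: baseline hazard 1e-4/day (≈ 31% ten-year mortality at
  multiplier 1), cluster multipliers (1, 1, 1, 2.5, 2.5) so the last
  two clusters are poor-prognosis, follow-up horizon 3 650 days.
  Censoring is independent exponential with rate tuned so the expected
  censored fraction matches `censor_rate` (default 0.3), plus
  administrative censoring at the horizon. The latent death probability
  `h/(h+c) · (1 − e^{−(h+c)τ})` is stored per patient as ground truth.
* **Planted gene structure (default study conditions).** Within the
  immune-regulatory block (first 25% of genes): five genes with large
  fold changes (50, 30, 25, 15, 10) *and* strong survival effects
  (β = 0.5 per SD) — high-index, prognostic genes; fifteen genes with
  FC 4 and moderate effects (β = 0.2); forty more genes with FC 4 only.
  A 63-gene positive-control analogue with weak effects (β = 0.1) sits
  outside the immune-regulatory block, and 365 structure-free genes are
  reserved as the negative-control pool. Effect sizes were set once from
  a power sketch: a β = 0.5 gene has a marginal AUC near 0.58 under the
  default hazard spread, five of them jointly separate pools clearly at
  2 000 draws, while β = 0.1 genes give the positive-control pool a
  benchmark distribution between candidate and noise.

What the generator does **not** emulate: deconvolution error structure
(fractions are drawn directly from the latent clusters), gene-gene
correlation beyond the planted cluster shifts, batch effects, or
non-proportional hazards. Tests passing on these cohorts therefore show
that the algorithms recover the structure they target, not that the
procedure is robust to real-data artifacts.

## Statistical primitives

Kaplan-Meier estimation and the k-sample log-rank test are delegated to
lifelines; Wilcoxon tests to scipy (signed-rank for matched pairs,
rank-sum otherwise; the paired test refuses all-zero differences). The
test suite re-derives all of them from definitions (product-limit
recursion, hypergeometric 2×2 accumulation, exact enumeration of sign
assignments, a permutation null) and checks exact agreement.

Logistic regression is a batched Newton (IRLS) solver written for this
package: the benchmarking and exhaustive stages fit on the order of a
million small models sharing one response vector, which rules out
per-model fitting through a general-purpose library on a single CPU.
Designs are stacked as (models × parameters × samples) so gathers stay
contiguous; converged models leave the working set each iteration.
Convergence is a gradient max-norm below 1e-6 (1e-10 for single fits,
where the suite verifies agreement with statsmodels to ~1e-7 and the
closed-form log-odds-ratio identity on 2×2 tables to 1e-6). AIC is
`2k − 2·loglik` with the unpenalized likelihood. Separation (any
coefficient beyond 40) triggers a refit with a fixed ridge penalty
(λ = 0.1, intercept unpenalized) and a `penalized` flag; AUC, the
quantity consumed downstream, is insensitive to the exact λ because it
depends only on the ranking of fitted probabilities. AUC is the
Mann-Whitney statistic with 0.5 credit for ties; its variance and the
paired two-model comparison use the DeLong structural components
(midrank formulation), with identical or monotonically related scores
giving p = 1 and a degenerate variance with unequal AUCs raising an
error.

## Immune-view stratification

`fit_gmm` selects the number of mixture components by BIC over k = 2..8
(10 restarts, fixed seed) or uses a fixed k. The default covariance
model is **diagonal** with 1e-6 regularization: a full covariance in 22
dimensions costs 253 parameters per component, and at a few hundred
samples BIC then collapses to too few components (measured: k = 3 and
ARI 0.61 on five separable planted clusters, versus k = 5 and ARI 1.0
with diagonal). Full covariance remains available.

**Cumulative-SD cutoff.** Samples are sorted descending (the long tail
first) and the SD of the first 3, 4, …, n samples is accumulated; the
trace is reported for prefixes 3..n. The cutoff is chosen among
prefixes 3..n−3 (both groups keep ≥ 3 samples). Two rules are
implemented. The default, `max_increase`, cuts at the largest
single-step rise of the trace: while the prefix stays inside the
homogeneous extreme group the SD is small, and the first bulk samples
produce the largest jump, so the rule recovers a planted two-component
boundary within ±1 rank. The literal `max_sd` rule (cut at the trace
maximum) is provided for comparison but overshoots by construction: for
a two-component mixture the prefix SD behaves like
`spread × √(p(1−p))` and keeps rising until the components are
balanced, so its argmax sits near twice the extreme-group size or at
the eligible-range cap, never at the boundary. Both the chosen rank and
the full trace are surfaced so users can audit edge cases; the cutoff
is scale-invariant (SD is homogeneous of degree 1).

**Per-cell-type screen.** Each cell type is dichotomized by the cutoff
and tested by two-group log-rank. A cell type is *excluded* (a result,
not an error) when > 90% of samples have fraction < 1e-4 or when either
stratum is smaller than `min_group` (default 10) — the numeric version
of an "insufficient data" rule. Direction is the sign of the difference
in KM median survival (high minus low). Under a survival-neutral
simulation the screen's false-positive rate is nominal (~5%), because
the cutoff depends only on the fractions, which are independent of
survival under the null.

## Expression-view stratification and the poor cohort

Expression clustering z-scores each gene (zero-variance genes dropped)
and projects onto the leading 20 principal components before the GMM —
a full-rank mixture in ~1 000 gene dimensions with a few hundred
samples is degenerate; 20 components retain the cluster structure the
procedure targets. Whether to standardize was treated as open; raw FPKM
scale would let high-abundance genes dominate, so standardization is
the default and a flag.

A cluster is **poor** when its KM median survival is below the cohort
median *and* its pairwise log-rank test against the best-surviving
cluster is significant at α (default 0.05) — an explicit rule replacing
the visual reading of KM curves. When medians are unreached (curves
above 0.5), restricted mean survival over the observed horizon
substitutes on both sides of the comparison. The poor-survival cohort
is the intersection of the poor strata of the two views; it is
invariant to cluster relabeling, never shrinks as α relaxes, and may be
legitimately empty (flagged, not an error). In the pipeline, if the
cohort provides fewer than six matched tumor/normal pairs, the index
and differential-expression stages fall back to all matched pairs with
a logged warning and a `cohort_fallback` flag in the artifact metadata.

## Gene index and shortlist

Fold change is the ratio of group means on the linear FPKM scale with
pseudocount 0.01 (the magnitudes of reference tables are only
consistent with linear ratios); the index is the exact product
`mean tumor expression × FC`, rounded to two decimals for display only.
Ranking is descending with alphabetical tie-break, stable and
idempotent. The shortlist rule cuts at the **last** rank within the top
`max_k` (default 10) whose consecutive-index ratio is ≥ `drop_ratio`
(default 1.3), falling back to `max_k`; "last" rather than "first"
because ranked index lists typically open with a large top-1/top-2
ratio, while the meaningful break is the final pronounced drop before
the list flattens. The applied rule and ratios are recorded in the
output. The tertile screen compares the top third against the bottom
third of expressers (group size ⌈n/3⌉, middle excluded, stable-sort
tie-breaks) by log-rank, plus a single-gene ROC over all samples.

## Panel construction

* **Differential expression:** two-sided paired Wilcoxon per gene over
  matched pairs, requiring p < α (raw by default, matching the
  procedure; Benjamini-Hochberg available) *and* mean tumor > mean
  normal. Genes with all-zero paired differences are reported with NA
  and never qualify.
* **Cell-type filter:** keep genes annotated (input table standing in
  for an immune-cell expression atlas) to at least one cell type that
  passed the survival screen; unannotated genes are dropped and
  reported. If no cell type passes, the pipeline filters against the
  full vocabulary with a warning.
* **Stepwise selection:** bidirectional from the null model; each step
  evaluates every single add/remove move (all same-size moves in one
  batched fit) and applies the best AIC improvement; stops when no move
  improves or after `max_steps` (default 100). Ties resolve
  alphabetically, making the search deterministic given the input; a
  p-value entry/removal variant (LR tests, p_enter 0.05 / p_remove
  0.10) is provided as an alternative criterion.
* **Benchmarking:** `n_draws` uniform k-subsets (without replacement
  within a draw, repeats across draws allowed; k default 20) from each
  of the candidate, positive-control and negative-control pools; one
  logistic fit and in-sample AUC per draw; reproducible per seed. When
  the smallest pool is below 2k the pipeline samples about half the
  pool instead (≥ 2), echoing the 20-of-87 proportion — otherwise a
  pool equal to k makes every draw identical and the distribution
  degenerate.
* **Frequency profiling:** count each gene's appearances among
  combinations with AUC above a threshold (pipeline default: the mean
  of the positive-control pool's AUC distribution, the natural
  benchmark summary when only a benchmark level is specified); top-m
  (default 20) by count, ties by the mean AUC of containing
  combinations, then alphabetically. No qualifying combination is an
  error suggesting a lower threshold.
* **Exhaustive search:** every non-empty subset of the top genes,
  hard-capped at 20 genes (1 048 575 models, about three minutes on one
  CPU with the batched solver); the winner is the maximum in-sample
  AUC, exact ties resolving to the smaller subset, then alphabetically.
  Leave-one-out refits each (k−1)-subset of the winning panel;
  `delta = panel AUC − reduced AUC` ranks gene contributions, and every
  reduced AUC is bounded by the panel AUC by construction of the
  maximum.

## Problem sizes used in the checks

The validation suite runs the full procedure at n = 300 patients,
2 000 genes and 10 000 draws per pool — a deliberate scale-down of the
source-scale setting (hundreds of patients, ~20 000 genes, 10⁶ draws)
that preserves every stage's statistical behavior while keeping a
complete run near ten seconds; 10⁶ draws and the full 2²⁰ exhaustive
search remain available through configuration. Pool-ordering and
frequency-recovery checks use 2 000 draws; oracle checks use 100 random
small instances each.

## Known limitations

* In-sample AUC overstates out-of-sample performance; the optional
  stratified k-fold evaluation is off by default to match the procedure
  being reproduced.
* The alive/dead dichotomy ignores follow-up length; cohorts with short
  follow-up will mislabel eventual deaths as "alive".
* The cumulative-SD cutoff is a heuristic: on unimodal data the largest
  SD rise often isolates a small extreme tail, and the screen's
  `min_group` exclusion is the guard against degenerate strata.
* Multiplicity is uncorrected by default throughout (per the procedure);
  the differential-expression stage exposes an FDR switch.
* The synthetic generator's independence assumptions (genes independent
  given cluster; censoring independent of covariates) make recovery
  tests necessary but not sufficient evidence for real-data behavior.
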