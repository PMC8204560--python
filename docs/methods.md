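# Methods

## Scope and data model

`omsurv` operates on a single sample-aligned table: a samples × features
numeric matrix (each feature tagged with an omics block: gene, methyl,
mirna, clinical, other), a non-negative survival time per sample, a binary
event indicator (1 = event observed, 0 = censored), and optional categorical
clinical columns. Time is treated as unitless; all horizons (default 6 and
12) must be expressed in the same unit as the time column. The train/test
split is simple random sampling with |train| = round(fraction·n),
round-half-away-from-zero, default fraction 0.7; event-stratified sampling
is an opt-in flag. All randomness in the package flows from explicit integer
seeds.

## Preprocessing

Three operations, in fixed order, with every statistic fitted on the
training partition only and re-applied unchanged to test data (no
test-set leakage into imputation or scaling):

1. **Outlier elimination** — value-level flagging to missing, not sample
   removal, so it composes with imputation. A value is flagged when its
   leave-one-out z-score exceeds the threshold (default 4): it is compared
   against the mean and population sd of the *remaining* observed values of
   its feature. The leave-one-out form matters in small samples, where a
   gross outlier inflates the all-sample sd enough to mask itself (the
   all-sample |z| is bounded by ~sqrt(n−1)); for large n the two rules
   coincide. Constant features are never flagged.
2. **Imputation** — per-feature mean or median (default median) of the
   observed training values; an all-missing feature is an error naming the
   feature.
3. **Scaling** — standardization (x−mean)/sd with population (divide-by-n)
   sd, or min-max to [0,1]; constant features map to 0 under both rather
   than erroring, since high-dimensional omics blocks routinely contain
   constants after filtering.

## Survival-statistics kernel

All estimators are implemented directly in `omsurv.survstat`:

- **Kaplan–Meier**: product-limit over distinct event times; censored-only
  data yields S ≡ 1.
- **Log-rank**: k-group chi-square with df = k−1 from the pooled
  observed-minus-expected vector and its hypergeometric covariance
  (generalized inverse on the first k−1 groups); zero total events returns
  statistic 0, p = 1.
- **Cox fitting**: Newton–Raphson on the Efron-approximation partial
  likelihood (Efron chosen as the safer default for omics data with tied
  times; suffix-cumulative-sum evaluation makes each likelihood pass
  O(n·p²)). Convergence at gradient max-norm < 1e-8, iteration cap 100,
  step halving on likelihood decrease with an acceptance tolerance
  *relative* to |loglik| (an absolute tolerance stalls on float-plateau
  noise when |loglik| is large). Standard errors from the inverse observed
  information; p-values are Wald. Zero-variance covariates are held at
  β = 0 with p = 1 so genome-wide screens never abort.
- **L1 (Lasso-Cox)**: glmnet-scale objective ℓ(β)/n − λΣ|β|, solved by
  proximal Newton: quadratic expansion at the current iterate, inner
  coordinate descent with soft thresholding. λ_max = max|∇ℓ(0)|/n is the
  smallest all-zero penalty; paths are warm-started along a log-spaced grid
  (50 points, down to 1e-2·λ_max by default).
- **Breslow baseline**: H₀(t) = Σ_{tᵢ≤t} dᵢ / Σ_{risk} exp(β·x); with β = 0
  this reduces exactly to Nelson–Aalen.
- **Concordance**: Harrell's c over comparable pairs (shorter time must
  have the event; time-tied event/censored pairs comparable, event/event
  not); tied scores count 1/2.
- **tdROC**: cumulative/dynamic estimator at a horizon t — cases have an
  observed event by t, controls are event-free past t — with
  inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
  the censoring distribution (cases weighted by 1/G(Tᵢ⁻), controls by
  1/G(t)). With no censoring this is exactly the binary ROC for the label
  "event by t". AUC by trapezoid. The estimator variant is a package
  choice and is isolated behind `td_roc` so it can be swapped.
- **Calibration**: equal-frequency bins of predicted survival; observed
  value is within-bin KM at the horizon, NaN-flagged when the bin's KM does
  not reach the horizon; identical predictions collapse to one bin.

## Feature selection

Five screens plus a chaining engine that applies each screen to the
survivors of the previous one and records a full trace (method, parameters,
per-feature statistics, kept/dropped). Sizes are non-increasing along the
chain; a screen that empties the feature set stops the chain with an
explicit `empty_result` status.

- **Correlation (redundancy) filter** — between-feature, not
  feature-vs-outcome: among each pair with |Pearson r| above the threshold
  (default 0.7) the lower-variance member is dropped, greedily in
  descending-|r| order, so no surviving pair exceeds the threshold. This
  reading (rather than correlation with outcome) is consistent with a
  redundancy-pruning step that retains most of a genome-scale feature set;
  dropped features record their retained partner.
- **Univariate Cox** — one single-feature fit per feature; keep Wald
  p < α (default 0.05). Per-feature fit failures are warnings, not fatal.
- **Log-rank screen** — each continuous feature dichotomized at its median
  (the field convention for putting a continuous marker into a log-rank
  test), 2-group test, keep p < α; degenerate splits drop the feature with
  a warning.
- **Multivariate Cox** — one joint fit over all current features; requires
  #features < #events (otherwise the error directs users to run a
  single-factor screen first); rank-deficient designs error naming the
  collinear features.
- **Lasso-Cox** — λ chosen by 5-fold event-stratified cross-validated
  partial likelihood (Verweij–Van Houwelingen: ℓ_full(β_k) − ℓ_train(β_k)),
  rule `cv_min` (default) or `cv_1se`, or a fixed λ; survivors are the
  nonzero coefficients.

No multiple-testing correction is applied by default (the worked thresholds
are raw p < 0.05); Benjamini–Hochberg can be layered on the exported
per-feature p-values.

## Risk assessment

The radscore is Σⱼ βⱼxᵢⱼ from a multivariate Cox fit on the selected
features. Covariates are mean-centered before Breslow baseline estimation so
H₀ refers to the average sample, making survival prediction and nomogram
anchoring well-defined: S(t|x) = exp(−H₀(t))^exp(β·(x−x̄)). Horizons default
to {6, 12} time units, primary 6; a horizon beyond the last baseline step
returns the last-step value with a warning.

The nomogram assigns points_j(x) = 100·|βⱼ|·|x−xⱼ⁰| / max_k(|β_k|·range_k),
with xⱼ⁰ the lowest-risk end of feature j's observed range, so the feature
with the largest |β|·range spans exactly 0–100 and total points are an
increasing affine function of the radscore; total points map to survival
probability per horizon through the same baseline. Cross-validated
evaluation pools out-of-fold radscores from event-stratified folds and
reports pooled c-index and tdROC AUC (per-fold values where defined).

## Subtyping and group survival

KMeans (k-means++/Lloyd, best of 10 restarts by within-cluster sum of
squares, deterministic per seed) on the selected-feature matrix; clustering,
silhouette and AMI are delegated to scikit-learn behind thin wrappers that
fix the package conventions: labels are 1-based, and AMI involving any
zero-entropy (constant) labeling is 0 by convention (avoiding the 0/0
indeterminacy; note this overrides the library's value of 1.0 for two
constant labelings). Model order is searched over k = 3..9: silhouette for
unlabeled data, AMI against a provided stage label otherwise; argmax with
ties broken toward the smallest k; user mode bypasses the search
(default k = 3). The stage label is used only to score k, never to
constrain the clustering itself.

Group survival comparison produces per-group KM curves, the overall k-group
log-rank test, and pairwise hazard ratios from separate 2-group Cox fits on
a group indicator (keeping every pair's reference explicit) with 95% Wald
CIs exp(β ± 1.96·SE); pairs involving an eventless group are NaN-flagged
rather than fatal. The at-risk timeline counts samples still under
observation at 10 equally spaced times from 0 to the maximum observed time.
A user-vs-system comparison clusters twice (system-selected k and the
user's k) and reports both log-rank p-values plus the AMI between the two
labelings.

## Synthetic cohorts

The generator emulates the shape of a TCGA-style multi-omics input.
Features are standard normal with optional exchangeable within-block
correlation and per-subtype mean shifts on a subset of features; event
times follow h(t|x) = h₀(t)exp(β·x) with an exponential or Weibull baseline,
drawn by inverting the closed-form cumulative hazard (exact, hence testable
against analytic survival curves); censoring is independent exponential
and/or an administrative cutoff; missing values and outliers are injected
*after* survival generation so the planted β is unaffected. Defaults
describe the cohort used in the package's own calibration suites: n = 300,
200 features in three blocks, 5 prognostic features with |β| = 1 and
alternating sign on standardized features, exponential baseline rate 0.05
(mean 20 time units), censoring rate 0.02 (roughly 30% censored), 3
subtypes with unit mean shift.

What the generator does **not** emulate: realistic omics covariance beyond
the single exchangeable-ρ block parameter, non-proportional hazards,
informative censoring, batch effects, or heavy-tailed expression
distributions. Passing calibration tests therefore demonstrates correctness
of the estimators under the proportional-hazards model, not robustness to
real-data violations of it.

## Pipeline, determinism and problem sizes

The driver executes load/split → preprocess → feature selection → risk
assessment → clustering → survival analysis, persists every stage's outputs
(CSV/JSON/PNG) under the run directory, and writes `report.json` (canonical)
plus `report.md`. A stage failure is recorded and stops the pipeline after
the report is written; persisted artifacts are sufficient to resume any
later stage (`--from-stage`), which replaces interactive undo. Identical
config + seed gives content-identical CSV/JSON outputs (timestamp fields
aside) — this is asserted by test and by the acceptance script.

Simulation sizes used by the test and acceptance suites, chosen to give
each check at least ~3.5σ of resolution while staying desk-scale: type-I
calibration with 500 null features at n = 300 (99% binomial band around
α = 0.05); planted recovery with 5 signals among 200 features, n = 300, 5
seeds; null discrimination at n = 400, 3 seeds; β recovery at n = 200 vs
2000 (3 replicates each); two-group HR = 2 recovery at 500 per group with
light (10%) censoring, 3 seeds — light censoring keeps the log-HR standard
error near 0.065 so the stated recovery band is a >3.5σ check; the
full-pipeline example at n = 200 with 100 features.

## Known limitations

- No time-varying covariates, stratified Cox, interval censoring, or
  proportionality diagnostics.
- The log-rank screen's median split discards within-half information; it
  is a screen, not an effect estimate.
- The nomogram's point system is this package's definition (documented
  above); other charting conventions scale points differently.
- The Lasso path uses the diagonal-free proximal-Newton scheme described
  above; for extremely correlated designs the CV curve can be flat near its
  maximum, and `cv_1se` is then the more stable rule.
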