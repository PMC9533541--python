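# Methods

## Model and pipeline

The core model is the Cox proportional-hazards model
h(t | x) = h0(t) · exp(βᵀx) fitted to per-patient gene expression x
(standardized log2-CPM) with a right-censored outcome (time, event). All
partial likelihoods use the **Breslow** tie convention — tied event times
share the risk-set denominator — consistently across the unpenalized
Newton fitter, the single-gene scan, the penalized coordinate-descent
engine, the baseline-hazard estimator and the Schoenfeld residuals. Efron
ties, stratified and time-varying models are out of scope.

The evaluation pipeline treats every data-dependent quantity as part of the
model: within each cross-validation split, the expressed-gene filter
(CPM > 1 in at least ⌈1% · n⌉ of patients; "at least 1%" is rounded up),
per-gene standardization parameters, the screening statistics (single-gene
p-values, VST IQRs) and the penalty strength λ are computed on the training
fold only and then frozen. This is enforced structurally — the training
artifacts are produced by a function that never receives test rows — and
verified by a corruption test.

## Preprocessing choices

* **log2-CPM pseudo-count = 1**: maps zero counts to exactly 0 and keeps the
  transform monotone. CPM uses library sizes of the full (filtered) count
  matrix.
* **VST**: median-of-ratios size factors; per-gene method-of-moments
  dispersions α̂ = (s² − μ̂)/μ̂² regressed on 1/μ̂ to get the trend
  α(μ) = a0 + a1/μ (coefficients clipped non-negative, a0 floored at 1e-8);
  closed-form transform f(q) = (2/√a0)·asinh(√(a0·q/(1+a1))), whose
  derivative is 1/√Var(q) under that trend. The (1+a1) factor matters: the
  NB variance is (1+a1)·μ + a0·μ², and omitting it leaves a residual
  negative median-IQR trend at low counts. With a0 → 0 and a1 = 0 the
  transform reduces to the Poisson square-root limit 2√q. This is a
  deterministic two-parameter analog of spline-based VSTs; it is chosen for
  reproducibility, and its adequacy is measured by the property it exists
  for (|Spearman(median, IQR)| ≤ 0.3 on simulated NB data, far below the
  log2-CPM value).
* **Standardization**: per-gene, with training-fold mean/SD applied to both
  folds (CV convention) or with the test set's own statistics
  (external-cohort convention, for cross-study transfer where location and
  scale are not comparable). Zero-SD genes are scaled by 1 and flagged
  rather than erroring — screening removes them downstream.

## Cox fitting

* Unpenalized (small p): Newton-Raphson with step-halving on the partial
  likelihood; convergence |Δl| < 1e-9 or 25 iterations. Monotone likelihood
  (divergence) is detected at |β| > 20: the coefficient is capped and the
  fit flagged, never raised — a 20,000-gene scan must survive separable
  genes. The capped likelihood still yields a valid, conservative LRT
  p-value. Failed single-gene fits get the sentinel p = 1 so the screen
  stays total-ordered.
* Single-gene scan: one-covariate Newton iterations vectorized across all
  genes simultaneously (risk-set sums via reverse cumulative sums), with
  per-gene step-halving.
* Penalized: glmnet-style outer IRLS on the Breslow likelihood (objective
  l(β)/n − penalty) with cyclic coordinate descent inside
  (soft-thresholding for ℓ1, closed-form ℓ2 shrinkage, firm-threshold rules
  for MCP γ=3 / SCAD γ=3.7). Inner CD tolerance 1e-7 on the max coefficient
  change, capped at 200 sweeps with an active-set strategy. For convex
  penalties the outer loop runs until the exact-score KKT conditions hold
  at 1e-4 (checked every iteration from the true partial-likelihood
  gradient), so "converged" means verifiable stationarity, not just small
  steps. Ridge is fitted as the elastic net at α = 0 (penalty λ/2·‖β‖²),
  making the α ∈ [0, 1] family continuous; λ is rescaled freely by CV so
  the factor-of-two convention is immaterial. α defaults to 0.5 for EN/AEN
  and is configurable.
* λ path: λ_max = max_j |∇_j l(0)/n / w_j| / max(α, 1e-3), 100 log-spaced
  values down to 0.01·λ_max. λ is selected by minimizing the
  cross-validated partial-likelihood deviance
  −2·[l_full(β̂₋k) − l₋k(β̂₋k)] over event-stratified inner folds; ties go
  to the larger λ (sparser model). During CV, fold paths are truncated once
  the active set exceeds the fold's event count — the saturated tail never
  wins the deviance comparison and is the expensive part of the path; the
  deviance minimum is taken over the λ prefix fitted by every fold.
* Adaptive elastic net: two-step — CV-selected ridge, then weights
  w_j = 1/|β⁰_j| capped at 1e6 below |β⁰_j| < 1e-6, then weighted EN.

## Screening

* IQR uses linear interpolation between order statistics (the numpy
  default), fixed because thresholds are compared across runs.
* Bi-dimensional screen: mask = (p_adj ≤ p_thr) AND (iqr ≥ iqr_thr);
  (1, 0) disables both screens and is the no-screening reference cell of
  every grid.
* Top-k: k smallest raw p-values; boundary ties broken by larger |β̂|, then
  lexicographic gene id (deterministic).
* Correlation pre-filter: greedy pass in ascending-p order, accepting a
  gene iff |Pearson r| ≤ 0.5 against every accepted gene.
* SIS ranks genes by single-variable |β̂| with d = ⌊n/log n⌋ computed on the
  training-fold n (screening must live inside CV). ISIS alternates a lasso
  refinement with re-admission of excluded genes by their *conditional
  contribution*, implemented as a single-variable Cox fit with the current
  prognostic index as a fixed offset (the published algorithm family leaves
  this operationalization open). At most 5 outer iterations; on
  non-convergence d falls back to d/2 then d/4, and the last iterate is
  returned flagged if that still fails.

## Metrics

* C-index over comparable pairs: the pair (i, j) is comparable iff the
  times differ and the shorter time is an observed event; PI ties count
  1/2; pairs with tied times are excluded. Zero comparable pairs yield an
  explicitly undefined value (NaN + flag), never a silent 0.5.
* Brier score at t with IPCW: events before t weighted by 1/Ĝ(T⁻),
  patients at risk past t by 1/Ĝ(t), censored-before-t patients weight 0;
  Ĝ is the Kaplan-Meier estimator of the censoring distribution computed on
  the **test** split (the alternative train-based Ĝ is a known variant);
  weights are truncated at the last positive Ĝ value.
* IBS: trapezoidal integral of BS(t) over {0} ∪ {test event times} ∪
  {t_max}, divided by t_max = the largest observed test event time.
* Condition comparisons: one-sided Wilcoxon signed-rank on the 50 paired
  per-split values (zeros discarded; exact null for small n, normal
  approximation with continuity correction otherwise; all-zero differences
  give p = 1), BH-corrected across a family. The dataset-inclusion rule is
  a one-sample one-sided Wilcoxon of the C-indices against 0.6 at level
  0.01.

## Cross-validation design

Folds are stratified by event status (high-censoring cohorts would
otherwise produce event-free folds) and re-drawn, with a shifted stream,
if a fold still lacks test events or leaves the training side event-poor.
All 36 grid cells share the same fold partitions so cells can be compared
with *paired* tests; whether the original procedure shared partitions is
not documented, and the shared design is this package's choice. The nested
phase derives a fresh seed stream (offset 500009) so its partitions are
independent of the grid search. Optimal thresholds are learned per metric
and both optima are reported; grid ties break toward fewer kept genes,
then the stricter p-threshold.

## Synthetic cohorts

The generator emulates the features of a bulk RNA-seq survival cohort that
the pipeline is sensitive to, not any particular tumor biology:

* gene means log-uniform on [1, 1e4] (spans low/high expressors, which is
  what makes the VST necessary);
* NB counts with variance μ + a0·μ² + a1·μ, defaults a0 = 0.15, a1 = 0.5
  (typical bulk overdispersion); block-correlated genes via a Gaussian
  copula, defaults block_size = 10, block_rho = 0.5 (correlated gene
  programs);
* survival from the Cox-Weibull model T = (−log U · exp(−βᵀx)/r)^(1/s);
  defaults n = 526 patients, 68 causal genes, coefficient SD σ = 0.2,
  target censoring 0.67 — the geometry of a typical large clear-cell
  renal-cell carcinoma cohort — with Weibull baseline r = 1, s = 1.5
  (increasing hazard, a package default) and p defaulting to a desk-scale
  1000 genes;
* βᵀx is computed on standardized log2-CPM values, the same scale the
  downstream Cox models fit on, so σ is interpretable as a standardized
  log-hazard ratio (whether the original simulation standardized before
  forming βᵀx is not documented; this is a package decision);
* θ is calibrated empirically: the expected censored fraction
  mean_i min(T_i, θ)/θ is monotone in θ and solved by bracketed
  root-finding to 1e-3 on the rate; target 0 returns a no-censoring
  sentinel; ties T = C count as events (measure-zero, fixed for
  determinism).

What the generator does **not** emulate: tumor purity and subtype mixtures,
batch effects, count outliers/zero inflation beyond NB, and the empirical
correlation structure of any real cancer. Passing tests therefore show the
pipeline's statistical machinery is correct and well-calibrated under its
own assumptions, not that a particular cancer attains a particular
C-index.

One seed determines everything; named sub-streams (expression,
coefficients, survival, censoring, folds, inner CV) are spawned from it so
stages are independently reproducible.

## Problem sizes used in the test and acceptance runs

Simulated cohorts are run at desk scale, chosen once: null-calibration at
n = 300 × p = 2000; screening monotonicity at n = 500 × p = 2000; parameter
recovery at n = 500, p = 1000, 20 causal genes with |β| ≥ 0.3 (Normal(0,
0.2) draws resampled past the floor); the screening-benefit study on three
cohorts of n = 220, p = 400, 20 causal genes, σ = 0.35, censoring 0.5,
with a 2-repetition grid phase and a 10×5-fold nested phase, elastic-net
penalty, 30-value λ paths and 3-fold inner CV. The censoring-calibration
run uses the full reference geometry (n = 526, 68 causal, σ = 0.2, target
0.67).

## Known limitations

* The Schoenfeld proportional-hazards test uses the identity time
  transform and evaluates residuals at a supplied (possibly penalized)
  coefficient vector treated as fixed; how a p ≫ n penalized fit should
  aggregate into one global test is not settled, and the operation simply
  supports any fixed β.
* MCP/SCAD share the coordinate-descent engine via firm thresholding (no
  local-linear-approximation variant) and carry no KKT certificate
  (non-convex); they are off the default benchmark path.
* The correlation pre-filter is greedy, not optimal set selection.
* The IQR can discard a gene expressed in fewer than 25% of patients even
  when it is prognostic; a wider quantile spread (e.g. 90th–10th) is a
  natural extension hook, not implemented.
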