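# Methods

`rehabfuse` re-implements, as a tested pipeline, an approach to predicting
post-treatment upper-limb movement quality — Functional Ability Scale (FAS)
scores on Wolf Motor Function Test (WMFT) tasks — in stroke and traumatic
brain injury survivors, from (a) wearable accelerometer recordings, (b)
six baseline clinical covariates, and (c) a covariate-conditioned
constrained linear fusion of the two estimates. Because no raw cohort data
are publicly available, a synthetic-data module generates cohorts and
recordings with the statistical structure the analysis assumes; every
empirical statement below is computed by the test suite or by
`scripts/acceptance.py`, not quoted from elsewhere.

## Score model

Clinicians rate each task repetition 0–5. Per visit, repetition scores are
averaged per task, the eight task means are summed (`FAS_8Tasks` ∈ [0,40]),
and the total is mapped to full-battery points by the affine calibration

    FAS_total_points = FAS_8Tasks × 1.78 + 2.97,

expressed as a percentage of the 75-point full scale (15 tasks × 5) and
clipped to [0, 100]. The mapping is strictly increasing and affine on its
domain; its inverse (used by the generator to derive per-task scores from a
target total) clips to the valid range.

## Synthetic cohorts

`CohortConfig` defaults define the study conditions:

- Covariates: age ~ N(45, 16²) yr truncated to [18, 80]; chronicity
  ~ lognormal(median ≈ 245 d, log-SD 1.0); treatment length ~ N(45, 15²) d;
  sessions ~ round(N(20, 8²)); baseline FMA-UE ~ N(35, 10²) truncated to
  the eligibility window [15, 55]; baseline total FAS ~ N(60.5, 15.2²) %
  (the two diagnostic groups are generated identically — group label has no
  generative effect, matching the absence of group differences in the
  setting modelled).
- True response: ΔFAS = 15 + 5·z(sessions) − 3·z(log chronicity) +
  2·z(FMA) − 3·z(FAS₀) − 1·z(age) + 1·z(treatment length) + ε, in
  %-points, with z(·) standardized by the configured moments. ε is a
  responder mixture: with probability 0.35, N(+4, 8²), else N(−2.15, 6²)
  (mean ≈ 0). The linear part contributes variance 49 and the mixture
  ≈ 54.5, so a linear model on the six covariates explains R² ≈ 0.47 of
  the true change — clinical information is predictive but incomplete,
  which is the regime the fusion method targets. A property test checks
  R² ∈ [0.2, 0.6] on a 2000-subject cohort.
- Rater labels: observed = clip(true + N(0, (2.5 % of 5)²), 0, 5) per
  repetition — 2.5 % repetition variability on the 5-point scale.
- Per-task true scores: the subject's total percentage is inverted through
  the score mapping, divided across the eight tasks, jittered with
  SD 0.15 points and clipped, so task-level and total-level scores stay
  approximately consistent (mirroring real rating data).

## Synthetic recordings

Five sensors (sternum, arm, wrist: 3-axis; thumb, index: 2-axis, simulated
by projecting 3-D acceleration onto two axes) sampled at 51.2 Hz. With
per-task impairment q = (5 − s)/5:

- Hand transport is an analytic minimum-jerk reach, x(τ) = D(10τ³ − 15τ⁴ +
  6τ⁵) with D = 0.35 m, differentiated in closed form to acceleration;
  duration T = T₀(1 + 1.5 q) with T₀ ≈ 1 s (small fixed per-task spread).
- Corrective submovements: Poisson(4 q) scaled minimum-jerk pulses
  (~0.25 s, ±25 % of the main peak) at random onsets.
- Tremor: 4–10 Hz band-limited noise, RMS 0.5 q m/s², on all moving
  sensors; a 0.02 m/s² noise floor on every channel avoids degenerate
  constant series.
- Trunk compensation: the sternum carries a slow minimum-jerk "lean"
  with amplitude ∝ 0.6 q plus attenuated tremor.
- Manipulation tasks concatenate three phases (reach, manipulate at 1.3 T,
  return) and carry a binary touch channel with exactly one contact
  interval strictly inside the middle phase; reaching tasks are a single
  phase without touch.

By construction, movement duration and jerk RMS increase monotonically
with q (checked over 20 seeds), so speed/smoothness/coordination features
are informative. All kinematic constants are artifact choices exposed in
`RecordingConfig` — the modelled study does not publish a generative
model. The generator does **not** emulate gravity components, sensor
orientation drift, spasticity-specific waveforms, or rater idiosyncrasies
beyond i.i.d. Gaussian noise; passing tests therefore demonstrate pipeline
correctness under the stated statistical structure, not clinical-grade
accuracy on real recordings (the synthetic sensor errors come out much
smaller than published real-data errors).

## Signal chain

Per axis: 6th-order Butterworth low-pass at 8 Hz; velocity and
displacement by cumulative trapezoid integration, each integration
followed by a 6th-order 0.25 Hz high-pass to remove integration drift
(displacement = two integrations with a drift high-pass after each — an
interpretation, flagged here, since only "high-pass after integrating" is
specified upstream); jerk by central finite differences. Filters are
applied forward–backward (zero-phase) by default so segment-aligned
features are not lag-distorted; the effective magnitude response is the
squared design response, and a config flag selects a causal single pass.
Filters run as second-order sections for stability at the 0.25 Hz/51.2 Hz
normalized cutoff. Magnitude series are per-sample Euclidean norms.
Touch-based segmentation merges contact gaps shorter than a 100 ms
debounce window and errors loudly (naming the recording) when no contact
exists. Series shorter than the zero-phase warm-up raise an explicit
error.

## Features and selection

Per magnitude series (5 sensors × displacement/velocity/acceleration/jerk):
min, max, mean, RMS, dominant-frequency ratio (periodogram peak power over
total power, DC excluded, computed on the mean-removed series), skewness,
excess kurtosis, and Shannon entropy of a 16-bin amplitude histogram
(bits). Degenerate zero-variance series return 0 for
skewness/kurtosis/entropy/dominant-frequency by convention. Ten pairwise
Spearman correlations (tie-corrected, average ranks) between the sensor
acceleration magnitudes capture inter-segment coordination and trunk
compensation. Reaching tasks yield one whole-task block plus duration
(171 features with the default registry); manipulation tasks yield one
block per movement component plus three durations (513). The registry is
data-driven, so counts follow the configuration rather than being
hard-coded.

Feature selection is CFS: merit M(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff) with
mean absolute Pearson correlations, best-first search with a stall limit
of 5 expansions and (on large pools) a 50-child beam per expansion;
exhaustive search is available for ≤ 15 candidates and best-first stays
within 1 % of the exhaustive optimum on such pools (tested). Selection is
fit on training folds only.

## Gaussian process regression

Squared-exponential kernel with isotropic length-scale on standardized
inputs, additive noise, targets mean-centered (prior mean = training
mean). Hyperparameters maximize the log marginal likelihood plus weak
log-normal hyperpriors (SD 2.0 in log space, centered on a data heuristic:
σ_f = SD(y), ℓ = median pairwise distance, σ_n = 0.1·SD(y)) — a MAP
estimate suited to small training sets; a config switch disables the
priors, and multi-start L-BFGS-B (analytic gradients, log
parameterization) is seeded and deterministic. Cholesky factorization
escalates jitter 1e-10 → 1e-6 before failing. Predictive variances
include the noise term by default (they feed the variance-weighting
benchmark and interval-coverage checks, both of which concern noisy
observations). ARD and per-task rounding are deliberately omitted:
standardized inputs justify isotropy, and continuous 0–5 predictions are
carried forward (clipped to the scale) rather than rounded to the ordinal
grid.

Two diagnostics anchor correctness: exact agreement (≤ 1e-8) with the
hand-computed two-point posterior, and 95 % predictive-interval coverage
within [88 %, 99 %] on draws from a known squared-exponential GP.

## Fusion by constrained quadratic programming

The fused estimate is ŷ = ω_c ŷ_c + (1 − ω_c) ŷ_s with ω_c,i = x_c,i·θ a
linear function of the normalized covariates. With A = X_c row-scaled by
(ŷ_c − ŷ_s) and b = y − ŷ_s, the training objective J(θ) = θᵀAᵀAθ − 2bᵀAθ
(= ‖b − Aθ‖² − ‖b‖²) is minimized subject to 0 ≤ X_cθ ≤ 1 (θ = 0 always
feasible). The QP is solved with a trust-region interior-point method
(analytic gradient and Hessian, tiny ridge 1e-8 for degenerate AᵀA),
followed by an active-set KKT polish on the near-active box faces — the
polish recovers boundary optima to ≤ 1e-6 of a 1e-3-step grid oracle —
and a final guard that never returns anything worse than θ = 0.
Constraints hold at θ* to 1e-8. Test-time weights are clipped to [0, 1]
(the printed constraint binds only training rows; unclipped test weights
could leave the convex hull — a documented deviation). No intercept
column by default (the published weight form has none); a flag appends
one.

A structural note discovered during implementation: if the covariate
columns are *exactly* mean-centered on the QP's own training rows, then
Σᵢ (X_cθ)ᵢ = 0, and the elementwise constraint 0 ≤ X_cθ ≤ 1 forces
X_cθ = 0 — generically (n > m) θ* = 0 and the fused estimator collapses
to the sensor-only estimator. The pipeline implements the constraint
exactly as specified and so reports θ* ≈ 0 and ω_c ≈ 0 on the LOSOCV
cohort; nonzero fusion weights require either uncentered covariates or an
intercept. The weight-recovery benchmark therefore plants θ on covariates
with positive means (ω ∈ [0.2, 0.65]), the only regime where a nonzero
planted weight function is feasible, and recovers fused predictions with
R² ≥ 0.98 at noise SD 0.5 points.

Benchmark combiners: equal weights (ω_c = 0.5); variance weighting with
both conventions — `as_printed` (ω_c = V_c/(V_c+V_s), faithful to the
published formula, which up-weights the *more* uncertain estimate) and
`inverse_variance` (the standard precision weighting); the default stays
`as_printed` because the ambiguity cannot be resolved from the text. The
oracle "upper bound" picks, per subject, the estimate closer to the
clinician score, with ties going to the sensor estimate; it dominates any
convex blend per subject only where both estimates err on the same side
of the truth, which the property test asserts on exactly that subset.

## Evaluation protocol

Leave-one-subject-out: each fold excludes the held-out subject's baseline
*and* post recordings from sensor training (the stricter reading; a flag
re-admits the baseline recordings), while the subject's observed baseline
FAS still serves as a clinical covariate. Within a fold: per-task CFS +
GPR on the training subjects' baseline+post repetitions; a clinical GPR
on the six covariates predicting the FAS *change*, added to the observed
baseline. Out-of-fold training estimates (ŷ_c, ŷ_s) for fitting θ come
from an exact inner leave-one-subject-out: closed-form leave-block-out GP
posteriors, μ_B = y_B − (K⁻¹)_BB⁻¹(K⁻¹(y − m))_B and Cov_B = (K⁻¹)_BB⁻¹,
with hyperparameters and the CFS subset fixed at the fold-level fit. This
is the exact inner LOO of the posterior given the fitted model, at a tiny
fraction of the cost of refitting hyperparameters per inner fold; an
in-fold option exists for comparison. Fold seeds derive from the global
seed via `SeedSequence`, making reports byte-identical across reruns.

Metrics: RMSE, Pearson r with Fisher-z 95 % CI (the upstream CI method is
unstated, so CI values are descriptive only), bias = mean(ŷ − y), and the
error SD in the population convention so RMSE² = bias² + SD² exactly.
Error-vs-change diagnostics regress (ŷ − y) on the true change with a
slope CI; group comparisons use Welch's unpaired t-test (pooled-variance
was not specified upstream; Welch is the safer default). FAS percentages
are clipped at 100 before metrics (the natural scale bound).

## Problem sizes and numerical choices

The cohort-level checks use the default n = 40 cohort, 8 tasks × 3
repetitions × 2 visits (1 920 recordings per seed): 5 seeds for the RMSE
ordering check and 10 for the error-vs-change pattern, sharing one batch.
Sensor GPRs use a single heuristic-start optimization (40 L-BFGS-B
iterations) — adequate on standardized CFS-selected features — and the
clinical GPR uses two extra restarts. CFS caps subsets at 20 features.
QP-vs-oracle uses 100 instances (half m = 1, half m = 2) with a coarse
polygon-localization pass before the 1e-3 grid and a 1e-5 local
refinement. Interval coverage pools 10 × 100 held-out points.

## Known limitations

- The published per-feature enumeration (357/1 035 features) lives in an
  unavailable supplement; the default registry reports 171/513 and counts
  are configuration-dependent, not reproduction targets.
- Cohort-specific published results (e.g. RMSE/r per method) are not
  reproducible without the original recordings; the cohort-level tests
  check the qualitative pattern (method ordering, error-vs-change
  asymmetry), not the printed numbers.
- One GPR per task (rather than a shared model with task indicators) is
  an interpretation of the per-task estimation description.
- The sensor-based estimates on synthetic data are substantially more
  accurate than published real-data estimates because the generator's
  impairment signal is clean; the ordering of methods, not the error
  magnitude, is the transferable result.
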