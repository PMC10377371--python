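# Methods

This note documents the models, estimators and numerical choices behind
`icgperf`, and what the synthetic study conditions do and do not show about
real intraoperative data.

## Curve model and kinetic parameters

A bolus of ICG reaching a tissue region produces a time–intensity curve that
is flat at a dark baseline, rises to a maximum as the dye transits the local
vasculature, and then stays bright while the dye recirculates. The kinetic
quantities are defined on the rise phase only:

- T_MAX: time from onset to the *first attainment* of the maximum intensity
  (first attainment makes the estimate well defined on saturation plateaus);
- T_1/2MAX: time from onset to the first upward crossing of
  baseline + F_MAX/2, linearly interpolated between the bracketing samples
  (the post-peak descent is never used);
- F_MAX: maximum intensity minus the baseline mean (removing ambient-light
  offset; intensities are camera AU and no absolute calibration is assumed);
- perfusion TR = T_1/2MAX / T_MAX and slope = F_MAX / T_MAX, by definition.
  These identities are enforced as invariants on every extraction.

Both reference times are measured from the detected onset rather than the
injection, which keeps TR inside (0, 1] regardless of injection-to-arrival
delay. Curves need not be uniformly sampled; all interpolation is linear in
time. A curve whose maximum sits on the final sample *and* is still climbing
by more than 5% of F_MAX over the last 10% of the window is rejected as
truncated (the observation ended before the peak) instead of extrapolated.

### Onset detection

"First fluorescence increase" is operationalised as the earliest sample
exceeding baseline mean + `k_sd` x baseline SD for `min_run` consecutive
samples, with baseline statistics over the first `baseline_window_s`
seconds. Defaults `k_sd = 3`, `min_run = 3`, `baseline_window_s = 5 s` are
standard bolus-arrival settings: 3 SDs bounds the per-sample false-trigger
rate, and the run requirement suppresses single-frame spikes. Onset is
always detected on the *raw* trace: a moving-average pre-smoothing
correlates neighbouring samples, which silently defeats the consecutive-run
protection (a single smoothed noise excursion spans several samples). When
the arrival time or dark level is known externally, both can be fixed via
`OnsetConfig(fixed_onset_s=..., fixed_baseline_au=...)`.

### Precision limits (why some errors cannot be one sample)

Three estimator properties matter when judging recovery accuracy:

1. **Onset lag.** A threshold detector fires only once the rise clears
   `k_sd` noise SDs. For a gamma-variate rise of shape `alpha` this costs
   `t_peak * x_det` seconds, where `g(x_det) = k_sd * sigma / F_MAX`. For
   shallow-onset curves (`alpha > ~6`, i.e. TR above ~0.6) the lag exceeds a
   sampling interval even on noiseless data, because the early rise is
   below floating-point visibility.
2. **Peak localisation.** Near the peak the curve is locally flat
   (`1 - g ≈ alpha (1-x)^2 / 2`), so with noise the argmax wanders by
   `t_peak * sqrt(2 c sigma_s / (alpha F_MAX))`; on a flat recirculation
   plateau the argmax is uniformly distributed over the plateau. No amount
   of smoothing removes this — it is a property of the estimand.
3. **Quantisation.** 8-bit video hides the sub-half-AU head and tail of the
   rise, adding an onset lag and a peak lead of the same analytic form with
   `q = 0.5 AU` in place of the noise term.

Consequently the test suite asserts one-sampling-interval recovery on
noise-free curves with TR in [0.10, 0.55] (the central bulk of the observed
time-ratio distribution, 0.43 ± 0.16), and asserts the analytic bounds above
— not one interval — for noisy or quantised data. The half-max crossing gets
a 5% allowance on top of one interval for the second-order chord bias of
linear interpolation on a convex rise.

## Cutoff derivation

Safe cutoffs are obtained by *inverse regression*: OLS of each parameter
(response) on StO₂ (predictor; plus StO₂² for the quadratic form), then the
predicted mean at StO₂ = 60…80% is read off as the cutoff. The interval
reported is the 95% CI of the **mean response**,
`x0' beta ± t(0.975, df) * sqrt(sigma² x0' (X'X)^{-1} x0)` — not a
prediction interval — because the cutoff is a property of the population
regression line. The implementation stores `(X'X)^{-1}`, the residual
variance and the residual df in the fit object; tests cross-check the CI
against `statsmodels` `get_prediction` as an independent route.

Rows with non-finite values are dropped; an optional one-pass filter
removing |externally studentized residual| > 4 reproduces the style of
exclusion the source analysis applied to two parameters (its exact rule is
unpublished). Published equations can be wrapped via
`RegressionFit.from_coefficients`, which evaluates them with a zero-width CI.

Parameters whose scatter against StO₂ has no usable trend (perfusion TR,
F_MAX) get a **descriptive cutoff**: the 97.5th (direction "le") or 2.5th
("ge") percentile of the sample — a percentile interval rather than
mean ± 1.96 SD, because the distributions are explicitly non-normal
(mean ± 1.96 SD is available as `method="normal"`). Cutoffs are rounded to
clinically convenient grids (1 s for T_1/2MAX, 5 for T_MAX/slope/NIR/F_MAX,
0.1 for TR) as a presentation-layer step only; raw values are always
available.

## Diagnostic evaluation

Points are cross-classified by safe-range membership (test) against
StO₂ ≥ 60% (condition). Orientation is fixed per parameter: T_1/2MAX,
T_MAX and TR are within range at or below their cutoff; slope and the NIR
perfusion index at or above; F_MAX strictly above (the published split is
≤25 / >25). Ties at inclusive cutoffs fall on the within-range side.

Proportion CIs default to exact Clopper–Pearson (the published sensitivity
interval for 319/329, (94.5, 98.5), matches the exact interval; Wilson is
available). Association uses Fisher's exact test (two-sided) when any
expected cell is below 5 and the uncorrected Pearson chi-square otherwise.
ROC analysis negates the lower-is-better parameters so that AUC > 0.5 is
always "informative", and computes the AUC variance with DeLong's
placement-value method (implemented here; the AUC itself is cross-checked
against the Mann–Whitney pair count in tests). Metrics with zero
denominators are reported as undefined values with a flag, never raised.

## Decision rules

First-stage protocol: StO₂ > 60% and T_1/2MAX < 10 s is good perfusion
(proceed to anastomosis); StO₂ < 50% and T_1/2MAX > 25 s is poor perfusion
(move the transection line proximally). The wedge in between
(50–60% StO₂, or 10–25 s half-rise) is an intermediate status referred to
the surgeon — in the source protocol such segments proceeded without
complications. Second stage (on the relocated line): StO₂ ≥ 60% with
T_1/2MAX ≤ 25 s is acceptable; anything else remains poor and goes back to
the surgeon (the protocol defines no automatic second line change).
Boundary strictness follows the protocol wording exactly (strict at the
first stage, inclusive at the second).

Stepwise StO₂-class prediction from ICG parameters alone: both time
parameters within their safe ranges → predict ≥ 60%; both outside →
predict < 60%; exactly one within → slope adjudicates (≥ 5 AU/s predicts
≥ 60%). The rule is total and deterministic, and improving any single
parameter toward its safe side can never flip a prediction from adequate to
low (verified over a 10⁴-point grid).

## Correlation networks

Spearman rho with average ranks for ties, pairwise-complete over missing
values; pairs with fewer than 3 complete observations or a constant member
are flagged NaN. Binary covariates enter as 0/1 (Spearman against a
continuous variable then equals the rank-biserial correlation). The network
keeps edges with rho strictly above 0.2 (positive class) or below −0.2
(negative class); edge count is monotone non-increasing in the threshold.
No p-value filtering is applied to edges.

## Synthetic study conditions

The generator emulates the published cohort structure — 68 patients × 5
points — because the patient data are not deposited:

- **StO₂**: truncated normal N(80, 7²) on [0, 95] (the 60–95% bulk), a
  low-oxygenation component N(48, 8²) on [20, 60] hit with probability
  0.028, and a patient-level intercept (SD 4%) for within-patient
  clustering; overall ~3.2% of points fall below 60%, matching the 11/340
  condition. Final values are clipped to [0, 100].
- **Regression-linked parameters** (T_1/2MAX, T_MAX, slope, NIR index):
  published linear equations as truth plus Gaussian residuals, floored at
  the smallest observed values (times) or clipped to [0, 100] (NIR). The
  residual SD is *calibrated by bisection on the realised fit* so the
  induced R² equals the published value after flooring — the naive
  `sd(signal) * sqrt((1-R²)/R²)` misses the target wherever the floor
  binds. T_MAX is drawn first and T_1/2MAX is capped at it; their residuals
  share a correlation of 0.7, reflecting that both transit times delay
  together under poor inflow (without this coupling, the cap would inject
  enough T_MAX signal into T_1/2MAX that hitting R² = 0.183 requires
  implausible censoring). TR is recomputed as T_1/2MAX / T_MAX after
  bounding, so it always lies in (0, 1].
- **F_MAX**: truncated normal over the observed range, independent of StO₂
  (it showed no discrimination in the source cohort, AUC ≈ 0.40).
- **Covariates**: patient-level binaries at roughly the published
  prevalences; age as a truncated normal over the eligibility range.
- **Curves**: gamma-variate rise
  `F(t) = F_MAX ((t-t0)/tp)^alpha exp(alpha (1-(t-t0)/tp))` with `tp = T_MAX`
  and `alpha = ln(1/2) / (ln TR + 1 - TR)` in closed form, so the analytic
  half-max upcrossing lands exactly at T_1/2MAX; TR at or above 1 is
  infeasible for this family and raises. After the peak the trace is held
  at F_MAX as a flat stand-in for recirculation (the parameters depend only
  on the rise). Default sampling 4 Hz over `t0 + 1.25 T_MAX + 5 s`.
- **Frame stacks**: disc ROIs rendered into uint8 frames with optional
  background noise; disjointness and bounds are validated.

What passing tests on these conditions does **not** show: the generator has
no respiration/motion artifacts, no camera drift or distance variation, no
ICG dosing variability, and Gaussian-censored rather than skewed residuals —
the marginal parameter distributions are wider than the published ones
(e.g. synthetic T_1/2MAX ≈ 6 ± 7 s vs the published 4.07 ± 5.85 s), because
matching both the published R² and Gaussian additive noise under physical
floors forces heavier spread. Recovery of regression truth on these cohorts
demonstrates estimator correctness, not clinical transportability of the
cutoffs across camera systems or dosing protocols.

## Problem sizes and determinism

Default analyses use one 340-point cohort, 100-curve round-trip batches and
500-replicate CI-coverage simulations; everything completes in seconds.
Every stochastic step takes an explicit integer seed (`numpy`
`default_rng`), and identical config + seed reproduces cohorts, curves and
stacks bit for bit.

## Known limitations

- The onset criterion is threshold-based; backward-extrapolation arrival
  estimators would reduce the shallow-rise lag but are not implemented.
- The cohort-level slope column is drawn from its own regression equation
  and does not satisfy slope = F_MAX / T_MAX across the table (the identity
  holds for curve-extracted parameters); the source cohort's joint
  distribution is not recoverable from published marginals.
- Points are treated as independent in all fits (as in the source
  analysis); the patient-level intercept in the generator means nominal SEs
  on synthetic cohorts are mildly optimistic.
- The hyperspectral StO₂ computation itself is out of scope; StO₂ is
  consumed (and simulated) as a percentage.
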