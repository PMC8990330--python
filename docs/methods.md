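# Methods

`ssridetect` re-implements, end to end, a digital-phenotyping analysis that
asks whether SSRI (selective serotonin reuptake inhibitor) use leaves a
detectable signature in week-long, minute-resolution actigraphy. The package
contains the complete analysis chain — preprocessing, a wavelet-feature
logistic baseline, a ConvLSTM classifier with class-weighted training and
optional depression-score fusion, additive temporal attribution, and
descriptive rest-activity statistics — together with a synthetic cohort
generator that serves as the ground-truth test surface for every stage.

## Data model

The unit of observation is one participant's **activity week**: 10,080
nonnegative vertical-acceleration counts, one per minute, over 7 days. The
deep model consumes the week reshaped to a `(7 days, 24 hours, 60 minutes)`
tensor, so each day is a 2-D "image" whose rows are hours. Alongside the
activity, a cohort carries a binary SSRI-exposure label (derived from
generic medication names), demographics (age, sex, race/ethnicity), and a
PHQ-9 depression score in [0, 27] with substantial missingness.

## Synthetic cohort generator

Real cohorts of this design (NHANES 2005-2006 scale: thousands of
participants, ~3.7% exposed) require a bulk download, so the package
generates cohorts with the statistical structure the analysis assumes and
*plantable* effect sizes:

* **Diurnal profile.** Expected counts/min follow a piecewise-linear day:
  night trough, a linear morning ramp over minutes [360, 540) (6–9 am), a
  daytime plateau, a linear evening decline over [1080, 1260) (6–9 pm), and
  a late-night trough. Defaults (plateau 250 counts/min, ramps ±1.0
  counts/min²) put the control group's whole-day mean at 160 counts/min and
  its ramp slopes near the values reported for population actigraphy.
* **Exposed-group contrasts.** Three ratios are planted: the whole-day mean
  ratio (`amplitude_ratio`, default 0.71), and morning/evening slope ratios
  (defaults 0.75 and 0.51). A single global scaling cannot realize all
  three at once, so the exposed profile gets its own plateau (solved in
  closed form — the daily mean is affine in the plateau with unit
  coefficient) and its own night levels; the three planted ratios then hold
  exactly in expectation.
* **Count noise.** Conditional on a participant, minute counts are
  gamma-Poisson (negative binomial, dispersion 2.0) around the personal
  profile; night minutes are additionally zeroed with probability 0.3, with
  the surviving mean rescaled so the per-minute expectation is unchanged.
  Between-person heterogeneity is a mean-one lognormal amplitude multiplier
  with SD 0.25.
* **Covariates.** Demographics are drawn group-conditionally (exposed:
  older, more female, different race/ethnicity mix). PHQ-9 is an
  overdispersed count score with a +1.58-point exposed-group shift, and is
  missing at random given age and sex, with the logistic intercept solved
  numerically so the expected missing fraction equals the configured rate
  (default 40.2%).

**What the generator does not emulate.** Every participant shares the same
diurnal *shape* (up to amplitude); there is no chronotype variation, no
weekday/weekend structure, no wear-time artifacts, and no label noise. As a
consequence planted effects are considerably easier to classify than the
corresponding real-data contrast — the baseline reaches CV AUC ≈ 0.99 on the
default planted cohort where the real-data analogue sits near 0.65. Passing
tests therefore demonstrate correctness of the pipeline and recoverability
of planted parameters, not real-world effect sizes. Shape homogeneity is
deliberate: the parameter-recovery tolerances (±0.05 on three ratios at
n=2000) constrain how much between-person variation the generator can carry.

## Preprocessing

* **Smoothing.** Savitzky–Golay filter, window 21 minutes, polynomial order
  3 (both configurable). The filter reproduces any cubic exactly, so the
  planted linear ramps survive smoothing; edges use scipy's boundary-window
  polynomial fit (`interp`), which keeps that property exact at the week
  boundaries.
* **Reshaping.** `(10,080,) -> (7, 24, 60)` with element `(d, h, m)` taken
  from flat index `d*1440 + h*60 + m`; flattening is the exact inverse.
* **Standardization.** Each of the 10,080 minute-of-week positions is
  z-scored across participants (constant positions map to zero). The
  cohort-wide variant is the default, matching the original analysis; a
  leakage-safe variant (statistics from training rows only) is available via
  `standardize_per_minute(..., train_idx=...)`.
* **Splitting.** Stratified 80/20 held-out test split plus stratified
  10-fold CV over the 80%, all seeded. Class weights follow the
  "other-class prevalence" convention: with 266 positives of 7,162 the
  negative class is weighted 266/7162 ≈ 0.03714 and the positive class
  6896/7162 ≈ 0.96286.

## Wavelet-logistic baseline

Each smoothed week is decomposed with a 6-level Daubechies-4 DWT. Boundary
handling is periodization, which keeps the transform orthogonal: subband
energies sum to the signal energy (exact at dyadic lengths; at 10,080 the
level-5 subband length is odd and conservation holds to ~1e-4) and subband
lengths halve per level. Per subband, seven statistics are extracted —
mean, 25th/75th percentiles, Shannon entropy (natural log) of the
normalized squared coefficients, SD, variance, and the mean-crossing rate
(sign changes of the mean-centered coefficients divided by length−1; for
zero-mean detail subbands this equals the zero-crossing rate). All-zero
subbands get entropy 0 and crossing rate 0 by convention. The classifier is
logistic regression with per-fold feature z-scoring, the class weights
above as sample weights, and a very weak L2 penalty (C = 1e4, effectively
maximum likelihood).

## ConvLSTM classifier

Architecture (layer order fixed; sizes configurable): ConvLSTM → 2×2 max
pool → ConvLSTM → dropout (rate 0.2) → flatten → [concatenate z-scored
PHQ-9 scalar] → dense (tanh) → dense → sigmoid. The ConvLSTM cell is the
standard formulation with convolutional state transitions: gates
`i, f, o = σ(conv([x_t, h_{t-1}]))`, candidate `g = tanh(conv(·))`,
`c_t = f⊙c_{t-1} + i⊙g`, `h_t = o⊙tanh(c_t)`, with forget-gate bias
initialized to 1 and Glorot-uniform kernels. The 7 daily frames are the
recurrent sequence, reducing the LSTM to 7 time steps.

The stack runs on the package's own reverse-mode autodiff engine
(`_autodiff.py`): numpy tensors with analytically derived backward rules
for every op, checked against central finite differences in the test suite.
Convolution gradients use a shift-and-add adjoint (9 small GEMMs into
strided slices) so the graph never materializes im2col windows of the
gradient; training runs in float32.

Training is class-weighted binary cross-entropy with Adam. Early stopping
monitors the class-weighted *validation loss*, not the validation AUC:
selecting the epoch that maximizes a rank statistic computed on a small
validation fold (often 1–7 positives) would bias reported AUCs upward under
the null and break the calibration checks. Unstated hyperparameters default
to: 16/8 filters, 3×3 kernels, dense width 16, Adam 1e-3, batch 32, ≤50
epochs, patience 5. The *desk-scale profile* used throughout the tests
(`reduced_config`) is 4/2 filters, dense 8, Adam 3e-3, ≤4 epochs, patience
2 — sized so full 10-fold runs complete in minutes on one CPU while still
saturating the planted-signal benchmarks.

Held-out test predictions are the mean of the 10 fold-models'
probabilities; per-fold test predictions are also retained so test-set
metrics can be averaged across fold models (the convention used in the
metrics table).

**PHQ-9 fusion and imputation.** Missing PHQ-9 scores are filled by
iterative chained regression (scikit-learn's IterativeImputer) on age, sex
and race/ethnicity one-hots; observed values pass through unchanged and
imputed values are clipped to [0, 27]. Single imputation with a fixed seed
is the default. The completed score is z-scored and concatenated to the
flattened ConvLSTM features, adding exactly `dense_width` parameters.

## Temporal attribution

Per-minute attributions are integrated gradients on the probability scale:
the gradient of the sigmoid output is integrated (midpoint rule) along the
straight path from a baseline to the participant's input and multiplied by
the input−baseline difference. The baseline is the mean of a seeded
background sample (typically 100 training participants). The path integral
makes attributions additive — `f(x) − f(baseline) = Σ φ` up to quadrature
error — and the number of steps is doubled adaptively (32 → at most 512)
until the worst additive-accuracy gap is below 1e-3; folds that cannot meet
the tolerance are excluded (at least 5 of 10 must survive). Fold maps are
averaged elementwise. Summaries follow the figure conventions: average
across participants and the 7 days to a 1,440-minute curve, then a centered
60-minute rolling mean with truncated edges; the activity–attribution
association is the per-minute Spearman correlation across participants
(day-averaged), smoothed the same way, with zero-variance minutes recorded
as missing and skipped.

## Movement statistics

* **Group means.** Per-participant mean over the 10,080 minutes, then group
  mean with a normal-approximation 95% CI over participant means.
* **Ramp slopes.** OLS slope of the smoothed, participant- and day-averaged
  minute-of-day curve over [360, 540) and [1080, 1260), in raw counts/min²;
  the CI is a seeded participant-level bootstrap (1,000 resamples,
  percentile interval). On noiseless planted cohorts the recovered slope
  ratios match the planted ones to <0.02 (the residual is the smoothing
  kink at the window boundaries); with smoothing off the match is exact.
* **Demographic table.** Chi-square tests of independence for sex and
  race/ethnicity; two-sided Welch t tests for age and PHQ-9; significance
  flagged at p < .05. A summary-statistic Welch t (`welch_t_from_summary`)
  supports checks against published tables.

## Evaluation metrics

AUC is Mann–Whitney concordance (ties half-weighted), with a t-interval
over per-fold AUCs for the CI. The operating threshold maximizes Youden's
J on validation predictions (ties toward the lower threshold; the constant
score degenerate case returns 0.5 with a warning). Sensitivity,
specificity, PPV/NPV (percent), and balanced accuracy come from the 2×2
table at that threshold; undefined predictive values (no predicted
positives) are reported as missing rather than coerced. The population
stability index uses decile bins of the reference (training-fold) score
distribution with proportions floored at 1e-4; it is validated against its
own formula only, since the original table's PSI scale (~10) is not
reconstructible from the published description.

## Problem sizes and numerical choices

The desk-scale runs are sized so every stochastic check is a ≥2-sigma
statement under its stated tolerance: parameter recovery and baseline
calibration at n=2000 (prevalence 0.037); ConvLSTM null calibration at
n=600 with prevalence 0.15 (at 3.7% prevalence a validation fold holds ~1
positive and the fold AUC is nearly uninformative; prevalence is a cohort
composition parameter, not a planted effect); signal detection at n=400
with amplitude ratio 0.5; the attribution benchmark at n=150 with the
contrast confined to minutes [480, 540). Bootstrap coverage is checked with
200 replicate cohorts of 50 participants and 400 resamples, where the
nominal 95% percentile interval achieves ~93% empirical coverage.

## Known limitations

* The generator's shape homogeneity (above) makes classification easier
  than on real data; absolute AUCs on synthetic cohorts are not comparable
  to published real-data AUCs.
* The XPT ingestion path (`read_xpt`) is exercised only through the shared
  CSV logic; no binary SAS fixtures ship with the package.
* Attribution tolerances are on the probability scale; for near-saturated
  models the integrated path can require many quadrature steps.
* PSI depends on the reference binning; values are comparable only within
  a fixed binning convention.
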