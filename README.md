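# ssridetect

Detecting SSRI (selective serotonin reuptake inhibitor) use from week-long,
minute-resolution actigraphy.

Population actigraphy studies have reported that people taking SSRIs move
less overall, ramp up more slowly in the morning, and wind down more slowly
in the evening — and that a classifier can detect SSRI exposure from the raw
activity trace alone, even after accounting for depression severity.
`ssridetect` is a tested, reusable implementation of that entire analysis
for biostatisticians and digital-phenotyping researchers: from NHANES-style
minute records to classifier metrics and temporal explanations, with a
synthetic cohort generator so every stage runs and is verifiable without any
data download.

## What's inside

* **`synthetic`** — cohorts of 10,080-minute count weeks with plantable
  effect sizes: an exposed subgroup with a lower whole-day mean
  (amplitude ratio, default 0.71), shallower 6–9 am and 6–9 pm ramps
  (slope ratios 0.75 / 0.51), older and more-female demographics, higher
  PHQ-9 depression scores, and ~40% missing-at-random PHQ-9.
* **`io`** — tidy-CSV cohort exchange, SAS-transport (XPT) ingestion for
  real NHANES files, and SSRI labelling from generic medication names
  (sertraline / escitalopram / fluoxetine / paroxetine / citalopram stems).
* **`preprocess`** — Savitzky–Golay smoothing, `(7, 24, 60)` week tensors,
  per-minute z-scoring across the cohort, stratified 80/20 + 10-fold CV
  splits, and imbalance class weights.
* **`wavelet`** — 6-level Daubechies decomposition, 7 statistics × 7
  subbands, and a class-weighted logistic baseline
  (`WaveletLogisticClassifier`).
* **`convlstm`** — a ConvLSTM → max-pool → ConvLSTM → dropout → dense
  classifier with optional PHQ-9 fusion and chained-regression imputation,
  running on the package's own numpy autodiff engine (`ConvLstmClassifier`).
* **`attribution`** — integrated-gradients per-minute attributions averaged
  across fold models, 60-minute rolling summaries, and minute-wise Spearman
  correlation with raw activity.
* **`movement`** — group mean activity with CIs, morning/evening best-fit
  slopes with participant-bootstrap CIs, and the chi-square / Welch-t
  demographic comparison table.
* **`evaluation`** — AUC (Mann–Whitney) with fold CIs, Youden cut points,
  sensitivity/specificity/PPV/NPV, balanced accuracy, and the population
  stability index.

Both classifiers follow the model/results convention: construct the model
from data, call `fit(fold_plan, class_weights)`, and get a results object
with per-fold predictions, AUC confidence intervals, and a `summary()`.

## Worked example

```python
import numpy as np
from ssridetect import (
    EffectConfig, generate_cohort, smooth_week, make_fold_plan,
    compute_class_weights, group_mean_activity, interval_slope,
    WaveletLogisticClassifier,
)

cohort = generate_cohort(EffectConfig(seed=20220407), n_participants=2000)
labels = cohort.labels

means = group_mean_activity(cohort.activity, labels)
for group, m in means.items():
    print(f"{group:8s} mean activity {m.mean:6.1f} counts/min "
          f"(95% CI {m.ci_low:.1f}-{m.ci_high:.1f}, n={m.n})")
for interval in ("morning", "evening"):
    e = interval_slope(cohort.activity[labels == 1], interval, seed=0)
    c = interval_slope(cohort.activity[labels == 0], interval, seed=0)
    print(f"{interval} slope: exposed {e.slope:+.3f}, control {c.slope:+.3f} "
          f"counts/min^2 (ratio {e.slope / c.slope:.3f})")

plan = make_fold_plan(labels, test_fraction=0.2, k=10, seed=0)
weights = compute_class_weights(labels)
results = WaveletLogisticClassifier.from_activity(
    smooth_week(cohort.activity), labels
).fit(plan, weights)
print(results.summary())
```

prints

```
exposed  mean activity  118.5 counts/min (95% CI 111.8-125.2, n=84)
control  mean activity  160.8 counts/min (95% CI 159.0-162.7, n=1916)
morning slope: exposed +0.788, control +1.005 counts/min^2 (ratio 0.784)
evening slope: exposed -0.528, control -1.006 counts/min^2 (ratio 0.525)
wavelet logistic regression
===========================
cross-validation AUC: 1.000 (95% CI 0.999-1.000) over 10 folds
held-out test AUC:    0.995 (95% CI 0.994-0.997) (fold-model ensemble mean prob)
```

The planted contrasts are recovered (84/2000 ≈ 3.7% exposed; whole-day mean
ratio 118.5/160.8 ≈ 0.74 vs planted 0.71; slope ratios 0.78 and 0.53 vs
planted 0.75 and 0.51 — the shared deviation is the exposed group's sampled
mean amplitude). The near-perfect AUC reflects the generator's deliberately
homogeneous diurnal shapes, not real-world separability; see
`docs/methods.md` for what the synthetic cohorts do and do not emulate.

The same pipeline runs from the shell:

```bash
ssridetect simulate --n 400 --out cohort/
ssridetect run-all --out runs/demo --seed 1
```

emitting `metrics.csv`, `group_curves.csv`, `slopes.json`,
`attributions.csv`, `table1.csv`, and `run.log`.

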