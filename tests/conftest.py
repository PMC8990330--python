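"""Shared fixtures: the study-condition cohorts and fitted models.

Heavy objects (n=2000 cohorts, trained fold models) are session-scoped so
the property tests and the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssridetect.convlstm import ConvLstmClassifier, reduced_config
from ssridetect.preprocess import (
    compute_class_weights,
    make_fold_plan,
    reshape_week,
    smooth_week,
    standardize_per_minute,
)
from ssridetect.synthetic import (
    DiurnalProfile,
    EffectConfig,
    NoiseModel,
    generate_cohort,
    generate_diurnal_profile,
    generate_participant_week,
    null_config,
)
from ssridetect.wavelet import WaveletLogisticClassifier

SEED = 20220407


def prepare(cohort, k=10, seed=1):
    """Smooth, reshape+standardize, split — the standard front end."""
    smoothed = smooth_week(cohort.activity)
    tensor = standardize_per_minute(reshape_week(smoothed))
    plan = make_fold_plan(cohort.labels, k=k, seed=seed)
    weights = compute_class_weights(cohort.labels)
    return smoothed, tensor, plan, weights


@pytest.fixture(scope="session")
def planted_cohort():
    """n=2000 cohort with the printed effect sizes (0.71 / 0.75 / 0.51)."""
    return generate_cohort(EffectConfig(seed=SEED), 2000)


@pytest.fixture(scope="session")
def null_cohort_2000():
    """n=2000 cohort with every effect ratio set to 1."""
    return generate_cohort(null_config(seed=SEED + 1), 2000)


@pytest.fixture(scope="session")
def null_baseline_results(null_cohort_2000):
    smoothed, _, plan, weights = prepare(null_cohort_2000)
    model = WaveletLogisticClassifier.from_activity(smoothed, null_cohort_2000.labels)
    return model.fit(plan, weights)


@pytest.fixture(scope="session")
def planted_baseline_results(planted_cohort):
    smoothed, _, plan, weights = prepare(planted_cohort)
    model = WaveletLogisticClassifier.from_activity(smoothed, planted_cohort.labels)
    return model.fit(plan, weights)


@pytest.fixture(scope="session")
def signal_cohort_400():
    """n=400 cohort with a strong planted amplitude effect (ratio 0.5)."""
    return generate_cohort(EffectConfig(amplitude_ratio=0.5, seed=SEED + 2), 400)


@pytest.fixture(scope="session")
def signal_run_400(signal_cohort_400):
    """Baseline + ConvLSTM fitted on the strong-effect cohort."""
    cohort = signal_cohort_400
    smoothed, tensor, plan, weights = prepare(cohort)
    baseline = WaveletLogisticClassifier.from_activity(smoothed, cohort.labels).fit(
        plan, weights
    )
    lstm = ConvLstmClassifier(tensor, cohort.labels, reduced_config(seed=3)).fit(plan, weights)
    return {
        "cohort": cohort,
        "tensor": tensor,
        "plan": plan,
        "baseline": baseline,
        "convlstm": lstm,
    }


@pytest.fixture(scope="session")
def null_convlstm_results():
    """ConvLSTM on a no-effect cohort (prevalence raised so per-fold AUCs
    are estimable: ~7 positives per validation fold at n=600)."""
    cohort = generate_cohort(null_config(seed=SEED + 3, prevalence=0.15), 600)
    _, tensor, plan, weights = prepare(cohort)
    return ConvLstmClassifier(tensor, cohort.labels, reduced_config(seed=4)).fit(plan, weights)


@pytest.fixture(scope="session")
def window_cohort():
    """Cohort whose group difference is confined to minutes [480, 540).

    Built directly from two diurnal profiles identical outside the planted
    one-hour window, with the standard count noise; used to check that
    attributions concentrate where the signal lives.
    """
    rng = np.random.default_rng(SEED + 4)
    n, prevalence = 150, 0.2
    control = generate_diurnal_profile(200.0, 1.0, -1.0)
    exposed_values = control.values.copy()
    exposed_values[480:540] *= 0.3
    exposed = DiurnalProfile(exposed_values, control.morning_ramp, control.evening_ramp)
    labels = (rng.random(n) < prevalence).astype(np.int8)
    noise = NoiseModel(between_person_sd=0.0)
    activity = np.vstack(
        [
            generate_participant_week(exposed if lab else control, noise, seed=rng)
            for lab in labels
        ]
    )
    return activity, labels


@pytest.fixture(scope="session")
def window_run(window_cohort):
    """Fold models trained on the planted-window cohort (5 folds)."""
    activity, labels = window_cohort
    smoothed = smooth_week(activity)
    tensor = standardize_per_minute(reshape_week(smoothed))
    plan = make_fold_plan(labels, k=5, seed=2)
    weights = compute_class_weights(labels)
    config = reduced_config(seed=5, filters=(2, 2), epochs=3)
    results = ConvLstmClassifier(tensor, labels, config).fit(plan, weights)
    return {
        "activity": activity,
        "labels": labels,
        "tensor": tensor,
        "plan": plan,
        "results": results,
    }
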