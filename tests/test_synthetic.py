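"""Generator correctness: planted profiles, noise expectations, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssridetect.movement import interval_slope
from ssridetect.synthetic import (
    EffectConfig,
    NoiseModel,
    exposed_profile_from_control,
    generate_cohort,
    generate_diurnal_profile,
    generate_participant_week,
    null_config,
)


def ols_slope(y):
    t = np.arange(len(y), dtype=float)
    t -= t.mean()
    return (t * (y - y.mean())).sum() / (t**2).sum()


class TestDiurnalProfile:
    def test_planted_morning_slope_is_exact(self):
        profile = generate_diurnal_profile(200.0, morning_ramp=1.0)
        assert ols_slope(profile.values[360:540]) == pytest.approx(1.0, abs=1e-9)

    def test_zero_plateau_rejected(self):
        with pytest.raises(ValueError):
            generate_diurnal_profile(0.0)

    def test_ramp_ratio_recovered_between_two_profiles(self):
        a = generate_diurnal_profile(250.0, morning_ramp=1.0)
        b = generate_diurnal_profile(250.0, morning_ramp=0.75)
        ratio = ols_slope(b.values[360:540]) / ols_slope(a.values[360:540])
        assert ratio == pytest.approx(0.75, abs=1e-6)

    @given(
        plateau=st.floats(200.0, 400.0),
        morning=st.floats(0.3, 1.0),
        evening=st.floats(-1.0, -0.3),
    )
    @settings(max_examples=25, deadline=None)
    def test_profile_invariants(self, plateau, morning, evening):
        profile = generate_diurnal_profile(plateau, morning, evening)
        assert profile.values.shape == (1440,)
        assert np.all(profile.values >= 0)
        assert profile.values[:300].mean() < profile.values[600:1020].mean()
        assert ols_slope(profile.values[360:540]) == pytest.approx(morning, abs=1e-9)
        assert ols_slope(profile.values[1080:1260]) == pytest.approx(evening, abs=1e-9)

    def test_exposed_profile_realizes_all_three_ratios(self):
        control = generate_diurnal_profile(250.0, 1.0, -1.0)
        exposed = exposed_profile_from_control(control, 0.71, 0.75, 0.51)
        assert exposed.daily_mean / control.daily_mean == pytest.approx(0.71, abs=1e-9)
        m_ratio = ols_slope(exposed.values[360:540]) / ols_slope(control.values[360:540])
        e_ratio = ols_slope(exposed.values[1080:1260]) / ols_slope(control.values[1080:1260])
        assert m_ratio == pytest.approx(0.75, abs=1e-9)
        assert e_ratio == pytest.approx(0.51, abs=1e-9)


class TestParticipantWeek:
    def test_zero_noise_week_is_tiled_profile(self):
        profile = generate_diurnal_profile(200.0)
        week = generate_participant_week(profile, noise_model=None)
        assert week.shape == (10080,)
        np.testing.assert_array_equal(week, np.tile(profile.values, 7))
        # noiseless generation is exactly periodic with period 1440
        np.testing.assert_array_equal(week[:1440], week[1440:2880])

    def test_seeded_generation_is_bitwise_reproducible(self):
        profile = generate_diurnal_profile(200.0)
        noise = NoiseModel()
        a = generate_participant_week(profile, noise, seed=42)
        b = generate_participant_week(profile, noise, seed=42)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0)

    def test_monte_carlo_mean_matches_profile(self):
        """Sample means over 1,000 weeks match the planted expectation.

        The per-minute z-scores of (sample mean - profile) should behave like
        standard normals: none beyond 4.5 SE, and at least 99% within 3 SE.
        """
        profile = generate_diurnal_profile(200.0)
        noise = NoiseModel()
        rng = np.random.default_rng(123)
        n = 1000
        total = np.zeros(10080)
        total_sq = np.zeros(10080)
        for _ in range(n):
            week = generate_participant_week(profile, noise, seed=rng)
            total += week
            total_sq += week**2
        mean = total / n
        sd = np.sqrt(total_sq / n - mean**2)
        se = sd / np.sqrt(n)
        z = (mean - np.tile(profile.values, 7)) / se
        assert np.abs(z).max() < 4.5
        assert (np.abs(z) < 3).mean() >= 0.99


class TestCohort:
    def test_exposed_count_within_binomial_bound(self):
        cohort = generate_cohort(EffectConfig(prevalence=0.037, seed=99), 2000)
        expected = 2000 * 0.037
        bound = 3 * np.sqrt(2000 * 0.037 * 0.963)
        assert abs(int(cohort.labels.sum()) - expected) < bound

    def test_too_few_expected_exposed_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(EffectConfig(prevalence=0.037), 30)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(EffectConfig(), 10)

    def test_null_config_gives_identical_group_profiles(self):
        cohort = generate_cohort(null_config(prevalence=0.2), 20)
        np.testing.assert_allclose(
            cohort.exposed_profile.values, cohort.control_profile.values, atol=1e-9
        )

    def test_cohort_reproducible_under_seed(self):
        a = generate_cohort(EffectConfig(prevalence=0.2, seed=7), 30)
        b = generate_cohort(EffectConfig(prevalence=0.2, seed=7), 30)
        np.testing.assert_array_equal(a.activity, b.activity)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.demographics.equals(b.demographics)
        np.testing.assert_array_equal(a.phq9, b.phq9)

    def test_phq9_range_and_missingness(self, planted_cohort):
        phq9 = planted_cohort.phq9
        present = ~np.isnan(phq9)
        assert np.all((phq9[present] >= 0) & (phq9[present] <= 27))
        missing_rate = np.isnan(phq9).mean()
        # MAR intercept is solved for the target rate; binomial noise remains
        assert missing_rate == pytest.approx(0.402, abs=3 * np.sqrt(0.402 * 0.598 / 2000))

    def test_demographics_shift_with_exposure(self, planted_cohort):
        demo, labels = planted_cohort.demographics, planted_cohort.labels
        age_gap = demo["age"][labels == 1].mean() - demo["age"][labels == 0].mean()
        assert age_gap > 8  # planted gap is ~16.5 years
        f_exposed = (demo["sex"][labels == 1] == "female").mean()
        f_control = (demo["sex"][labels == 0] == "female").mean()
        assert f_exposed > f_control

    def test_activity_nonnegative(self, planted_cohort):
        assert np.all(planted_cohort.activity >= 0)

    def test_noiseless_cohort_recovers_ratios_exactly(self):
        config = EffectConfig(prevalence=0.3, noise_model=None, seed=5)
        cohort = generate_cohort(config, 40)
        exposed = cohort.activity[cohort.labels == 1]
        control = cohort.activity[cohort.labels == 0]
        assert exposed.mean() / control.mean() == pytest.approx(0.71, abs=1e-9)
        sm = interval_slope(exposed, "morning", smooth=False, n_boot=0).slope
        cm = interval_slope(control, "morning", smooth=False, n_boot=0).slope
        assert sm / cm == pytest.approx(0.75, abs=1e-9)
        se_ = interval_slope(exposed, "evening", smooth=False, n_boot=0).slope
        ce = interval_slope(control, "evening", smooth=False, n_boot=0).slope
        assert se_ / ce == pytest.approx(0.51, abs=1e-9)
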