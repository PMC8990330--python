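"""Smoothing, reshaping, standardization, splitting, class weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssridetect.preprocess import (
    compute_class_weights,
    flatten_week,
    make_fold_plan,
    reshape_week,
    smooth_week,
    standardize_per_minute,
)


class TestSmoothWeek:
    def test_reproduces_low_order_polynomials_exactly(self):
        t = np.linspace(-1, 1, 10080)
        for degree in range(4):  # polyorder default is 3
            series = t**degree
            np.testing.assert_allclose(smooth_week(series), series, atol=1e-9)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_week(np.full(10080, 100.0)), 100.0, atol=1e-9)

    def test_snr_beats_moving_mean_on_noisy_sinusoid(self):
        """Polynomial smoothing should distort a smooth signal less than a
        moving mean of equal window, giving a higher output SNR."""
        rng = np.random.default_rng(0)
        t = np.arange(10080)
        # minute-scale activity bursts: structure fast enough that a moving
        # mean of the same width distorts it heavily
        signal = 100 + 50 * np.sin(2 * np.pi * t / 40)
        noisy = signal + rng.normal(0, 10, t.size)
        window = 21
        sg = smooth_week(noisy, window, 3)
        kernel = np.ones(window) / window
        mm = np.convolve(np.pad(noisy, window // 2, mode="reflect"), kernel, mode="valid")
        snr = lambda est: (signal**2).sum() / ((est - signal) ** 2).sum()
        assert snr(sg) > snr(mm)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 10080))
        lhs = smooth_week(2.5 * x + 0.5 * y)
        rhs = 2.5 * smooth_week(x) + 0.5 * smooth_week(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_invalid_windows_rejected(self):
        series = np.zeros(10080)
        with pytest.raises(ValueError):
            smooth_week(series, window=20)
        with pytest.raises(ValueError):
            smooth_week(series, window=3, polyorder=3)
        with pytest.raises(ValueError):
            smooth_week(np.zeros(11), window=21)


class TestReshapeWeek:
    def test_index_mapping(self):
        flat = np.arange(10080)
        tensor = reshape_week(flat)
        assert tensor[0, 0, 0] == 0
        assert tensor[6, 23, 59] == 10079
        assert tensor[2, 5, 7] == 2 * 1440 + 5 * 60 + 7

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        flat = rng.normal(size=(3, 10080))
        np.testing.assert_array_equal(flatten_week(reshape_week(flat)), flat)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            reshape_week(np.zeros(10079))


class TestStandardizePerMinute:
    def test_two_point_z_score(self):
        cohort = np.array([[1.0], [3.0]]) * np.ones((2, 10080))
        out = standardize_per_minute(cohort)
        np.testing.assert_allclose(out[0], -1.0)
        np.testing.assert_allclose(out[1], 1.0)

    def test_constant_minute_maps_to_zero(self):
        cohort = np.full((5, 10080), 7.0)
        np.testing.assert_array_equal(standardize_per_minute(cohort), 0.0)

    def test_moments_recomputed_post_hoc(self):
        rng = np.random.default_rng(3)
        out = standardize_per_minute(rng.gamma(2, 50, (40, 10080)))
        assert np.abs(out.mean(axis=0)).max() < 1e-8
        assert np.abs(out.std(axis=0) - 1).max() < 1e-8

    def test_commutes_with_participant_permutation(self):
        rng = np.random.default_rng(4)
        cohort = rng.normal(size=(12, 10080))
        perm = rng.permutation(12)
        np.testing.assert_allclose(
            standardize_per_minute(cohort)[perm],
            standardize_per_minute(cohort[perm]),
            atol=1e-12,
        )

    def test_leakage_safe_mode_uses_train_statistics_only(self):
        rng = np.random.default_rng(5)
        cohort = rng.normal(size=(10, 10080))
        train = np.arange(6)
        out = standardize_per_minute(cohort, train_idx=train)
        assert np.abs(out[train].mean(axis=0)).max() < 1e-8
        assert np.abs(out.mean(axis=0)).max() > 1e-4  # full cohort not centered

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            standardize_per_minute(np.zeros((1, 10080)))

    def test_tensor_input_supported(self):
        rng = np.random.default_rng(6)
        flat = rng.normal(size=(8, 10080))
        from_tensor = standardize_per_minute(reshape_week(flat))
        np.testing.assert_allclose(flatten_week(from_tensor), standardize_per_minute(flat))


class TestFoldPlan:
    def test_stratified_test_count_at_published_scale(self):
        labels = np.zeros(7162, dtype=int)
        labels[:266] = 1
        plan = make_fold_plan(labels, test_fraction=0.2, k=10, seed=0)
        assert int(labels[plan.test_idx].sum()) in (53, 54)

    def test_balanced_labels_split_exactly(self):
        labels = np.array([0, 1] * 100)
        plan = make_fold_plan(labels, test_fraction=0.2, k=10, seed=1)
        for _, val in plan.cv_folds:
            assert labels[val].sum() == 8  # 10% of the 80 training positives

    def test_deterministic_under_seed(self):
        labels = np.array([0] * 180 + [1] * 20)
        a = make_fold_plan(labels, seed=11)
        b = make_fold_plan(labels, seed=11)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        for (ta, va), (tb, vb) in zip(a.cv_folds, b.cv_folds):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    @given(n_pos=st.integers(30, 60), n_neg=st.integers(300, 500), seed=st.integers(0, 99))
    @settings(max_examples=10, deadline=None)
    def test_partition_and_stratification_invariants(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        labels = rng.permutation(np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)])
        plan = make_fold_plan(labels, seed=seed)
        pool = plan.train_pool
        assert np.intersect1d(plan.test_idx, pool).size == 0
        assert np.union1d(plan.test_idx, pool).size == labels.size
        all_val = np.concatenate([v for _, v in plan.cv_folds])
        np.testing.assert_array_equal(np.sort(all_val), pool)
        # stratification deviation at most one participant per class, with
        # each subset judged against the pool it was stratified from
        assert abs(labels[plan.test_idx].sum() - labels.mean() * plan.test_idx.size) <= 1 + 1e-9
        pool_frac = labels[pool].mean()
        for tr, va in plan.cv_folds:
            assert np.intersect1d(tr, va).size == 0
            for subset in (tr, va):
                assert abs(labels[subset].sum() - pool_frac * subset.size) <= 1 + 1e-9

    def test_too_few_positives_rejected(self):
        labels = np.array([0] * 95 + [1] * 5)
        with pytest.raises(ValueError, match="stratify"):
            make_fold_plan(labels, k=10)


class TestClassWeights:
    def test_published_imbalance_fractions(self):
        labels = np.r_[np.ones(266, int), np.zeros(6896, int)]
        w = compute_class_weights(labels)
        assert w.weight_negative == pytest.approx(266 / 7162)
        assert w.weight_positive == pytest.approx(6896 / 7162)
        assert round(w.weight_negative, 5) == 0.03714
        assert round(w.weight_positive, 5) == 0.96286

    def test_balanced_labels_are_symmetric(self):
        w = compute_class_weights(np.array([0, 1, 0, 1]))
        assert (w.weight_negative, w.weight_positive) == (0.5, 0.5)

    def test_one_in_ten(self):
        w = compute_class_weights(np.r_[1, np.zeros(9, int)])
        assert (w.weight_negative, w.weight_positive) == pytest.approx((0.1, 0.9))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.ones(5, int))

    def test_per_sample_expansion(self):
        w = compute_class_weights(np.array([0, 1, 1, 0]))
        np.testing.assert_allclose(w.per_sample([1, 0]), [0.5, 0.5])
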