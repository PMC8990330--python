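"""ConvLSTM classifier: architecture contracts, training, imputation."""

import numpy as np
import pytest

from ssridetect import _autodiff as ad
from ssridetect.convlstm import (
    ConvLstmConfig,
    build_model,
    impute_phq9,
    reduced_config,
)


@pytest.fixture(scope="module")
def tiny_config():
    return ConvLstmConfig(filters=(2, 2), dense_width=4, dropout_rate=0.2, seed=11)


@pytest.fixture(scope="module")
def tiny_batch():
    rng = np.random.default_rng(0)
    return rng.normal(size=(4, 7, 24, 60, 1))


class TestBuildModel:
    def test_forward_gives_probability_in_unit_interval(self, tiny_config, tiny_batch):
        net = build_model(tiny_config)
        probs = net.predict_proba(tiny_batch)
        assert probs.shape == (4,)
        assert np.all((probs > 0) & (probs < 1))

    def test_phq9_variant_adds_exactly_one_dense_fan_in(self, tiny_config):
        base = build_model(tiny_config, with_phq9=False).parameter_count()
        fused = build_model(tiny_config, with_phq9=True).parameter_count()
        assert fused - base == tiny_config.dense_width

    def test_same_seed_same_initial_forward(self, tiny_config, tiny_batch):
        a = build_model(tiny_config).predict_proba(tiny_batch)
        b = build_model(tiny_config).predict_proba(tiny_batch)
        np.testing.assert_array_equal(a, b)

    def test_predictions_invariant_to_batch_order(self, tiny_config, tiny_batch):
        net = build_model(tiny_config)
        perm = np.array([2, 0, 3, 1])
        direct = net.predict_proba(tiny_batch)[perm]
        permuted = net.predict_proba(tiny_batch[perm])
        np.testing.assert_allclose(permuted, direct, atol=1e-6)

    def test_odd_spatial_dims_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="even"):
            build_model(tiny_config, input_shape=(7, 23, 60, 1))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ConvLstmConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ConvLstmConfig(kernel_size=4)
        with pytest.raises(ValueError):
            ConvLstmConfig(filters=(0, 2))

    def test_phq9_input_required_when_fused(self, tiny_config, tiny_batch):
        net = build_model(tiny_config, with_phq9=True)
        with pytest.raises(ValueError, match="PHQ-9"):
            net.forward(tiny_batch)


class TestTraining:
    def test_weighted_loss_matches_hand_computation_on_toy_batch(self):
        rng = np.random.default_rng(1)
        z = ad.Tensor(rng.normal(size=6), requires_grad=True)
        y = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        w = np.where(y == 1, 4 / 6, 2 / 6)
        loss = ad.weighted_bce_with_logits(z, y, w)
        p = 1 / (1 + np.exp(-z.data))
        hand = np.mean(-w * (y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert loss.data == pytest.approx(hand, abs=1e-6)

    def test_learns_a_planted_spatial_signal(self):
        """A localized frame-mean shift should be perfectly learnable."""
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=(n, 7, 24, 60, 1)).astype(np.float32)
        labels = rng.permutation(np.r_[np.ones(20, int), np.zeros(40, int)])
        x[labels == 1, :, 8:12, 20:40] += 1.5
        from ssridetect.convlstm import _train_one
        from ssridetect.evaluation import roc_auc

        net = build_model(ConvLstmConfig(filters=(2, 2), dense_width=4, epochs=0, seed=0))
        cfg = reduced_config(seed=0, filters=(2, 2), dense_width=4, epochs=6, batch_size=16)
        net = build_model(cfg)
        w = np.where(labels == 1, 2 / 3, 1 / 3)
        _train_one(net, x[:48], labels[:48], w[:48], x[48:], labels[48:])
        assert roc_auc(net.predict_proba(x[48:]), labels[48:]) >= 0.9


class TestPhq9Ablation:
    def test_constant_phq9_input_reproduces_activity_only_detection(self):
        """Fusing a constant (hence uninformative) PHQ-9 column must leave
        the planted-signal detection intact (ablation sanity)."""
        from ssridetect.convlstm import ConvLstmClassifier
        from ssridetect.preprocess import compute_class_weights, make_fold_plan

        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=(n, 7, 24, 60)).astype(np.float32)
        labels = rng.permutation(np.r_[np.ones(15, int), np.zeros(45, int)])
        x[labels == 1, :, 8:12, 20:40] += 1.5
        plan = make_fold_plan(labels, k=5, seed=0)
        weights = compute_class_weights(labels)
        config = reduced_config(seed=0, filters=(2, 2), dense_width=4, epochs=4)
        activity_only = ConvLstmClassifier(x, labels, config).fit(plan, weights)
        fused = ConvLstmClassifier(
            x, labels, config, phq9=np.full(n, 7.0)
        ).fit(plan, weights)
        assert activity_only.val_auc[0] >= 0.85
        assert fused.val_auc[0] >= 0.85
        assert abs(fused.val_auc[0] - activity_only.val_auc[0]) < 0.15


class TestImputePhq9:
    @pytest.fixture()
    def demographics(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 300
        return pd.DataFrame(
            {
                "age": rng.uniform(18, 80, n).round(),
                "sex": rng.choice(["female", "male"], n),
                "race": rng.choice(["White", "Black", "Other"], n),
            }
        )

    def test_no_missing_is_identity(self, demographics):
        phq9 = np.arange(300.0) % 28
        np.testing.assert_array_equal(impute_phq9(phq9, demographics), phq9)

    def test_beats_mean_imputation_under_planted_age_dependence(self, demographics):
        rng = np.random.default_rng(4)
        age = demographics["age"].to_numpy()
        truth = np.clip(0.2 * age + rng.normal(0, 1.5, age.size), 0, 27)
        phq9 = truth.copy()
        # missing-at-random given age: older participants drop out more
        missing = rng.random(age.size) < 1 / (1 + np.exp(-(age - 50) / 10))
        phq9[missing] = np.nan
        filled = impute_phq9(phq9, demographics, seed=0)
        rmse = np.sqrt(np.mean((filled[missing] - truth[missing]) ** 2))
        mean_fill = np.nanmean(phq9)
        rmse_mean = np.sqrt(np.mean((mean_fill - truth[missing]) ** 2))
        assert rmse < rmse_mean
        np.testing.assert_array_equal(filled[~missing], truth[~missing])

    def test_imputed_values_clipped_to_score_range(self, demographics):
        age = demographics["age"].to_numpy()
        # observed scores stay in range, but the linear trend extrapolates
        # past 27 for the (older) missing participants
        phq9 = 0.38 * age
        phq9[age > 70] = np.nan
        filled = impute_phq9(phq9, demographics, seed=0)
        assert np.all((filled >= 0) & (filled <= 27))

    def test_all_missing_rejected(self, demographics):
        with pytest.raises(ValueError):
            impute_phq9(np.full(300, np.nan), demographics)

    def test_deterministic_under_seed(self, demographics):
        rng = np.random.default_rng(6)
        phq9 = rng.integers(0, 28, 300).astype(float)
        phq9[rng.random(300) < 0.4] = np.nan
        a = impute_phq9(phq9, demographics, seed=9)
        b = impute_phq9(phq9, demographics, seed=9)
        np.testing.assert_array_equal(a, b)
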