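"""ConvLSTM classifier for week-long actigraphy tensors.

The network consumes each participant's week as a sequence of 7 daily
(24 x 60) frames: a ConvLSTM layer (convolutional state transitions, as in
Shi et al.'s precipitation-nowcasting architecture), 2x2 max pooling, a
second ConvLSTM layer, dropout (rate 0.2), flattening, an optional
concatenation of the (z-scored, imputed) PHQ-9 score, and a dense head with
a sigmoid output giving the probability of SSRI exposure.  Training is
class-weighted binary cross-entropy with Adam; the whole stack runs on the
package's own numpy autodiff engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from . import _autodiff as ad
from .evaluation import roc_auc
from .preprocess import ClassWeights, FoldPlan
from .wavelet import CrossValidationResults

logger = logging.getLogger(__name__)

#: training dtype: single precision halves memory traffic with ample headroom
#: for gradient accuracy at these depths
DTYPE = np.float32


@dataclass(frozen=True)
class ConvLstmConfig:
    """Hyperparameters; defaults are the full-scale profile."""

    filters: tuple[int, int] = (16, 8)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.2
    dense_width: int = 16
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.filters) <= 0 or self.kernel_size <= 0 or self.dense_width <= 0:
            raise ValueError("all layer sizes must be positive")
        if self.pool_size != 2:
            raise ValueError("only 2x2 max pooling is implemented")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd ('same' padding)")


def reduced_config(seed: int = 0, **overrides) -> ConvLstmConfig:
    """Desk-scale training profile used by the test suite and examples."""
    defaults = dict(
        filters=(4, 2),
        dense_width=8,
        learning_rate=3e-3,
        epochs=4,
        batch_size=32,
        patience=2,
        seed=seed,
    )
    defaults.update(overrides)
    return ConvLstmConfig(**defaults)


class ConvLstmNetwork:
    """The trainable network: parameters plus a graph-building forward pass."""

    def __init__(self, config: ConvLstmConfig, input_shape=(7, 24, 60, 1), with_phq9=False):
        self.config = config
        self.with_phq9 = with_phq9
        self.input_shape = input_shape
        t, h, w, cin = input_shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for pooling, got {(h, w)}")
        f1, f2 = config.filters
        k = config.kernel_size
        rng = np.random.default_rng(config.seed)

        def conv_param(cin_total, fout):
            fan_in = k * k * cin_total
            w_ = ad.Tensor(
                ad.glorot_uniform(rng, (k, k, cin_total, 4 * fout), fan_in, 4 * fout).astype(DTYPE),
                requires_grad=True,
            )
            b_ = np.zeros(4 * fout, dtype=DTYPE)
            b_[fout : 2 * fout] = 1.0  # forget-gate bias init
            return w_, ad.Tensor(b_, requires_grad=True)

        self.W1, self.b1 = conv_param(cin + f1, f1)
        self.W2, self.b2 = conv_param(f1 + f2, f2)
        flat = (h // 2) * (w // 2) * f2
        dense_in = flat + (1 if with_phq9 else 0)
        self.Wd = ad.Tensor(
            ad.glorot_uniform(
                rng, (dense_in, config.dense_width), dense_in, config.dense_width
            ).astype(DTYPE),
            requires_grad=True,
        )
        self.bd = ad.Tensor(np.zeros(config.dense_width, dtype=DTYPE), requires_grad=True)
        self.Wo = ad.Tensor(
            ad.glorot_uniform(rng, (config.dense_width, 1), config.dense_width, 1).astype(DTYPE),
            requires_grad=True,
        )
        self.bo = ad.Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.Wd, self.bd, self.Wo, self.bo]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters))

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights):
            p.data = w.copy()

    @staticmethod
    def _cell_step(x_t, h, c, W, b, nfilters):
        """One ConvLSTM step: gates from conv([x, h]), standard LSTM update."""
        stacked = ad.concat([x_t, h], axis=-1)
        gates = ad.conv2d(stacked, W, b)
        i = ad.sigmoid(ad.narrow(gates, -1, 0, nfilters))
        f = ad.sigmoid(ad.narrow(gates, -1, nfilters, nfilters))
        o = ad.sigmoid(ad.narrow(gates, -1, 2 * nfilters, nfilters))
        g = ad.tanh(ad.narrow(gates, -1, 3 * nfilters, nfilters))
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def forward(
        self,
        x: np.ndarray,
        phq9: np.ndarray | None = None,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        return_input_tensors: bool = False,
    ):
        """Logit tensor for a batch x of shape (B, 7, 24, 60, 1)."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 4:
            x = x[..., None]
        b, t, h, w, cin = x.shape
        f1, f2 = self.config.filters
        x_steps = [ad.Tensor(x[:, j], requires_grad=return_input_tensors) for j in range(t)]

        h1 = ad.Tensor(np.zeros((b, h, w, f1), dtype=DTYPE))
        c1 = ad.Tensor(np.zeros((b, h, w, f1), dtype=DTYPE))
        pooled = []
        for j in range(t):
            h1, c1 = self._cell_step(x_steps[j], h1, c1, self.W1, self.b1, f1)
            pooled.append(ad.maxpool2x2(h1))

        h2 = ad.Tensor(np.zeros((b, h // 2, w // 2, f2), dtype=DTYPE))
        c2 = ad.Tensor(np.zeros((b, h // 2, w // 2, f2), dtype=DTYPE))
        for j in range(t):
            h2, c2 = self._cell_step(pooled[j], h2, c2, self.W2, self.b2, f2)

        feat = h2
        if training and self.config.dropout_rate > 0:
            rng = dropout_rng or np.random.default_rng(self.config.seed)
            keep = 1.0 - self.config.dropout_rate
            mask = ((rng.random(feat.data.shape) < keep) / keep).astype(DTYPE)
            feat = ad.mul(feat, ad.Tensor(mask))
        flat = ad.reshape(feat, (b, -1))
        if self.with_phq9:
            if phq9 is None:
                raise ValueError("model was built with_phq9 but no PHQ-9 input given")
            flat = ad.concat([flat, ad.Tensor(np.asarray(phq9, DTYPE).reshape(b, 1))], axis=1)
        hidden = ad.tanh(ad.add(ad.matmul(flat, self.Wd), self.bd))
        logits = ad.add(ad.matmul(hidden, self.Wo), self.bo)
        if return_input_tensors:
            return logits, x_steps
        return logits

    def predict_proba(self, x: np.ndarray, phq9=None, batch_size: int = 32) -> np.ndarray:
        """Deterministic (dropout-free) probabilities, in input order."""
        x = np.asarray(x, dtype=DTYPE)
        probs = []
        for start in range(0, x.shape[0], batch_size):
            stop = min(start + batch_size, x.shape[0])
            z = self.forward(
                x[start:stop], None if phq9 is None else phq9[start:stop], training=False
            )
            probs.append(1.0 / (1.0 + np.exp(-z.data.reshape(-1).astype(float))))
        return np.concatenate(probs)


def build_model(
    config: ConvLstmConfig, with_phq9: bool = False, input_shape=(7, 24, 60, 1)
) -> ConvLstmNetwork:
    """Construct the ConvLSTM network (reported shapes checked at build)."""
    return ConvLstmNetwork(config, input_shape=input_shape, with_phq9=with_phq9)


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def _train_one(
    net: ConvLstmNetwork,
    x_train: np.ndarray,
    y_train: np.ndarray,
    w_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    w_val: np.ndarray | None = None,
    phq9_train=None,
    phq9_val=None,
) -> None:
    """Class-weighted Adam training, early stopping on validation loss.

    The monitored quantity is the class-weighted validation cross-entropy,
    not the validation AUC: selecting the epoch that maximizes a rank
    statistic on a small validation fold would bias reported AUCs upward
    under the null.
    """
    cfg = net.config
    rng = np.random.default_rng(cfg.seed + 1)
    opt = ad.Adam(net.parameters, lr=cfg.learning_rate)
    if w_val is None:
        w_val = np.ones_like(y_val, dtype=float)
    best_loss, best_weights, stale = np.inf, net.get_weights(), 0
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward(
                x_train[idx],
                None if phq9_train is None else phq9_train[idx],
                training=True,
                dropout_rng=rng,
            )
            loss = ad.weighted_bce_with_logits(logits, y_train[idx], w_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            loss.backward()
            opt.step()
        p_val = net.predict_proba(x_val, phq9_val)
        val_loss = _weighted_bce(p_val, y_val, w_val)
        logger.debug("epoch %d: val loss %.4f", epoch, val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, stale = val_loss, net.get_weights(), 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    net.set_weights(best_weights)


class ConvLstmClassifier:
    """Model object: standardized week tensor (+ optional PHQ-9) vs labels.

    ``fit(fold_plan, class_weights)`` trains one network per CV fold and
    returns a :class:`CrossValidationResults`; the held-out test probability
    is the mean over the 10 fold models.  Fitted fold networks are kept on
    the results object (``results.fold_networks``) for attribution.
    """

    def __init__(
        self,
        tensor: np.ndarray,
        labels: np.ndarray,
        config: ConvLstmConfig | None = None,
        phq9: np.ndarray | None = None,
    ):
        tensor = np.asarray(tensor, dtype=float)
        if tensor.ndim == 4:
            tensor = tensor[..., None]
        if tensor.shape[1:4] != (7, 24, 60):
            raise ValueError(f"expected (n, 7, 24, 60[, 1]) tensor, got {tensor.shape}")
        self.tensor = tensor
        self.labels = np.asarray(labels)
        self.config = config or ConvLstmConfig()
        self.phq9 = None
        if phq9 is not None:
            phq9 = np.asarray(phq9, dtype=float)
            if np.isnan(phq9).any():
                raise ValueError("PHQ-9 input must be imputed before model fitting")
            # z-score before concatenation so the scalar is on the activity scale
            self.phq9 = (phq9 - phq9.mean()) / (phq9.std() if phq9.std() else 1.0)

    @property
    def with_phq9(self) -> bool:
        return self.phq9 is not None

    def fit(self, fold_plan: FoldPlan, class_weights: ClassWeights) -> CrossValidationResults:
        X, y = self.tensor, self.labels
        test = fold_plan.test_idx
        w = class_weights.per_sample(y)
        fold_val_aucs, fold_test_aucs = [], []
        val_predictions, test_probs, train_probs, networks = [], [], [], []
        for fold, (tr, va) in enumerate(fold_plan.cv_folds):
            net = build_model(
                replace(self.config, seed=self.config.seed + fold),
                with_phq9=self.with_phq9,
                input_shape=X.shape[1:],
            )
            ph = self.phq9
            _train_one(
                net,
                X[tr],
                y[tr],
                w[tr],
                X[va],
                y[va],
                w_val=w[va],
                phq9_train=None if ph is None else ph[tr],
                phq9_val=None if ph is None else ph[va],
            )
            p_val = net.predict_proba(X[va], None if ph is None else ph[va])
            p_test = net.predict_proba(X[test], None if ph is None else ph[test])
            train_probs.append(net.predict_proba(X[tr], None if ph is None else ph[tr]))
            fold_val_aucs.append(roc_auc(p_val, y[va]))
            fold_test_aucs.append(roc_auc(p_test, y[test]))
            val_predictions.append((va, p_val))
            test_probs.append(p_test)
            networks.append(net)
            logger.info("fold %d: val AUC %.3f test AUC %.3f", fold, fold_val_aucs[-1], fold_test_aucs[-1])
        results = CrossValidationResults(
            model="ConvLSTM" + (" + PHQ-9" if self.with_phq9 else " (activity only)"),
            fold_val_aucs=np.asarray(fold_val_aucs),
            val_predictions=val_predictions,
            test_idx=test,
            test_probabilities=np.mean(test_probs, axis=0),
            fold_test_aucs=np.asarray(fold_test_aucs),
            train_probabilities_per_fold=train_probs,
            fold_test_probabilities=test_probs,
        )
        results.fold_networks = networks
        return results


def impute_phq9(
    phq9: np.ndarray, demographics, seed: int = 0, max_iter: int = 10
) -> np.ndarray:
    """Fill missing PHQ-9 scores by chained regression on demographics.

    Iterative multivariate imputation on age, sex and race/ethnicity
    (one-hot); observed scores pass through unchanged and imputed values are
    clipped to [0, 27].  Deterministic under ``seed``.
    """
    phq9 = np.asarray(phq9, dtype=float)
    observed = ~np.isnan(phq9)
    if not observed.any():
        raise ValueError("cannot impute: every PHQ-9 score is missing")
    if observed.all():
        return phq9.copy()
    import pandas as pd

    demo = pd.DataFrame(demographics)
    design = pd.get_dummies(demo[["sex", "race"]], drop_first=True).astype(float)
    design.insert(0, "age", demo["age"].to_numpy())
    X = np.column_stack([design.to_numpy(), phq9])
    imputer = IterativeImputer(max_iter=max_iter, random_state=seed, sample_posterior=False)
    filled = imputer.fit_transform(X)[:, -1]
    out_of_range = (~observed) & ((filled < 0) | (filled > 27))
    if out_of_range.any():
        logger.info("impute_phq9: clipped %d imputed values into [0, 27]", out_of_range.sum())
    filled = np.clip(filled, 0.0, 27.0)
    filled[observed] = phq9[observed]
    return filled
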