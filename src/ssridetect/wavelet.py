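"""Daubechies wavelet featurization and the cross-validated logistic baseline.

Each smoothed week is decomposed with a 6-level discrete wavelet transform
(Daubechies-4 by default, symmetric boundary padding), giving six detail
subbands and one final approximation.  Seven statistics are extracted per
subband — mean, 25th/75th percentiles, Shannon entropy of the normalized
squared coefficients, SD, variance, and the mean-crossing rate — for a
49-dimensional feature vector per participant.  The baseline classifier is a
class-weighted logistic regression evaluated under the shared fold plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .evaluation import auc_confidence_interval, roc_auc
from .preprocess import ClassWeights, FoldPlan

N_LEVELS = 6
DEFAULT_WAVELET = "db4"
#: periodization keeps the transform orthogonal, so subband energies sum to
#: the signal energy exactly and subband lengths halve per level
BOUNDARY_MODE = "periodization"

FEATURE_STATS = ("mean", "pct25", "pct75", "entropy", "sd", "variance", "mean_crossing_rate")


def wavelet_decompose(
    week: np.ndarray, levels: int = N_LEVELS, wavelet: str = DEFAULT_WAVELET
) -> list[np.ndarray]:
    """Multilevel DWT: returns [a_L, d_L, ..., d_1] coefficient subbands."""
    week = np.asarray(week, dtype=float)
    if week.ndim != 1:
        raise ValueError("expected a single 1-d series")
    if week.size < 2**levels:
        raise ValueError(f"series of length {week.size} too short for {levels} levels")
    return pywt.wavedec(week, wavelet, mode=BOUNDARY_MODE, level=levels)


def _entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized squared-coefficient mass."""
    energy = coeffs**2
    total = energy.sum()
    if total == 0:
        return 0.0
    p = energy / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _mean_crossing_rate(coeffs: np.ndarray) -> float:
    centered = coeffs - coeffs.mean()
    if np.all(centered == 0):
        return 0.0
    signs = np.sign(centered)
    # a zero sits on the mean; carry the previous sign so it is not a crossing
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    if signs[0] == 0:
        nz = np.flatnonzero(signs)
        signs[0] = signs[nz[0]] if nz.size else 1
    return float((signs[1:] != signs[:-1]).sum() / (signs.size - 1))


def extract_features(subbands: list[np.ndarray]) -> np.ndarray:
    """The 7 statistics for each subband, concatenated (7 x n_subbands)."""
    feats = []
    for band in subbands:
        band = np.asarray(band, dtype=float)
        if band.size < 2:
            raise ValueError("each subband needs at least 2 coefficients")
        feats.extend(
            [
                band.mean(),
                np.percentile(band, 25),
                np.percentile(band, 75),
                _entropy(band),
                band.std(),
                band.var(),
                _mean_crossing_rate(band),
            ]
        )
    return np.asarray(feats)


def featurize_cohort(
    activity: np.ndarray, levels: int = N_LEVELS, wavelet: str = DEFAULT_WAVELET
) -> np.ndarray:
    """Feature matrix (n_participants x 7*(levels+1)) from smoothed weeks."""
    return np.vstack([extract_features(wavelet_decompose(w, levels, wavelet)) for w in activity])


@dataclass
class CrossValidationResults:
    """Per-fold validation predictions, pooled test predictions, AUCs.

    ``val_predictions`` maps fold -> (indices, probabilities); the held-out
    test probabilities are the mean over the fold models.  ``summary()``
    renders the AUC line the way a model-comparison table would.
    """

    model: str
    fold_val_aucs: np.ndarray
    val_predictions: list[tuple[np.ndarray, np.ndarray]]
    test_idx: np.ndarray
    test_probabilities: np.ndarray
    fold_test_aucs: np.ndarray
    train_probabilities_per_fold: list[np.ndarray]
    fold_test_probabilities: list[np.ndarray] | None = None

    @property
    def val_auc(self) -> tuple[float, float, float]:
        return auc_confidence_interval(self.fold_val_aucs)

    @property
    def test_auc(self) -> tuple[float, float, float]:
        return auc_confidence_interval(self.fold_test_aucs)

    def pooled_val(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.concatenate([i for i, _ in self.val_predictions])
        prob = np.concatenate([p for _, p in self.val_predictions])
        order = np.argsort(idx)
        return idx[order], prob[order]

    def summary(self) -> str:
        vm, vl, vh = self.val_auc
        tm, tl, th = self.test_auc
        lines = [
            f"{self.model}",
            "=" * len(self.model),
            f"cross-validation AUC: {vm:.3f} (95% CI {vl:.3f}-{vh:.3f}) over {len(self.fold_val_aucs)} folds",
            f"held-out test AUC:    {tm:.3f} (95% CI {tl:.3f}-{th:.3f}) (fold-model ensemble mean prob)",
        ]
        return "\n".join(lines)


class WaveletLogisticClassifier:
    """Class-weighted logistic regression on wavelet features.

    Statsmodels-style model object: construct from the feature matrix and
    labels, then ``fit(fold_plan, class_weights)`` returns a
    :class:`CrossValidationResults`.  Features are z-scored on each training
    fold; the L2 penalty is fixed very weak so the fit is effectively
    maximum likelihood.
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray, C: float = 1e4):
        features = np.asarray(features, dtype=float)
        if not np.all(np.isfinite(features)):
            bad = np.argwhere(~np.isfinite(features))
            raise ValueError(f"non-finite features at (row, col): {bad[:10].tolist()}")
        self.features = features
        self.labels = np.asarray(labels)
        self.C = C

    @classmethod
    def from_activity(cls, smoothed_activity: np.ndarray, labels: np.ndarray, **kwargs):
        return cls(featurize_cohort(smoothed_activity), labels, **kwargs)

    def fit(self, fold_plan: FoldPlan, class_weights: ClassWeights) -> CrossValidationResults:
        X, y = self.features, self.labels
        test = fold_plan.test_idx
        fold_val_aucs, fold_test_aucs = [], []
        val_predictions, test_probs, train_probs = [], [], []
        for train_idx, val_idx in fold_plan.cv_folds:
            scaler = StandardScaler().fit(X[train_idx])
            clf = LogisticRegression(C=self.C, max_iter=5000)
            clf.fit(
                scaler.transform(X[train_idx]),
                y[train_idx],
                sample_weight=class_weights.per_sample(y[train_idx]),
            )
            p_val = clf.predict_proba(scaler.transform(X[val_idx]))[:, 1]
            p_test = clf.predict_proba(scaler.transform(X[test]))[:, 1]
            train_probs.append(clf.predict_proba(scaler.transform(X[train_idx]))[:, 1])
            fold_val_aucs.append(roc_auc(p_val, y[val_idx]))
            fold_test_aucs.append(roc_auc(p_test, y[test]))
            val_predictions.append((val_idx, p_val))
            test_probs.append(p_test)
        return CrossValidationResults(
            model="wavelet logistic regression",
            fold_val_aucs=np.asarray(fold_val_aucs),
            val_predictions=val_predictions,
            test_idx=test,
            test_probabilities=np.mean(test_probs, axis=0),
            fold_test_aucs=np.asarray(fold_test_aucs),
            train_probabilities_per_fold=train_probs,
            fold_test_probabilities=test_probs,
        )
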