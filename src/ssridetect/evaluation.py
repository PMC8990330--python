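"""Classifier performance metrics: AUC with CI, cut point, 2x2 rates, PSI."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

PSI_EPSILON = 1e-4


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(probabilities)))


def auc_confidence_interval(
    fold_aucs: np.ndarray, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Mean AUC across folds with a t-interval over the per-fold values."""
    fold_aucs = np.asarray(fold_aucs, dtype=float)
    mean = float(fold_aucs.mean())
    if fold_aucs.size < 2 or np.allclose(fold_aucs, mean):
        return mean, mean, mean
    sem = stats.sem(fold_aucs)
    half = sem * stats.t.ppf(0.5 + confidence / 2, fold_aucs.size - 1)
    return mean, mean - half, mean + half


def select_cut_point(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Probability threshold maximizing Youden's J = sens + spec - 1.

    Candidate thresholds are midpoints between consecutive distinct scores;
    ties in J are broken toward the lower threshold.  If every score is
    identical no threshold separates anything and 0.5 is returned with a
    warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("cut point undefined: only one class present")
    uniq = np.unique(p)
    if uniq.size == 1:
        logger.warning("select_cut_point: constant scores, returning 0.5")
        return 0.5
    candidates = (uniq[:-1] + uniq[1:]) / 2
    n_pos = (y == 1).sum()
    n_neg = y.size - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = p > t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv_pct: float | None  # None when no positives are predicted
    npv_pct: float | None
    bac: float


def confusion_metrics(
    probabilities: np.ndarray, labels: np.ndarray, cut: float
) -> ConfusionMetrics:
    """2x2 rates at threshold ``cut`` (predicted positive iff score > cut).

    PPV/NPV are percentages; balanced accuracy is the mean of sensitivity and
    specificity.  A denominator of zero (e.g. no predicted positives) yields
    None for the affected predictive value, with a log flag.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pred = p > cut
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = 100 * tp / (tp + fp) if tp + fp else None
    npv = 100 * tn / (tn + fn) if tn + fn else None
    if ppv is None:
        logger.warning("confusion_metrics: no predicted positives, PPV undefined")
    if npv is None:
        logger.warning("confusion_metrics: no predicted negatives, NPV undefined")
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, ppv_pct=ppv, npv_pct=npv, bac=(sens + spec) / 2
    )


def population_stability_index(
    reference: np.ndarray, comparison: np.ndarray, bins: int = 10
) -> float:
    """PSI between two score samples over rank bins of the reference.

    Bin edges are the ``bins``-quantiles of the reference distribution; both
    samples are binned, proportions are floored at 1e-4, and
    PSI = sum (p_b - q_b) * ln(p_b / q_b) >= 0.
    """
    ref = np.asarray(reference, dtype=float)
    cmp_ = np.asarray(comparison, dtype=float)
    if ref.size == 0 or cmp_.size == 0:
        raise ValueError("both score sets must be non-empty")
    if ref.size < bins:
        raise ValueError(f"need at least {bins} reference scores for {bins} bins")
    edges = np.quantile(ref, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    edges = np.unique(edges)  # degenerate quantiles collapse bins
    p = np.histogram(ref, edges)[0] / ref.size
    q = np.histogram(cmp_, edges)[0] / cmp_.size
    p = np.maximum(p, PSI_EPSILON)
    q = np.maximum(q, PSI_EPSILON)
    return float(np.sum((p - q) * np.log(p / q)))


@dataclass(frozen=True)
class MetricsReport:
    """One model variant on one evaluation set, Table-style."""

    model: str
    evaluation_set: str
    auc_mean: float
    auc_ci_low: float
    auc_ci_high: float
    cut_point: float
    sensitivity: float
    specificity: float
    ppv_pct: float | None
    npv_pct: float | None
    bac: float
    psi: float
    fold_aucs: tuple = field(default=())

    def as_row(self) -> dict:
        row = {
            "model": self.model,
            "set": self.evaluation_set,
            "auc_mean": round(self.auc_mean, 4),
            "auc_ci": f"({self.auc_ci_low:.2f}-{self.auc_ci_high:.2f})",
            "cut_point": round(self.cut_point, 4),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "ppv_pct": None if self.ppv_pct is None else round(self.ppv_pct, 2),
            "npv_pct": None if self.npv_pct is None else round(self.npv_pct, 2),
            "bac": round(self.bac, 4),
            "psi": round(self.psi, 4),
        }
        return row
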