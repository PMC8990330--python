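"""Smoothing, tensor reshaping, standardization, splitting, class weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.model_selection import StratifiedKFold, train_test_split

from .synthetic import DAYS_PER_WEEK, MINUTES_PER_WEEK

HOURS_PER_DAY = 24
MINUTES_PER_HOUR = 60

DEFAULT_SAVGOL_WINDOW = 21
DEFAULT_SAVGOL_POLYORDER = 3


def smooth_week(
    week: np.ndarray,
    window: int = DEFAULT_SAVGOL_WINDOW,
    polyorder: int = DEFAULT_SAVGOL_POLYORDER,
) -> np.ndarray:
    """Savitzky-Golay smoothing of minute-level activity.

    Local least-squares polynomial smoothing reproduces any polynomial of
    degree <= ``polyorder`` exactly, so the linear morning/evening ramps are
    preserved while minute-scale spikes are attenuated.  Edges are handled by
    polynomial extrapolation of the boundary window ('interp'), which keeps
    the polynomial-reproduction property exact at minutes 0 and 10,079.
    Works on a single week (10,080,) or a cohort matrix (n, 10,080);
    smoothing is applied along the last axis.
    """
    week = np.asarray(week, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window >= week.shape[-1]:
        raise ValueError("window must be shorter than the series")
    return savgol_filter(week, window, polyorder, axis=-1, mode="interp")


def reshape_week(flat: np.ndarray) -> np.ndarray:
    """(10,080,) minute vector -> (7, 24, 60) day x hour x minute array.

    Element (d, h, m) is flat[d*1440 + h*60 + m]; also accepts a cohort
    matrix (n, 10,080) -> (n, 7, 24, 60).  Flattening the result recovers the
    input exactly.
    """
    flat = np.asarray(flat)
    if flat.shape[-1] != MINUTES_PER_WEEK:
        raise ValueError(f"expected last axis of length {MINUTES_PER_WEEK}, got {flat.shape[-1]}")
    return flat.reshape(*flat.shape[:-1], DAYS_PER_WEEK, HOURS_PER_DAY, MINUTES_PER_HOUR)


def flatten_week(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_week`."""
    tensor = np.asarray(tensor)
    if tensor.shape[-3:] != (DAYS_PER_WEEK, HOURS_PER_DAY, MINUTES_PER_HOUR):
        raise ValueError(f"expected trailing shape (7, 24, 60), got {tensor.shape[-3:]}")
    return tensor.reshape(*tensor.shape[:-3], MINUTES_PER_WEEK)


def standardize_per_minute(
    cohort: np.ndarray,
    train_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Z-score each of the 10,080 minute-of-week positions across participants.

    By default the mean/SD are computed over the full cohort (the
    reproduction-faithful mode); passing ``train_idx`` computes them on those
    rows only and applies them everywhere (leakage-safe mode).  Minute
    positions that are constant across the (training) cohort map to zero.
    Accepts a flat (n, 10,080) matrix or an (n, 7, 24, 60) tensor.
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.shape[0] < 2:
        raise ValueError("standardization needs at least 2 participants")
    ref = cohort if train_idx is None else cohort[np.asarray(train_idx)]
    if ref.shape[0] < 2:
        raise ValueError("training subset too small to standardize")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)
    nonconst = sd > 0
    return np.where(nonconst, (cohort - mean) / np.where(nonconst, sd, 1.0), 0.0)


@dataclass(frozen=True)
class FoldPlan:
    """Stratified held-out test split plus k-fold CV over the remainder.

    ``test_idx`` holds the single held-out test set (default 20%);
    ``cv_folds`` is a list of (train_idx, val_idx) pairs partitioning the
    remaining 80%, stratified by class.
    """

    test_idx: np.ndarray
    cv_folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def train_pool(self) -> np.ndarray:
        pool = np.concatenate([self.cv_folds[0][0], self.cv_folds[0][1]])
        return np.sort(pool)

    @property
    def k(self) -> int:
        return len(self.cv_folds)


def make_fold_plan(
    labels: np.ndarray,
    test_fraction: float = 0.2,
    k: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Stratified 80/20 split with stratified k-fold CV on the 80%.

    Class proportions in every subset match the global proportion to within
    one participant per class.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(np.unique(labels)) != 2:
        raise ValueError("labels must be a 1-d binary array with both classes present")
    idx = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    n_pos_train = int(labels[train_idx].sum())
    n_neg_train = int(train_idx.size - n_pos_train)
    if n_pos_train < k or n_neg_train < k:
        raise ValueError(
            f"cannot stratify {k} folds with {n_pos_train} positives / "
            f"{n_neg_train} negatives in the training pool"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_folds = [
        (np.sort(train_idx[tr]), np.sort(train_idx[va]))
        for tr, va in skf.split(train_idx, labels[train_idx])
    ]
    return FoldPlan(test_idx=np.sort(test_idx), cv_folds=cv_folds, seed=seed)


@dataclass(frozen=True)
class ClassWeights:
    """Loss multipliers: each class is weighted by the other's prevalence."""

    weight_negative: float
    weight_positive: float

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        return np.where(labels == 1, self.weight_positive, self.weight_negative)


def compute_class_weights(labels: np.ndarray) -> ClassWeights:
    """Class weights for imbalanced binary labels.

    The negative class is weighted by the positive prevalence and vice versa
    (266 positives of 7,162 gives weights 266/7162 and 6896/7162), so errors
    on the rare class carry proportionally more loss.
    """
    labels = np.asarray(labels)
    n = labels.size
    n_pos = int((labels == 1).sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    return ClassWeights(weight_negative=n_pos / n, weight_positive=n_neg / n)
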