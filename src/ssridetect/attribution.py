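"""Temporal additive attribution for the ConvLSTM classifier.

Per-minute attributions are computed by integrated gradients: the gradient of
the predicted probability is integrated along the straight path from a
background (baseline) input to the participant's input, and multiplied by the
input-baseline difference.  The path integral makes the attributions additive
— baseline output plus the summed attributions equals the model output up to
quadrature error, which is driven below a stated tolerance by adaptive step
doubling.  Attributions are computed per fold model and averaged elementwise
across folds, then summarized as minute-of-day curves with a 60-minute
rolling window, and correlated (Spearman, across participants) with raw
activity minute by minute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import flatten_week
from .synthetic import DAYS_PER_WEEK, MINUTES_PER_DAY

logger = logging.getLogger(__name__)

LOCAL_ACCURACY_TOL = 1e-3
DEFAULT_STEPS = 32
MAX_STEPS = 512
MIN_FOLDS = 5


@dataclass
class AttributionMap:
    """Fold-averaged per-participant, per-minute additive attributions."""

    values: np.ndarray  # (n_explained, 10080), signed
    participant_idx: np.ndarray  # rows of the cohort tensor explained
    base_value: float  # mean over folds of the baseline output
    fold_base_values: np.ndarray
    n_folds_used: int


def _integrated_gradients(
    net,
    x: np.ndarray,
    baseline: np.ndarray,
    phq9: np.ndarray | None,
    phq9_baseline: float,
    steps: int,
    batch_size: int = 32,
) -> np.ndarray:
    """Midpoint-rule path integral of the probability gradient; (n, 7, 24, 60)."""
    n = x.shape[0]
    total = np.zeros(x.shape[:4])
    alphas = (np.arange(steps) + 0.5) / steps
    diff = x - baseline
    # freeze parameters: only input gradients are needed on this pass
    frozen = [(p, p.requires_grad) for p in net.parameters]
    for p, _ in frozen:
        p.requires_grad = False
    try:
        for start in range(0, n, batch_size):
            stop = min(start + batch_size, n)
            acc = np.zeros(diff[start:stop].shape[:4])
            for a in alphas:
                xa = baseline + a * diff[start:stop]
                pha = None
                if phq9 is not None:
                    pha = phq9_baseline + a * (phq9[start:stop] - phq9_baseline)
                logits, x_steps = net.forward(xa, pha, training=False, return_input_tensors=True)
                p = 1.0 / (1.0 + np.exp(-logits.data))
                logits.backward(seed_grad=(p * (1.0 - p)))
                grads = np.stack([t.grad[..., 0] for t in x_steps], axis=1)  # (b, 7, 24, 60)
                acc += grads
            total[start:stop] = acc / steps * diff[start:stop, ..., 0]
    finally:
        for p, flag in frozen:
            p.requires_grad = flag
    return total


def compute_attributions(
    networks: list,
    tensor: np.ndarray,
    background_idx: np.ndarray,
    phq9: np.ndarray | None = None,
    participant_idx: np.ndarray | None = None,
    steps: int = DEFAULT_STEPS,
    tol: float = LOCAL_ACCURACY_TOL,
) -> AttributionMap:
    """Fold-averaged integrated-gradients attributions.

    ``networks`` are the fitted fold models (``results.fold_networks``);
    ``background_idx`` indexes the (seeded, typically 100-participant)
    background sample whose mean input is the attribution baseline.  Steps
    are doubled (up to a cap) until the additive-accuracy gap
    |f(x) - f(baseline) - sum(attributions)| is below ``tol`` for every
    participant; a fold that cannot meet the tolerance is excluded with a
    warning, and at least 5 folds must survive.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim == 4:
        tensor = tensor[..., None]
    if participant_idx is None:
        participant_idx = np.arange(tensor.shape[0])
    participant_idx = np.asarray(participant_idx)
    x = tensor[participant_idx]
    baseline = tensor[np.asarray(background_idx)].mean(axis=0, keepdims=True)
    ph = None if phq9 is None else np.asarray(phq9, float)[participant_idx]
    ph_base = 0.0 if phq9 is None else float(np.asarray(phq9, float)[background_idx].mean())

    fold_maps, fold_bases = [], []
    for fold, net in enumerate(networks):
        p_x = net.predict_proba(x, ph)
        p_base = float(net.predict_proba(baseline, None if ph is None else np.array([ph_base]))[0])
        n_steps = steps
        while True:
            phi = _integrated_gradients(net, x, baseline, ph, ph_base, n_steps)
            gap = np.abs(p_x - p_base - phi.sum(axis=(1, 2, 3)))
            if phq9 is not None:
                # the PHQ-9 path carries part of the output change; its share
                # is the remainder and is not part of the temporal map
                gap = np.abs(
                    p_x - p_base - phi.sum(axis=(1, 2, 3)) - _phq9_share(net, x, baseline, ph, ph_base, n_steps)
                )
            if gap.max() <= tol or n_steps >= MAX_STEPS:
                break
            n_steps *= 2
        if gap.max() > tol:
            logger.warning(
                "fold %d: additive accuracy %.2e above tolerance %.0e, fold excluded",
                fold,
                gap.max(),
                tol,
            )
            continue
        fold_maps.append(flatten_week(phi))
        fold_bases.append(p_base)
    if len(fold_maps) < MIN_FOLDS:
        raise RuntimeError(
            f"only {len(fold_maps)} folds met the additive-accuracy tolerance "
            f"(need >= {MIN_FOLDS})"
        )
    return AttributionMap(
        values=np.mean(fold_maps, axis=0),
        participant_idx=participant_idx,
        base_value=float(np.mean(fold_bases)),
        fold_base_values=np.asarray(fold_bases),
        n_folds_used=len(fold_maps),
    )


def _phq9_share(net, x, baseline, ph, ph_base, steps) -> np.ndarray:
    """Attribution mass carried by the PHQ-9 input along the same path."""
    alphas = (np.arange(steps) + 0.5) / steps
    diff_x = x - baseline
    diff_p = ph - ph_base
    acc = np.zeros(x.shape[0])
    eps = 1e-4
    for a in alphas:
        xa = baseline + a * diff_x
        pa = ph_base + a * diff_p
        up = net.predict_proba(xa, pa + eps)
        down = net.predict_proba(xa, pa - eps)
        acc += (up - down) / (2 * eps)
    return acc / steps * diff_p


def rolling_minute_mean(curve: np.ndarray, window: int = 60) -> np.ndarray:
    """Centered rolling mean over minute-of-day, edges truncated, NaN-aware."""
    return (
        pd.Series(np.asarray(curve, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def summarize_attributions(attribution_map: AttributionMap, window: int = 60) -> np.ndarray:
    """Minute-of-day attribution curve: participant- and day-averaged, smoothed.

    Attributions are averaged across participants and across the 7 days to a
    1,440-minute curve, then smoothed with a centered ``window``-minute
    rolling mean (edges truncated to the available support).
    """
    per_minute = attribution_map.values.mean(axis=0)
    daily = per_minute.reshape(DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=0)
    return rolling_minute_mean(daily, window)


def attribution_activity_correlation(
    activity: np.ndarray, attribution_map: AttributionMap, window: int = 60
) -> np.ndarray:
    """Per-minute Spearman rho between raw activity and attributions.

    Both inputs are day-averaged to (participants x 1,440); for each minute
    of the day the Spearman rank correlation across participants is computed
    and the resulting curve smoothed with a centered 60-minute rolling mean.
    Zero-variance minutes give an undefined rho, recorded as NaN and skipped
    by the rolling mean.
    """
    act = np.asarray(activity, dtype=float)[attribution_map.participant_idx]
    if act.shape[1] != attribution_map.values.shape[1]:
        raise ValueError("activity and attribution shapes do not match")
    n = act.shape[0]
    act_day = act.reshape(n, DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=1)
    att_day = attribution_map.values.reshape(n, DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=1)

    ra = rankdata(act_day, axis=0)
    rb = rankdata(att_day, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (ra * rb).sum(axis=0) / np.where(denom > 0, denom, 1.0), np.nan)
    n_undefined = int(np.isnan(rho).sum())
    if n_undefined:
        logger.info("attribution_activity_correlation: %d undefined minutes", n_undefined)
    return rolling_minute_mean(rho, window)
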