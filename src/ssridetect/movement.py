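"""Descriptive movement phenotype: group means, ramp slopes, Table-1 tests.

These are the group-level rest-activity statistics: each group's mean
vertical-acceleration counts/min with a normal-approximation 95% CI over
participant means, ordinary-least-squares slopes of the participant- and
day-averaged minute-of-day curve over the 6-9 am and 6-9 pm windows (with
participant-bootstrap CIs), and the chi-square / Welch-t demographic
comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import smooth_week
from .synthetic import DAYS_PER_WEEK, EVENING_WINDOW, MINUTES_PER_DAY, MORNING_WINDOW

INTERVALS = {"morning": MORNING_WINDOW, "evening": EVENING_WINDOW}


@dataclass(frozen=True)
class GroupMean:
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class GroupCurve:
    """Minute-of-day mean counts/min (participant- and day-averaged) + 95% CI."""

    mean: np.ndarray  # (1440,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float  # counts/min^2
    ci_low: float
    ci_high: float
    interval: str


def _participant_day_curves(activity: np.ndarray) -> np.ndarray:
    """(n, 10080) -> (n, 1440) day-averaged minute-of-day curves."""
    activity = np.asarray(activity, dtype=float)
    n = activity.shape[0]
    return activity.reshape(n, DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=1)


def group_mean_activity(
    activity: np.ndarray, labels: np.ndarray, confidence: float = 0.95
) -> dict[str, GroupMean]:
    """Whole-week mean counts/min per group with a normal-approximation CI.

    Each participant contributes their mean over 10,080 minutes; the group
    mean and its CI are computed over those participant means.
    """
    labels = np.asarray(labels)
    out = {}
    z = stats.norm.ppf(0.5 + confidence / 2)
    for name, mask in (("exposed", labels == 1), ("control", labels == 0)):
        if not mask.any():
            raise ValueError(f"group '{name}' is empty")
        per_participant = np.asarray(activity, dtype=float)[mask].mean(axis=1)
        m = per_participant.mean()
        se = per_participant.std(ddof=1) / np.sqrt(per_participant.size) if per_participant.size > 1 else 0.0
        out[name] = GroupMean(float(m), float(m - z * se), float(m + z * se), int(mask.sum()))
    return out


def group_curve(
    activity: np.ndarray, smooth: bool = True, confidence: float = 0.95
) -> GroupCurve:
    """Participant- and day-averaged minute-of-day curve with pointwise CI."""
    curves = _participant_day_curves(activity)
    if smooth:
        curves = smooth_week(curves) if curves.shape[1] >= 21 else curves
    mean = curves.mean(axis=0)
    n = curves.shape[0]
    z = stats.norm.ppf(0.5 + confidence / 2)
    se = curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return GroupCurve(mean=mean, ci_low=mean - z * se, ci_high=mean + z * se, n=n)


def _ols_slope(y: np.ndarray, t: np.ndarray) -> float:
    t_c = t - t.mean()
    return float((t_c * (y - y.mean())).sum() / (t_c**2).sum())


def interval_slope(
    activity: np.ndarray,
    interval: str | tuple[int, int],
    smooth: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
) -> SlopeEstimate:
    """OLS slope of the group mean curve over a minute-of-day interval.

    ``interval`` is 'morning' ([360, 540): 6-9 am), 'evening' ([1080, 1260):
    6-9 pm), or an explicit half-open (start, stop) pair.  The slope is fit
    to the smoothed, participant- and day-averaged curve in raw counts/min
    per minute; the CI is a seeded participant-level bootstrap percentile
    interval over ``n_boot`` resamples.
    """
    name = interval if isinstance(interval, str) else f"[{interval[0]},{interval[1]})"
    lo, hi = INTERVALS[interval] if isinstance(interval, str) else interval
    if not (0 <= lo < hi <= MINUTES_PER_DAY):
        raise ValueError(f"interval must lie within [0, {MINUTES_PER_DAY})")
    if hi - lo < 3:
        raise ValueError("interval must span at least 3 minutes")
    curves = _participant_day_curves(activity)
    if smooth:
        curves = smooth_week(curves)
    t = np.arange(lo, hi, dtype=float)
    point = _ols_slope(curves.mean(axis=0)[lo:hi], t)
    n = curves.shape[0]
    if n_boot > 0 and n > 1:
        rng = np.random.default_rng(seed)
        seg = curves[:, lo:hi]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.integers(0, n, n)
            boots[b] = _ols_slope(seg[take].mean(axis=0), t)
        alpha = 1 - confidence
        ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        ci_low = ci_high = point
    return SlopeEstimate(slope=point, ci_low=float(ci_low), ci_high=float(ci_high), interval=name)


def demographic_tests(
    demographics: pd.DataFrame,
    labels: np.ndarray,
    phq9: np.ndarray | None = None,
    age_column: str = "age",
) -> pd.DataFrame:
    """Group comparison table: chi-square for categoricals, Welch t for means.

    Sex and race/ethnicity are compared with the chi-square test of
    independence; age and (where provided) PHQ-9 with the two-sided Welch
    unequal-variance t test.  Returns a tidy table with statistic, p-value
    and a significance flag at p < .05.
    """
    labels = np.asarray(labels)
    rows = []
    for col in ("sex", "race"):
        if col not in demographics:
            continue
        table = pd.crosstab(demographics[col], labels)
        expected = stats.contingency.expected_freq(table.to_numpy())
        if (expected == 0).any():
            raise ValueError(f"chi-square for '{col}': zero expected cell count\n{table}")
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
        rows.append({"variable": col, "test": "chi-square", "statistic": chi2, "p_value": p})
    continuous = {age_column: demographics[age_column].to_numpy(dtype=float)}
    if phq9 is not None:
        continuous["phq9"] = np.asarray(phq9, dtype=float)
    for name, values in continuous.items():
        a = values[(labels == 1) & ~np.isnan(values)]
        b = values[(labels == 0) & ~np.isnan(values)]
        if a.size < 2 or b.size < 2:
            raise ValueError(f"t test for '{name}': group with fewer than 2 observations")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": name, "test": "welch-t", "statistic": t, "p_value": p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < 0.05
    return out


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided Welch t test from summary statistics (mean, SD, n) alone."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)
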