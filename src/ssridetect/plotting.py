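"""Basic numeric plots: group activity curves and attribution summaries."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_group_curves(curves: dict, ax=None):
    """Minute-of-day mean activity per group with CI bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    hours = np.arange(1440) / 60
    for name, curve in curves.items():
        ax.plot(hours, curve.mean, label=name)
        ax.fill_between(hours, curve.ci_low, curve.ci_high, alpha=0.2)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("vertical acceleration counts/min")
    ax.set_xlim(0, 24)
    ax.legend()
    return ax


def plot_attribution_summary(summary: np.ndarray, rho: np.ndarray | None = None, ax=None):
    """Smoothed minute-of-day attribution curve, optionally with Spearman rho."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    hours = np.arange(len(summary)) / 60
    ax.plot(hours, summary, color="tab:red", label="mean attribution")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("attribution")
    if rho is not None:
        ax2 = ax.twinx()
        ax2.plot(hours, rho, color="tab:blue", alpha=0.7, label="Spearman rho")
        ax2.set_ylabel("Spearman rho")
        ax2.set_ylim(-1, 1)
    ax.set_xlim(0, 24)
    ax.legend(loc="upper left")
    return ax
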