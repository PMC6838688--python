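"""Standard figures: intensity-response curve with the fitted sigmoid, the
sorted peak-RMS threshold plot, and the binned I50 time course."""

from __future__ import annotations

from typing import Optional

import numpy as np


def plot_response_curve(curve, fit=None, ax=None):
    """oPD ratio per level with the fitted Boltzmann overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(curve.level, curve.ratio, "o", color="k", ms=4, label="observed")
    if fit is not None:
        xs = np.linspace(curve.level.min(), curve.level.max(), 200)
        ax.plot(xs, fit.f(xs), "-", color="tab:red",
                label=f"Boltzmann (I50={fit.a:.2f}, b={fit.b:.2f})")
        ax.axvline(fit.a, color="tab:red", lw=0.8, ls=":")
        ax.axhline(0.5, color="0.6", lw=0.8, ls=":")
    ax.set_xlabel("intensity (level)")
    ax.set_ylabel("P(PD)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_sorted_peaks(per_level: dict, threshold: Optional[float] = None,
                      ax=None):
    """Per-level descending-sorted max-RMS statistics (threshold plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    cmap = plt.get_cmap("viridis")
    levels = sorted(per_level)
    for i, lvl in enumerate(levels):
        vals = per_level[lvl]
        ax.plot(np.arange(1, len(vals) + 1), vals, ".", ms=3,
                color=cmap(i / max(len(levels) - 1, 1)))
    if threshold is not None:
        ax.axhline(threshold, color="k", lw=1.0, ls="--", label="threshold")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("sorted trial rank")
    ax.set_ylabel("max RMS of 2nd derivative")
    ax.set_yscale("log")
    return ax


def plot_timecourse(timecourse, ax=None):
    """Normalized binned-I50 series over a session."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    mid = (timecourse["bin_start_s"] + timecourse["bin_end_s"]) / 2.0
    ax.plot(mid / 60.0, timecourse["i50_normalized"], "o-", color="k", ms=4)
    ax.axhline(0.0, color="0.6", lw=0.8, ls=":")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("I50 - session I50 (levels)")
    return ax
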