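"""Hypnogram and actogram figures.

Output is deterministic: rendering the same input twice produces
byte-identical SVG (fixed hash salt, no embedded date), which makes the
figures themselves regression-testable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .types import Hypnogram, State, StateSchedule

__all__ = ["render_hypnogram", "render_actogram"]

_SVG_META = {"Date": None, "Creator": "homecage"}


def _savefig(fig, path) -> None:
    path = Path(path)
    with matplotlib.rc_context({"svg.hashsalt": "homecage", "svg.fonttype": "none"}):
        if path.suffix.lower() == ".svg":
            fig.savefig(path, metadata=_SVG_META)
        else:
            fig.savefig(path)
    plt.close(fig)


def render_hypnogram(hypnogram: Hypnogram, path, schedule: StateSchedule | None = None):
    """Step plot of scored state against time, optionally with the
    ground-truth schedule overlaid for synthetic data."""
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    fig, ax = plt.subplots(figsize=(10, 2.5))
    t = hypnogram.times_s / 3600.0
    y = np.where(hypnogram.states == int(State.MISSING), np.nan, hypnogram.states)
    ax.step(t, y, where="post", lw=0.8, color="k", label="scored")
    if schedule is not None:
        ts = np.asarray(hypnogram.times_s, dtype=float)
        truth = schedule.states_at(ts)
        ax.step(ts / 3600.0, truth + 0.05, where="post", lw=0.8, color="r", alpha=0.6,
                label="ground truth")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_yticks([0, 1])
    ax.set_yticklabels(["SLEEP", "WAKE"])
    ax.set_xlabel("time (h)")
    ax.set_ylim(-0.3, 1.35)
    fig.tight_layout()
    _savefig(fig, path)
    return Path(path)


def render_actogram(
    hypnogram: Hypnogram,
    path,
    bin_s: float = 600.0,
    lights_on_s: float | None = None,
    lights_off_s: float | None = None,
):
    """Double-plotted actogram: one row per 24 h, each row showing that
    day and the next side by side; bar height is the fraction of each
    bin spent awake."""
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    total_s = len(hypnogram) * hypnogram.epoch_s
    n_days = max(1, int(np.ceil(total_s / 86400.0)))
    bins_per_day = int(round(86400.0 / bin_s))

    epochs_per_bin = max(1, int(round(bin_s / hypnogram.epoch_s)))
    states = hypnogram.states
    n_bins_total = n_days * bins_per_day
    activity = np.full(n_bins_total, np.nan)
    for b in range(n_bins_total):
        seg = states[b * epochs_per_bin : (b + 1) * epochs_per_bin]
        seg = seg[seg != int(State.MISSING)]
        if len(seg):
            activity[b] = np.mean(seg == int(State.WAKE))

    fig, axes = plt.subplots(
        n_days, 1, figsize=(10, 0.9 * n_days + 0.8), sharex=True, squeeze=False
    )
    x = (np.arange(2 * bins_per_day) + 0.5) * bin_s / 3600.0
    for d in range(n_days):
        ax = axes[d, 0]
        row = np.full(2 * bins_per_day, np.nan)
        today = activity[d * bins_per_day : (d + 1) * bins_per_day]
        row[: len(today)] = today
        nxt = activity[(d + 1) * bins_per_day : (d + 2) * bins_per_day]
        row[bins_per_day : bins_per_day + len(nxt)] = nxt
        ax.bar(x, np.nan_to_num(row), width=bin_s / 3600.0, color="k")
        if lights_on_s is not None and lights_off_s is not None:
            for offset in (0.0, 24.0):
                ax.axvspan(
                    offset + lights_on_s / 3600.0,
                    offset + lights_off_s / 3600.0,
                    color="gold",
                    alpha=0.15,
                    lw=0,
                )
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(f"day {d + 1}", rotation=0, ha="right", va="center", fontsize=8)
    axes[-1, 0].set_xlabel("time (h, double-plotted)")
    axes[-1, 0].set_xlim(0, 48)
    fig.tight_layout()
    _savefig(fig, path)
    return Path(path)
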