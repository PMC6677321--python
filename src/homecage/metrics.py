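"""Hypnogram comparison, bout statistics, and day/night summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Hypnogram, State, runs

__all__ = ["ComparisonResult", "accuracy", "bout_durations", "day_night_summary"]


@dataclass(frozen=True)
class ComparisonResult:
    """Epochwise agreement between two hypnograms.

    ``accuracy`` is the fraction of compared time in which the two
    scorings assign the same state (agreement); ``disagreement_s`` is the
    complementary time in seconds. Epochs that are MISSING in either
    input are excluded from both numerator and denominator and counted
    in ``n_missing``.
    """

    accuracy: float
    disagreement_s: float
    n_epochs: int
    compared_s: float
    n_missing: int = 0


def accuracy(hyp_a: Hypnogram, hyp_b: Hypnogram, epoch_s: float = 1.0) -> ComparisonResult:
    """Agreement between two hypnograms on a common epoch grid.

    Both inputs are resampled (majority state) onto a shared grid
    covering the overlap of their supports; matching time divided by
    compared time gives the accuracy. Symmetric in its arguments.
    """
    t0 = max(hyp_a.t0_s, hyp_b.t0_s)
    t1 = min(hyp_a.end_s, hyp_b.end_s)
    n = int(np.floor((t1 - t0) / epoch_s + 1e-9))
    if n < 1:
        raise ValueError("hypnograms have no overlapping support")
    a = hyp_a.resample(epoch_s, t0, n).states
    b = hyp_b.resample(epoch_s, t0, n).states
    valid = (a != int(State.MISSING)) & (b != int(State.MISSING))
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no overlapping non-missing epochs")
    matches = int(np.sum(a[valid] == b[valid]))
    acc = matches / n_valid
    return ComparisonResult(
        accuracy=acc,
        disagreement_s=(n_valid - matches) * epoch_s,
        n_epochs=n_valid,
        compared_s=n_valid * epoch_s,
        n_missing=int(n - n_valid),
    )


def bout_durations(
    hypnogram: Hypnogram, state: State, density_points: int = 200
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Maximal runs of ``state`` with a log-duration kernel density.

    Returns a bout table (state, start_s, duration_s) and, when at least
    two distinct durations exist, a Gaussian-kernel density estimate of
    the bout-duration distribution evaluated on a log-spaced grid
    (columns duration_s, density; density is per log-duration).
    """
    state = State(state)
    table_rows = []
    for start, stop, value in runs(hypnogram.states):
        if value == int(state):
            table_rows.append(
                {
                    "state": state.name,
                    "start_s": hypnogram.t0_s + start * hypnogram.epoch_s,
                    "duration_s": (stop - start) * hypnogram.epoch_s,
                }
            )
    table = pd.DataFrame(table_rows, columns=["state", "start_s", "duration_s"])
    density = None
    durations = table["duration_s"].to_numpy(float)
    if len(durations) >= 2 and np.ptp(durations) > 0:
        from scipy.stats import gaussian_kde

        log_d = np.log(durations)
        kde = gaussian_kde(log_d)
        grid = np.linspace(log_d.min() - 1.0, log_d.max() + 1.0, density_points)
        density = pd.DataFrame(
            {"duration_s": np.exp(grid), "density": kde(grid)}
        )
    return table, density


def day_night_summary(
    hypnogram: Hypnogram, lights_on_s: float, lights_off_s: float
) -> dict[str, float]:
    """Percent of time awake within each light phase.

    Phases are half-open intervals on the 24-h recording clock: day
    (lights on) is ``[lights_on_s, lights_off_s)`` modulo 24 h, night the
    complement. Each epoch is assigned by its start time; MISSING epochs
    are excluded.
    """
    day_len = (lights_off_s - lights_on_s) % 86400.0
    if day_len == 0:
        raise ValueError("light phases must have nonzero length")
    tod = hypnogram.times_s % 86400.0
    in_day = ((tod - lights_on_s) % 86400.0) < day_len
    states = hypnogram.states
    out = {}
    for name, sel in (("day", in_day), ("night", ~in_day)):
        phase_states = states[sel]
        valid = phase_states != int(State.MISSING)
        n_valid = int(valid.sum())
        if n_valid == 0:
            out[f"{name}_pct_wake"] = float("nan")
        else:
            out[f"{name}_pct_wake"] = (
                100.0 * np.sum(phase_states[valid] == int(State.WAKE)) / n_valid
            )
    return out
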