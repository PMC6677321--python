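"""Core data containers shared across the analysis pipeline.

Everything downstream of the camera is expressed in terms of five simple
containers: a lazy :class:`FrameStream` of grayscale frames, a uniformly
sampled scalar :class:`MotionSignal`, a centroid :class:`Trajectory`, a
binary sleep/wake :class:`Hypnogram` on a fixed epoch grid, and an
:class:`EphysRecording` holding EMG and/or hippocampal LFP channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Callable, Iterator

import numpy as np
import pandas as pd


class State(IntEnum):
    """Behavioural state code used throughout.

    SLEEP/WAKE are the two scored states; MISSING marks epochs with no
    usable data (dropped frames, gaps in the timestamp record).
    """

    SLEEP = 0
    WAKE = 1
    MISSING = -1


STATE_NAMES = {State.SLEEP: "SLEEP", State.WAKE: "WAKE", State.MISSING: "MISSING"}
NAME_TO_STATE = {v: k for k, v in STATE_NAMES.items()}


@dataclass(frozen=True)
class StateSchedule:
    """Ground-truth sequence of sleep/wake bouts.

    Epochs are ``(start_s, end_s, state)`` triples that are contiguous,
    non-overlapping and cover ``[0, total_duration_s)``.
    """

    epochs: tuple[tuple[float, float, State], ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be positive")
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        prev_end = 0.0
        for start, end, state in self.epochs:
            if end <= start:
                raise ValueError("epoch durations must be positive")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("epochs must be contiguous from time 0")
            if State(state) is State.MISSING:
                raise ValueError("schedule states must be SLEEP or WAKE")
            prev_end = end
        if abs(prev_end - self.total_duration_s) > 1e-9:
            raise ValueError("epochs must cover [0, total_duration_s)")

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([e[0] for e in self.epochs] + [self.total_duration_s])

    def states_at(self, times_s: np.ndarray) -> np.ndarray:
        """State label for each time point (int8 array of State values)."""
        times_s = np.asarray(times_s, dtype=float)
        idx = np.searchsorted(self.boundaries, times_s, side="right") - 1
        idx = np.clip(idx, 0, len(self.epochs) - 1)
        labels = np.array([int(e[2]) for e in self.epochs], dtype=np.int8)
        return labels[idx]

    def to_hypnogram(self, epoch_s: float = 1.0) -> "Hypnogram":
        """Sample the schedule onto a uniform epoch grid (state at epoch midpoint;
        exact because the schedule is piecewise constant on a coarser grid)."""
        n = int(round(self.total_duration_s / epoch_s))
        mids = (np.arange(n) + 0.5) * epoch_s
        return Hypnogram(states=self.states_at(mids), epoch_s=epoch_s, t0_s=0.0)


@dataclass
class FrameStream:
    """Ordered grayscale frames with per-frame timestamps.

    ``frames`` is re-iterable: each ``iter()`` restarts from the first
    frame, which lets several analyses consume the same (possibly
    synthetic, generated on the fly) stream.
    """

    frame_factory: Callable[[], Iterator[np.ndarray]]
    timestamps_s: np.ndarray
    fps_nominal: float
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.timestamps_s.ndim != 1 or len(self.timestamps_s) == 0:
            raise ValueError("timestamps_s must be a non-empty 1-D array")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.fps_nominal <= 0:
            raise ValueError("fps_nominal must be positive")

    def __iter__(self) -> Iterator[np.ndarray]:
        return self.frame_factory()

    def __len__(self) -> int:
        return len(self.timestamps_s)


@dataclass
class MotionSignal:
    """Uniformly sampled per-frame motion magnitude (fraction of frame area)."""

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.values), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.missing) != len(self.values):
            raise ValueError("missing mask must match values length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times_s, "motion": self.values, "missing": self.missing.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotionSignal":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("motion signal file must contain at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("motion signal file must be uniformly sampled")
        missing = df["missing"].to_numpy(bool) if "missing" in df else None
        return cls(df["motion"].to_numpy(float), rate_hz=1.0 / dt[0], t0_s=t[0], missing=missing)


@dataclass
class Trajectory:
    """Centroid track in pixel coordinates with a per-sample missing flag."""

    time_s: np.ndarray
    row: np.ndarray
    col: np.ndarray
    missing: np.ndarray
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.row = np.asarray(self.row, dtype=float)
        self.col = np.asarray(self.col, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.time_s)
        if not (len(self.row) == len(self.col) == len(self.missing) == n):
            raise ValueError("trajectory arrays must share one length")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "time_s": self.time_s,
                "row": self.row,
                "col": self.col,
                "missing": self.missing.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(float),
            df["row"].to_numpy(float),
            df["col"].to_numpy(float),
            df["missing"].to_numpy(bool),
        )


@dataclass
class Hypnogram:
    """Binary sleep/wake state sequence on a uniform epoch grid."""

    states: np.ndarray
    epoch_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        valid = np.isin(self.states, [int(s) for s in State])
        if not valid.all():
            raise ValueError("states must be SLEEP, WAKE or MISSING codes")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times_s(self) -> np.ndarray:
        """Epoch start times."""
        return self.t0_s + np.arange(len(self.states)) * self.epoch_s

    @property
    def end_s(self) -> float:
        return self.t0_s + len(self.states) * self.epoch_s

    def duration_in(self, state: State) -> float:
        return float(np.sum(self.states == int(state)) * self.epoch_s)

    def resample(self, epoch_s: float, t0_s: float, n_epochs: int) -> "Hypnogram":
        """Majority-state resampling onto an arbitrary uniform grid.

        Each target epoch takes the state occupying most of its span
        (piecewise-constant source; oversample at 10 points per target
        epoch). Spans outside the source support are MISSING.
        """
        oversample = 10
        fine = t0_s + (np.arange(n_epochs * oversample) + 0.5) * (epoch_s / oversample)
        src_idx = np.floor((fine - self.t0_s) / self.epoch_s).astype(int)
        inside = (src_idx >= 0) & (src_idx < len(self.states))
        fine_states = np.full(len(fine), int(State.MISSING), dtype=np.int8)
        fine_states[inside] = self.states[src_idx[inside]]
        fine_states = fine_states.reshape(n_epochs, oversample)
        out = np.empty(n_epochs, dtype=np.int8)
        counts = {
            code: (fine_states == code).sum(axis=1)
            for code in (int(State.SLEEP), int(State.WAKE), int(State.MISSING))
        }
        out[:] = int(State.MISSING)
        sw = np.stack([counts[int(State.SLEEP)], counts[int(State.WAKE)]])
        has_data = sw.sum(axis=0) > counts[int(State.MISSING)]
        # ties between SLEEP and WAKE resolve to SLEEP (argmax picks first row)
        winner = np.where(sw[0] >= sw[1], int(State.SLEEP), int(State.WAKE))
        out[has_data] = winner[has_data]
        return Hypnogram(out, epoch_s=epoch_s, t0_s=t0_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "state": [STATE_NAMES[State(s)] for s in self.states],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("hypnogram file must contain at least two epochs")
        epoch = float(t[1] - t[0])
        states = np.array([int(NAME_TO_STATE[s]) for s in df["state"]], dtype=np.int8)
        return cls(states, epoch_s=epoch, t0_s=float(t[0]))


@dataclass
class EphysRecording:
    """EMG and/or LFP channels sampled at ``fs`` Hz, time-locked to the video."""

    fs: float
    emg: np.ndarray | None = None
    lfp: np.ndarray | None = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.emg is None and self.lfp is None:
            raise ValueError("recording must contain at least one channel")
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=np.float32)
        if self.lfp is not None:
            self.lfp = np.asarray(self.lfp, dtype=np.float32)
        if self.emg is not None and self.lfp is not None and len(self.emg) != len(self.lfp):
            raise ValueError("EMG and LFP must have equal length")

    def __len__(self) -> int:
        ch = self.emg if self.emg is not None else self.lfp
        return len(ch)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def to_csv(self, path) -> None:
        cols = {"time_s": self.t0_s + np.arange(len(self)) / self.fs}
        if self.emg is not None:
            cols["emg"] = self.emg
        if self.lfp is not None:
            cols["lfp"] = self.lfp
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "EphysRecording":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer fs from fewer than two samples")
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(
            fs=fs,
            emg=df["emg"].to_numpy(np.float32) if "emg" in df else None,
            lfp=df["lfp"].to_numpy(np.float32) if "lfp" in df else None,
            t0_s=float(t[0]) if len(t) else 0.0,
        )


def runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of an integer sequence as (start, stop, value)."""
    values = np.asarray(values)
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(values)]])
    return [(int(a), int(b), int(values[a])) for a, b in zip(starts, stops)]
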