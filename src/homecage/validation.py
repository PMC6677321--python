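"""Reference study conditions for end-to-end validation.

One function simulates a coupled recording - video, EMG and LFP driven
by the same sleep/wake schedule - under the conditions used throughout
the package's validation: a 2-h recording, 320x240 video at 15 fps,
4 kHz electrophysiology, exponential bouts with 300-s mean and 60-s
minimum. Both the test suite and the acceptance script build on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import accuracy
from .motion import MotionConfig, motion_signal
from .scoring import (
    EmgScoringConfig,
    LfpScoringConfig,
    VideoScoringConfig,
    score_emg,
    score_lfp_emg,
    score_video,
)
from .synthetic import EphysConfig, SceneConfig, make_schedule, render_ephys, render_video
from .types import Hypnogram, MotionSignal, State, StateSchedule, Trajectory

__all__ = ["CoupledRun", "simulate_coupled_run", "agreement_summary"]


@dataclass
class CoupledRun:
    """Everything the cross-scorer comparisons need from one simulation."""

    seed: int
    schedule: StateSchedule
    truth: Hypnogram
    motion: MotionSignal
    trajectory: Trajectory
    hyp_video: Hypnogram
    hyp_emg: Hypnogram
    hyp_lfp_emg: Hypnogram | None


def simulate_coupled_run(
    seed: int,
    duration_s: float = 7200.0,
    fps: float = 15.0,
    frame_size: tuple[int, int] = (240, 320),
    fs: float = 4000.0,
    mean_bout_s: float = 300.0,
    min_bout_s: float = 60.0,
    motion_config: MotionConfig | None = None,
    video_config: VideoScoringConfig | None = None,
    emg_config: EmgScoringConfig | None = None,
    lfp_config: LfpScoringConfig | None = None,
    score_lfp: bool = True,
) -> CoupledRun:
    """Simulate one coupled recording and score it three ways."""
    schedule = make_schedule(
        duration_s,
        {State.SLEEP: mean_bout_s, State.WAKE: mean_bout_s},
        min_bout_s=min_bout_s,
        seed=seed,
    )
    scene = SceneConfig(frame_size=frame_size, fps=fps, seed=seed)
    stream, trajectory = render_video(schedule, scene)
    motion = motion_signal(stream, motion_config)
    rec = render_ephys(schedule, EphysConfig(fs=fs, seed=seed))
    return CoupledRun(
        seed=seed,
        schedule=schedule,
        truth=schedule.to_hypnogram(),
        motion=motion,
        trajectory=trajectory,
        hyp_video=score_video(motion, video_config),
        hyp_emg=score_emg(rec.emg, rec.fs, emg_config),
        hyp_lfp_emg=(
            score_lfp_emg(rec.lfp, rec.emg, rec.fs, lfp_config, emg_config)
            if score_lfp
            else None
        ),
    )


def agreement_summary(run: CoupledRun) -> dict[str, float]:
    """The headline cross-scorer agreements for one run (fractions)."""
    out = {
        "video_vs_emg": accuracy(run.hyp_video, run.hyp_emg).accuracy,
        "video_vs_truth": accuracy(run.hyp_video, run.truth).accuracy,
        "emg_vs_truth": accuracy(run.hyp_emg, run.truth).accuracy,
    }
    if run.hyp_lfp_emg is not None:
        out["lfp_emg_vs_emg"] = accuracy(run.hyp_lfp_emg, run.hyp_emg).accuracy
    return out
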