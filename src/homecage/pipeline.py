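"""End-to-end analysis pipeline and parameter sweeps."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .metrics import accuracy
from .motion import motion_signal
from .plots import render_actogram, render_hypnogram
from .scoring import score_emg, score_video
from .tracking import track
from .types import EphysRecording, Hypnogram, MotionSignal
from .video_io import open_stream

__all__ = ["run_pipeline", "sweep", "SWEEPABLE_PARAMETERS"]

log = logging.getLogger("homecage")

SWEEPABLE_PARAMETERS = ("min_sleep_s", "integrate_window_s")


def run_pipeline(
    video_path,
    ephys_path=None,
    config: RunConfig | None = None,
    outdir="hcm_output",
    timestamps_path=None,
    do_tracking: bool = True,
) -> Path:
    """Run motion detection, tracking and sleep/wake scoring on a video,
    optionally scoring a coupled EMG recording and comparing the two.

    Writes motion.csv, traj.csv, hypnogram_video.csv, figures and - with
    ephys - hypnogram_emg.csv plus a comparison report. A manifest JSON
    records the configuration and which stages completed, so a partial
    failure still leaves an account of what ran.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "video": str(video_path),
            "ephys": str(ephys_path) if ephys_path else None,
        },
        "stages": {},
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, manifest)
            raise
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    stream = _stage(
        "open", lambda: open_stream(video_path, timestamps_path, fps_nominal=config.fps)
    )
    motion = _stage("motion", lambda: motion_signal(stream, config.motion))
    motion.to_csv(outdir / "motion.csv")

    if do_tracking:
        traj = _stage("track", lambda: track(stream, config.tracking))
        traj.to_csv(outdir / "traj.csv")

    hyp_video = _stage("score_video", lambda: score_video(motion, config.video_scoring))
    hyp_video.to_csv(outdir / "hypnogram_video.csv")
    _stage(
        "figures",
        lambda: (
            render_hypnogram(hyp_video, outdir / "hypnogram_video.svg"),
            render_actogram(hyp_video, outdir / "actogram_video.svg"),
        ),
    )

    if ephys_path is not None:
        rec = _stage(
            "load_ephys", lambda: EphysRecording.from_csv(ephys_path, fs=config.ephys_fs)
        )
        hyp_emg = _stage(
            "score_emg", lambda: score_emg(rec.emg, rec.fs, config.emg_scoring)
        )
        hyp_emg.to_csv(outdir / "hypnogram_emg.csv")
        cmp_result = _stage("compare", lambda: accuracy(hyp_video, hyp_emg))
        (outdir / "report.json").write_text(
            json.dumps(
                {
                    "accuracy": cmp_result.accuracy,
                    "disagreement_s": cmp_result.disagreement_s,
                    "compared_s": cmp_result.compared_s,
                    "n_epochs": cmp_result.n_epochs,
                    "n_missing": cmp_result.n_missing,
                },
                indent=2,
            )
        )
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def sweep(
    parameter_name: str,
    values,
    motion: MotionSignal,
    reference: Hypnogram,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Video/EMG agreement as a function of one video-scoring parameter.

    ``parameter_name`` must be ``min_sleep_s`` or ``integrate_window_s``;
    the motion signal is re-scored at each value and compared to the
    reference (typically EMG-derived) hypnogram.
    """
    if parameter_name not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter_name!r}; "
            f"choose one of {SWEEPABLE_PARAMETERS}"
        )
    config = config or RunConfig()
    rows = []
    for v in values:
        vs_cfg = _replace_video(config.video_scoring, parameter_name, float(v))
        hyp = score_video(motion, vs_cfg)
        res = accuracy(hyp, reference)
        rows.append(
            {
                parameter_name: float(v),
                "accuracy": res.accuracy,
                "disagreement_s": res.disagreement_s,
                "n_epochs": res.n_epochs,
            }
        )
    return pd.DataFrame(rows)


def _replace_video(cfg, name, value):
    import dataclasses

    return dataclasses.replace(cfg, **{name: value})
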