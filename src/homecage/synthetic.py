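"""Ground-truth-labelled synthetic home-cage data.

Generates the three coupled products the analysis pipeline consumes —
top-down video of a single dark mouse-sized blob, EMG, and hippocampal
LFP — all driven by one known sleep/wake schedule, so every downstream
stage can be scored against exact ground truth.

The scene emulates the features the motion detector must cope with:
high blob/background contrast, sub-threshold breathing motion during
sleep, slow sinusoidal illumination drift, small static distractors with
jitter, and i.i.d. Gaussian pixel noise. During wake the blob performs a
reflected random walk whose speed is modulated on two time scales a
resting mouse actually shows: an Ornstein-Uhlenbeck speed factor
(seconds-scale vigour fluctuations) and brief quiet-wakefulness pauses
(immobile but awake), the behaviour that makes very short immobility
thresholds misclassify wake as sleep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .types import EphysRecording, FrameStream, State, StateSchedule, Trajectory

__all__ = [
    "SceneConfig",
    "EphysConfig",
    "make_schedule",
    "render_video",
    "render_ephys",
    "write_dataset",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, photometry and kinematics of the rendered cage scene.

    Intensities are 8-bit grey levels; the blob is darker than the
    background, matching a dark-coated mouse on light bedding.
    """

    frame_size: tuple[int, int] = (240, 320)  # (rows, cols)
    fps: float = 15.0
    mouse_axes: tuple[float, float] = (18.0, 11.0)  # ellipse semi-axes, px
    mouse_intensity: float = 60.0
    background_intensity: float = 170.0
    pixel_noise_sd: float = 2.0
    illumination_drift_amplitude: float = 8.0
    illumination_drift_period_s: float = 3600.0
    breathing_amplitude_px: float = 0.5  # sub-pixel flank motion at rest
    breathing_rate_hz: float = 3.0  # typical murine resting respiration order
    wake_step_sd_px: float = 3.0  # per-frame step SD while moving
    # quiet-wakefulness pauses: immobile-but-awake episodes inside WAKE
    # bouts (brief scanning/grooming stops, <10% of active time)
    wake_pause_mean_s: float = 3.0
    wake_move_mean_s: float = 35.0
    # lognormal OU modulation of step SD (tau in seconds, sigma of log-speed)
    speed_mod_tau_s: float = 15.0
    speed_mod_sigma: float = 0.5
    distractor_spec: tuple[tuple[tuple[float, float], float, float], ...] = (
        ((30.0, 40.0), 6.0, 0.3),
        ((200.0, 270.0), 5.0, 0.3),
    )  # ((row, col), size_px, jitter_px)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        rows, cols = self.frame_size
        if rows <= 0 or cols <= 0:
            raise ValueError("frame_size must be positive")
        a, b = self.mouse_axes
        if 2 * a >= rows or 2 * b >= cols:
            raise ValueError("mouse blob larger than frame")
        for lo_hi in (self.mouse_intensity, self.background_intensity):
            if not 0 <= lo_hi <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        mouse_area = np.pi * a * b
        for _, size, _ in self.distractor_spec:
            if size * size >= mouse_area:
                raise ValueError("distractor area must be smaller than the mouse")


@dataclass(frozen=True)
class EphysConfig:
    """Amplitude/spectral parameters for the coupled EMG/LFP channels."""

    fs: float = 4000.0
    emg_wake_sd: float = 10.0
    emg_sleep_sd: float = 1.0
    lfp_delta_amp_sleep: float = 30.0
    lfp_theta_amp_wake: float = 20.0
    lfp_background_sd: float = 10.0
    one_over_f_exponent: float = 1.0
    crossfade_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 2000:
            raise ValueError("fs must be at least 2000 Hz to represent the EMG band")
        if self.emg_wake_sd <= self.emg_sleep_sd:
            raise ValueError("emg_wake_sd must exceed emg_sleep_sd")


def make_schedule(
    total_duration_s: float,
    mean_bout_s_by_state: dict | None = None,
    min_bout_s: float = 60.0,
    seed: int = 0,
    start_state: State = State.WAKE,
) -> StateSchedule:
    """Alternating sleep/wake bouts with shifted-exponential durations.

    Bout lengths are exponential truncated below at ``min_bout_s``
    (equivalently ``min_bout_s + Exp(mean - min_bout_s)``), so the stated
    per-state means are the actual bout means and no bout is shorter than
    the minimum. The final bout is clipped at ``total_duration_s``.
    """
    if total_duration_s <= 0:
        raise ValueError("total_duration_s must be positive")
    if min_bout_s <= 0:
        raise ValueError("min_bout_s must be positive")
    if mean_bout_s_by_state is None:
        mean_bout_s_by_state = {State.SLEEP: 300.0, State.WAKE: 300.0}
    means = {State(k) if not isinstance(k, State) else k: float(v)
             for k, v in mean_bout_s_by_state.items()}
    for st in (State.SLEEP, State.WAKE):
        if st not in means:
            raise ValueError(f"mean bout length missing for {st.name}")
        if means[st] < min_bout_s:
            raise ValueError("mean bout lengths must be >= min_bout_s")
    rng = np.random.default_rng(seed)
    epochs: list[tuple[float, float, State]] = []
    t = 0.0
    state = State(start_state)
    while t < total_duration_s - 1e-9:
        scale = means[state] - min_bout_s
        dur = min_bout_s + (rng.exponential(scale) if scale > 0 else 0.0)
        end = min(t + dur, total_duration_s)
        epochs.append((t, end, state))
        t = end
        state = State.WAKE if state is State.SLEEP else State.SLEEP
    return StateSchedule(tuple(epochs), total_duration_s)


def _gaussian_f32(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standard-normal float32 draws via Box-Muller (exact, and faster than
    the ziggurat path for the full-frame sizes used here)."""
    half = (n + 1) // 2
    u1 = rng.random(half, dtype=np.float32)
    u2 = rng.random(half, dtype=np.float32)
    r = np.sqrt(-2.0 * np.log1p(-u1))
    th = np.float32(2.0 * np.pi) * u2
    z = np.empty(2 * half, dtype=np.float32)
    z[:half] = r * np.cos(th)
    z[half:] = r * np.sin(th)
    return z[:n]


def _truncated_exp(rng: np.random.Generator, mean_s: float, min_s: float) -> float:
    scale = mean_s - min_s
    return min_s + (rng.exponential(scale) if scale > 0 else 0.0)


def _simulate_path(schedule: StateSchedule, scene: SceneConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame centroid (row, col) and a moving? flag.

    WAKE: reflected random walk; per-frame steps are N(0, sd_t) with
    sd_t = wake_step_sd_px * OU lognormal speed factor, interrupted by
    quiet pauses. SLEEP (and pauses): stationary.
    """
    fps = scene.fps
    n = int(round(schedule.total_duration_s * fps))
    times = np.arange(n) / fps
    states = schedule.states_at(times)
    rows_n, cols_n = scene.frame_size
    a, b = scene.mouse_axes
    margin_r = a + scene.breathing_amplitude_px + 1.0
    margin_c = b + scene.breathing_amplitude_px + 1.0
    lo_r, hi_r = margin_r, rows_n - 1 - margin_r
    lo_c, hi_c = margin_c, cols_n - 1 - margin_c

    # OU log-speed factor, AR(1) at frame rate
    phi = np.exp(-1.0 / (scene.speed_mod_tau_s * fps))
    innov_sd = scene.speed_mod_sigma * np.sqrt(1.0 - phi**2)
    log_speed = np.empty(n)
    eps = rng.standard_normal(n)
    log_speed[0] = scene.speed_mod_sigma * eps[0]
    for i in range(1, n):
        log_speed[i] = phi * log_speed[i - 1] + innov_sd * eps[i]
    speed = np.exp(log_speed - 0.5 * scene.speed_mod_sigma**2)

    # move/pause process inside wake, alternating truncated exponentials
    moving = np.zeros(n, dtype=bool)
    i = 0
    in_move = True
    seg_left = int(round(_truncated_exp(rng, scene.wake_move_mean_s, 1.0) * fps))
    while i < n:
        if states[i] == int(State.WAKE):
            moving[i] = in_move
            seg_left -= 1
            if seg_left <= 0:
                in_move = not in_move
                mean = scene.wake_move_mean_s if in_move else scene.wake_pause_mean_s
                seg_left = max(1, int(round(_truncated_exp(rng, mean, 1.0) * fps)))
        i += 1

    steps = rng.standard_normal((n, 2)) * scene.wake_step_sd_px * speed[:, None]
    steps[~moving] = 0.0
    row = np.empty(n)
    col = np.empty(n)
    row[0] = 0.5 * (lo_r + hi_r)
    col[0] = 0.5 * (lo_c + hi_c)
    for i in range(1, n):
        row[i] = _reflect(row[i - 1] + steps[i, 0], lo_r, hi_r)
        col[i] = _reflect(col[i - 1] + steps[i, 1], lo_c, hi_c)
    return row, col, moving


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return 0.5 * (lo + hi)
    y = (x - lo) % (2 * span)
    if y > span:
        y = 2 * span - y
    return lo + y


def _draw_ellipse(frame: np.ndarray, centre: tuple[float, float],
                  axes: tuple[float, float], value: float) -> None:
    """Paint a filled ellipse into ``frame`` (touches only a bounding patch)."""
    rows_n, cols_n = frame.shape
    cr, cc = centre
    a, b = axes
    r0 = max(0, int(np.floor(cr - a)))
    r1 = min(rows_n, int(np.ceil(cr + a)) + 1)
    c0 = max(0, int(np.floor(cc - b)))
    c1 = min(cols_n, int(np.ceil(cc + b)) + 1)
    if r1 <= r0 or c1 <= c0:
        return
    rr = (np.arange(r0, r1, dtype=np.float32) - cr) / a
    cc_ = (np.arange(c0, c1, dtype=np.float32) - cc) / b
    mask = rr[:, None] ** 2 + cc_[None, :] ** 2 <= 1.0
    patch = frame[r0:r1, c0:c1]
    patch[mask] = value


def ellipse_mask(shape: tuple[int, int], centre: tuple[float, float],
                 axes: tuple[float, float]) -> np.ndarray:
    """Boolean mask of the rendered blob; the segmentation ground truth."""
    out = np.zeros(shape, dtype=np.float32)
    _draw_ellipse(out, centre, axes, 1.0)
    return out.astype(bool)


def render_video(schedule: StateSchedule, scene: SceneConfig) -> tuple[FrameStream, Trajectory]:
    """Render the schedule into a lazy frame stream plus the exact trajectory.

    Frames are produced on demand and are identical on every pass over the
    stream (the per-frame noise generator restarts from the same child
    seed), so multiple analyses can consume one stream reproducibly.
    """
    rows_n, cols_n = scene.frame_size
    a, b = scene.mouse_axes
    if 2 * a >= rows_n or 2 * b >= cols_n:
        raise ValueError("mouse blob larger than frame")
    ss = np.random.SeedSequence(scene.seed)
    path_seed, frame_seed = ss.spawn(2)
    rng_path = np.random.default_rng(path_seed)
    row, col, moving = _simulate_path(schedule, scene, rng_path)
    n = len(row)
    times = np.arange(n) / scene.fps
    states = schedule.states_at(times)
    breathing_scale = scene.breathing_amplitude_px * np.sin(
        2 * np.pi * scene.breathing_rate_hz * times
    )
    drift = (
        scene.illumination_drift_amplitude
        * np.sin(2 * np.pi * times / scene.illumination_drift_period_s)
        if scene.illumination_drift_amplitude > 0
        else np.zeros(n)
    )
    npix = rows_n * cols_n

    def factory() -> Iterator[np.ndarray]:
        rng = np.random.default_rng(frame_seed)
        base = np.empty((rows_n, cols_n), dtype=np.float32)
        for i in range(n):
            base.fill(np.float32(scene.background_intensity + drift[i]))
            for (dr, dc), size, jitter in scene.distractor_spec:
                if jitter > 0:
                    jr, jc = rng.standard_normal(2) * jitter
                else:
                    jr = jc = 0.0
                half = size / 2.0
                _draw_ellipse(base, (dr + jr, dc + jc), (half, half), scene.mouse_intensity)
            axes_i = (a + breathing_scale[i], b + breathing_scale[i])
            _draw_ellipse(base, (row[i], col[i]), axes_i, scene.mouse_intensity)
            if scene.pixel_noise_sd > 0:
                noise = _gaussian_f32(rng, npix).reshape(rows_n, cols_n)
                frame = base + np.float32(scene.pixel_noise_sd) * noise
                np.clip(frame, 0, 255, out=frame)
                yield frame.astype(np.uint8)
            else:
                yield np.clip(base, 0, 255).astype(np.uint8)

    stream = FrameStream(
        frame_factory=factory,
        timestamps_s=times,
        fps_nominal=scene.fps,
        frame_shape=(rows_n, cols_n),
    )
    traj = Trajectory(
        time_s=times,
        row=row,
        col=col,
        missing=np.zeros(n, dtype=bool),
        frame_shape=(rows_n, cols_n),
    )
    return stream, traj


def render_ephys(schedule: StateSchedule, config: EphysConfig) -> EphysRecording:
    """Schedule-locked EMG and LFP.

    EMG is white noise whose SD switches between the wake and sleep values
    with a linear cross-fade over ``crossfade_s`` at transitions. LFP is a
    1/f^beta background plus a 2 Hz delta sinusoid gated by sleep and an
    8 Hz theta sinusoid gated by wake (same cross-fade).
    """
    fs = config.fs
    n = int(round(schedule.total_duration_s * fs))
    if n < 2:
        raise ValueError("schedule too short for the requested sampling rate")
    ss = np.random.SeedSequence(config.seed)
    rng_emg, rng_lfp = (np.random.default_rng(s) for s in ss.spawn(2))
    t = np.arange(n) / fs
    sleep = (schedule.states_at(t) == int(State.SLEEP)).astype(np.float32)
    fade = max(1, int(round(config.crossfade_s * fs)))
    from scipy.ndimage import uniform_filter1d

    sleep_frac = uniform_filter1d(sleep, size=fade, mode="nearest")
    emg_sd = config.emg_wake_sd + (config.emg_sleep_sd - config.emg_wake_sd) * sleep_frac
    emg = _gaussian_f32(rng_emg, n) * emg_sd

    # spectrally shaped background: |X(f)| ~ f^(-beta/2), unit variance
    white = _gaussian_f32(rng_lfp, n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-config.one_over_f_exponent / 2.0)
    shaping[0] = 0.0
    spec *= shaping
    bg = np.fft.irfft(spec, n=n)
    bg_sd = bg.std()
    if bg_sd > 0:
        bg *= config.lfp_background_sd / bg_sd
    delta = np.sin(2 * np.pi * 2.0 * t).astype(np.float32)
    theta = np.sin(2 * np.pi * 8.0 * t).astype(np.float32)
    lfp = (
        bg.astype(np.float32)
        + config.lfp_delta_amp_sleep * sleep_frac * delta
        + config.lfp_theta_amp_wake * (1.0 - sleep_frac) * theta
    )
    return EphysRecording(fs=fs, emg=emg.astype(np.float32), lfp=lfp.astype(np.float32))


def write_dataset(
    outdir,
    schedule: StateSchedule,
    scene: SceneConfig | None = None,
    ephys_config: EphysConfig | None = None,
    video_format: str = "png",
) -> dict:
    """Materialise a synthetic dataset on disk.

    Writes a PNG image-sequence directory (or MP4 when an ffmpeg-capable
    imageio plugin is available), the ground-truth trajectory/state CSV,
    the ephys CSV and a JSON sidecar with every config field and seed.
    Returns the manifest dict.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = scene or SceneConfig()
    stream, traj = render_video(schedule, scene)
    states = schedule.states_at(stream.timestamps_s)
    if video_format == "png":
        frames_dir = outdir / "frames"
        frames_dir.mkdir(exist_ok=True)
        for i, frame in enumerate(stream):
            iio.imwrite(frames_dir / f"frame_{i:06d}.png", frame)
        video_path = str(frames_dir)
    elif video_format == "mp4":
        video_path = str(outdir / "video.mp4")
        iio.imwrite(video_path, np.stack(list(stream)), fps=scene.fps, codec="libx264")
    else:
        raise ValueError(f"unknown video_format: {video_format}")

    truth = traj.to_frame()
    truth["state"] = [
        "SLEEP" if s == int(State.SLEEP) else "WAKE" for s in states
    ]
    truth.to_csv(outdir / "truth.csv", index=False)
    import pandas as pd

    pd.DataFrame(
        {"frame_index": np.arange(len(stream)), "time_s": stream.timestamps_s}
    ).to_csv(outdir / "timestamps.csv", index=False)

    manifest: dict = {
        "video": video_path,
        "truth": str(outdir / "truth.csv"),
        "timestamps": str(outdir / "timestamps.csv"),
        "scene": _jsonable(asdict(scene)),
        "schedule": {
            "total_duration_s": schedule.total_duration_s,
            "epochs": [(s, e, State(st).name) for s, e, st in schedule.epochs],
        },
    }
    if ephys_config is not None:
        rec = render_ephys(schedule, ephys_config)
        rec.to_csv(outdir / "ephys.csv")
        manifest["ephys"] = str(outdir / "ephys.csv")
        manifest["ephys_config"] = _jsonable(asdict(ephys_config))
    (outdir / "dataset.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
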