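"""Frame-stream input and timestamp regularisation.

Reads image-sequence directories (PNG/TIFF/JPG) or, when an
ffmpeg-capable imageio plugin is present, standard video containers.
Colour input is converted to grayscale with ITU-R BT.601 luminance
weights. A per-frame timestamp CSV (``frame_index,time_s``) may accompany
the video; without one, timestamps default to ``index / fps_nominal``.

``regularize`` puts an irregularly timed scalar series onto a uniform
grid by linear interpolation, flagging long acquisition gaps as missing
rather than silently interpolating through them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .types import FrameStream

__all__ = ["open_stream", "regularize", "RegularizedSeries", "read_timestamps"]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return (frame[..., :3].astype(np.float32) @ _LUMA).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def read_timestamps(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("timestamp file must have a 'time_s' column")
    return df["time_s"].to_numpy(float)


def open_stream(path, timestamps_path=None, fps_nominal: float = 30.0) -> FrameStream:
    """Open a video container or image-sequence directory as a FrameStream.

    The stream is lazy and re-iterable. Raises ``FileNotFoundError`` for
    unreadable paths and ``ValueError`` when the timestamp file length
    does not match the frame count.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such video source: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        first = to_grayscale(iio.imread(files[0]))
        n = len(files)

        def factory() -> Iterator[np.ndarray]:
            for f in files:
                yield to_grayscale(iio.imread(f))

        shape = first.shape
    else:
        try:
            props = iio.improps(path)
        except Exception as exc:  # unreadable container
            raise OSError(f"cannot read video container {path}: {exc}") from exc
        n = props.n_images
        if n is None or n < 0 or n == float("inf"):
            frames_count = sum(1 for _ in iio.imiter(path))
            n = frames_count

        def factory() -> Iterator[np.ndarray]:
            for frame in iio.imiter(path):
                yield to_grayscale(np.asarray(frame))

        shape = tuple(props.shape[-2:]) if props.shape else None
        if shape is None or len(shape) != 2:
            shape = to_grayscale(next(iter(iio.imiter(path)))).shape

    if timestamps_path is not None:
        ts = read_timestamps(timestamps_path)
        if len(ts) != n:
            raise ValueError(
                f"timestamp count ({len(ts)}) does not match frame count ({n})"
            )
    else:
        ts = np.arange(n) / fps_nominal
    return FrameStream(
        frame_factory=factory, timestamps_s=ts, fps_nominal=fps_nominal, frame_shape=shape
    )


@dataclass
class RegularizedSeries:
    """Uniformly sampled series with a missing-data mask."""

    values: np.ndarray
    times_s: np.ndarray
    rate_hz: float
    missing: np.ndarray


def regularize(
    signal_values, timestamps_s, target_rate_hz: float, gap_factor: float = 5.0
) -> RegularizedSeries:
    """Linearly interpolate an irregular series onto a uniform grid.

    Grid points falling inside an inter-sample gap longer than
    ``gap_factor`` times the median interval are flagged missing (the
    value there is still the interpolant, but consumers should treat the
    span as unobserved).
    """
    values = np.asarray(signal_values, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    if len(values) != len(t):
        raise ValueError("values and timestamps must have equal length")
    if len(t) < 2:
        raise ValueError("need at least two samples to regularize")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    n_out = int(np.floor((t[-1] - t[0]) * target_rate_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_rate_hz
    out = np.interp(grid, t, values)
    missing = np.zeros(n_out, dtype=bool)
    median_dt = float(np.median(dt))
    gap_idx = np.flatnonzero(dt > gap_factor * median_dt)
    for i in gap_idx:
        inside = (grid > t[i]) & (grid < t[i + 1])
        missing |= inside
    return RegularizedSeries(values=out, times_s=grid, rate_hz=target_rate_hz, missing=missing)
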