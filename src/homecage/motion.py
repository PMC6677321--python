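"""Adaptive-background motion detection.

The background is a running weighted mean of past frames that slowly
tracks illumination changes. Each new frame is compared to the background
taken *before* it is absorbed:

    delta_frame = |background_estimate - current_frame|

The delta frame is binarised at a grey-level threshold, 8-connected
components are extracted, and components whose changed-pixel area is at
least a mouse-sized minimum become motion regions; smaller components
(cables, bedding shifts, breathing flutter, pixel noise) are discarded.
The per-frame motion signal is the summed qualifying area as a fraction
of the frame, the quantity later thresholded to score sleep and wake.

A consequence of the adaptive background worth knowing: a mouse that
stays still is absorbed into the background within a few time constants,
after which it produces no motion. That is the intended behaviour - for
sleep scoring, "part of the background" and "not moving" coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import FrameStream, MotionSignal
from .video_io import regularize

__all__ = [
    "MotionConfig",
    "BackgroundModel",
    "MotionRegion",
    "update_background",
    "delta_frame",
    "detect_regions",
    "motion_signal",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=np.int32)


@dataclass
class MotionConfig:
    """Parameters of the motion detector.

    alpha
        Background update weight in (0, 1]. 0.05 keeps a stationary
        mouse distinct from the background for a few seconds while still
        absorbing slow illumination drift.
    delta_threshold
        Grey-level difference above which a pixel counts as changed.
    min_area_px
        Minimum changed-pixel area of a component to count as animal
        motion. ``None`` resolves to 0.5% of the frame area at run time.
    """

    alpha: float = 0.05
    delta_threshold: float = 25.0
    min_area_px: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.delta_threshold < 255:
            raise ValueError("delta_threshold must be in (0, 255)")
        if self.min_area_px is not None and self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")

    def resolved_min_area(self, frame_shape: tuple[int, int]) -> int:
        if self.min_area_px is not None:
            return int(self.min_area_px)
        return max(1, int(round(0.005 * frame_shape[0] * frame_shape[1])))


@dataclass
class BackgroundModel:
    """Running weighted-mean background; ``estimate`` is None until the
    first frame initialises it verbatim."""

    alpha: float
    estimate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class MotionRegion:
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area_px: int


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """estimate <- (1 - alpha) * estimate + alpha * frame (in place)."""
    frame_f = np.asarray(frame, dtype=np.float64)
    if model.estimate is None:
        model.estimate = frame_f.copy()
        return model
    if model.estimate.shape != frame_f.shape:
        raise ValueError("frame shape does not match background model")
    model.estimate *= 1.0 - model.alpha
    model.estimate += model.alpha * frame_f
    return model


def delta_frame(model: BackgroundModel, frame: np.ndarray) -> np.ndarray:
    """Per-pixel |background - frame| against the pre-update background."""
    if model.estimate is None:
        raise ValueError("background model is uninitialised")
    frame_f = np.asarray(frame, dtype=np.float64)
    if model.estimate.shape != frame_f.shape:
        raise ValueError("frame shape does not match background model")
    return np.abs(model.estimate - frame_f)


def detect_regions(delta_image: np.ndarray, config: MotionConfig) -> list[MotionRegion]:
    """Area-filtered 8-connected components of the thresholded delta frame.

    Pixels strictly above ``delta_threshold`` count as changed; components
    with fewer than ``min_area_px`` changed pixels are discarded. Regions
    are returned sorted by area, largest first.
    """
    delta_image = np.asarray(delta_image)
    min_area = config.resolved_min_area(delta_image.shape)
    mask = delta_image > config.delta_threshold
    return _regions_from_mask(mask, min_area)


def _regions_from_mask(mask: np.ndarray, min_area: int) -> list[MotionRegion]:
    if np.count_nonzero(mask) < min_area:
        return []
    # label only inside the changed-pixel bounding box (identical result,
    # much cheaper when the change is mouse-sized within a large frame)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = mask[r0:r1, c0:c1]
    labels, n = ndimage.label(sub, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    if len(keep) == 0:
        return []
    slices = ndimage.find_objects(labels)
    regions = []
    for lab in keep:
        sl = slices[lab - 1]
        regions.append(
            MotionRegion(
                bounding_box=(
                    r0 + sl[0].start,
                    c0 + sl[1].start,
                    r0 + sl[0].stop,
                    c0 + sl[1].stop,
                ),
                area_px=int(areas[lab - 1]),
            )
        )
    regions.sort(key=lambda r: (-r.area_px, r.bounding_box))
    return regions


def motion_signal(
    stream: FrameStream,
    config: MotionConfig | None = None,
    target_rate_hz: float | None = None,
) -> MotionSignal:
    """Scalar motion magnitude per frame, regularised to a uniform rate.

    Per frame: total area of qualifying motion regions divided by the
    frame pixel count (so the signal is a dimensionless fraction in
    [0, 1] and comparable across resolutions). The first frame, which
    only initialises the background, yields 0.
    """
    config = config or MotionConfig()
    n = len(stream)
    if n == 0:
        raise ValueError("empty frame stream")
    min_area = config.resolved_min_area(stream.frame_shape)
    npix = float(stream.frame_shape[0] * stream.frame_shape[1])
    thr = np.float32(config.delta_threshold)
    values = np.zeros(n)
    bg: np.ndarray | None = None
    one_minus_alpha = np.float32(1.0 - config.alpha)
    alpha = np.float32(config.alpha)
    for i, frame in enumerate(stream):
        frame_f = frame.astype(np.float32)
        if bg is None:
            bg = frame_f.copy()
            continue
        delta = np.abs(bg - frame_f)
        mask = delta > thr
        # areas-only fast path, same component logic as detect_regions
        if int(np.count_nonzero(mask)) >= min_area:
            labels, nlab = ndimage.label(mask, structure=_EIGHT_CONNECTED)
            if nlab:
                areas = np.bincount(labels.ravel())[1:]
                values[i] = areas[areas >= min_area].sum() / npix
        bg *= one_minus_alpha
        bg += alpha * frame_f
    if target_rate_hz is None:
        target_rate_hz = stream.fps_nominal
    reg = regularize(values, stream.timestamps_s, target_rate_hz)
    return MotionSignal(
        values=reg.values, rate_hz=reg.rate_hz, t0_s=float(reg.times_s[0]), missing=reg.missing
    )
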