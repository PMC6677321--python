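"""Single-animal segmentation and centroid tracking.

Assumes high contrast between the animal and the cage floor. Each frame
is smoothed with a Gaussian (kernel size 21, sigma 3.5), thresholded
(Otsu by default, so a uniform brightness offset does not move the
segmentation), and the largest connected component - in a home cage,
almost always the animal - yields the centroid. Connecting centroids
across frames gives the trajectory, from which distance travelled and
spatial occupancy derive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import FrameStream, Trajectory

__all__ = [
    "TrackingConfig",
    "segment_animal",
    "largest_contour_centroid",
    "track",
    "path_length",
    "occupancy_map",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=np.int32)


@dataclass
class TrackingConfig:
    blur_size: int = 21
    blur_sigma: float = 3.5
    intensity_threshold: float | None = None  # None -> Otsu
    polarity: str = "dark"  # animal darker ("dark") or brighter ("bright")

    def __post_init__(self) -> None:
        if self.blur_size % 2 == 0 or self.blur_size < 1:
            raise ValueError("blur_size must be odd and positive")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


def segment_animal(
    frame: np.ndarray,
    blur_size: int = 21,
    blur_sigma: float = 3.5,
    intensity_threshold: float | None = None,
    polarity: str = "dark",
) -> np.ndarray:
    """Blur-then-threshold foreground mask of the animal.

    With ``intensity_threshold=None`` the level is chosen by Otsu's
    method on the blurred frame; a frame with no contrast (all pixels
    equal) yields an empty mask.
    """
    if blur_size % 2 == 0 or blur_size < 1:
        raise ValueError("blur_size must be odd and positive")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("segment_animal expects a grayscale frame")
    radius = blur_size // 2
    blurred = ndimage.gaussian_filter(
        frame.astype(np.float32), sigma=blur_sigma, radius=radius, mode="nearest"
    )
    if intensity_threshold is None:
        if np.ptp(blurred) == 0:
            return np.zeros(frame.shape, dtype=bool)
        from skimage.filters import threshold_otsu

        intensity_threshold = float(threshold_otsu(blurred))
    if polarity == "dark":
        return blurred < intensity_threshold
    return blurred > intensity_threshold


def largest_contour_centroid(mask: np.ndarray) -> tuple[float, float] | None:
    """Centroid (row, col) of the largest 8-connected component.

    Area ties break on the component containing the first foreground
    pixel in row-major order. Returns None for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    areas = np.bincount(labels.ravel())[1:]
    best_area = areas.max()
    tied = np.flatnonzero(areas == best_area) + 1
    if len(tied) == 1:
        lab = int(tied[0])
    else:
        # first row-major foreground pixel among tied components
        flat = labels.ravel()
        tied_mask = np.isin(flat, tied)
        lab = int(flat[np.flatnonzero(tied_mask)[0]])
    rows, cols = np.nonzero(labels == lab)
    return float(rows.mean()), float(cols.mean())


def track(stream: FrameStream, config: TrackingConfig | None = None) -> Trajectory:
    """Per-frame largest-component centroid; frames with an empty mask
    are stored missing, never interpolated."""
    config = config or TrackingConfig()
    n = len(stream)
    if n == 0:
        raise ValueError("empty frame stream")
    row = np.full(n, np.nan)
    col = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    for i, frame in enumerate(stream):
        mask = segment_animal(
            frame,
            blur_size=config.blur_size,
            blur_sigma=config.blur_sigma,
            intensity_threshold=config.intensity_threshold,
            polarity=config.polarity,
        )
        c = largest_contour_centroid(mask)
        if c is None:
            missing[i] = True
        else:
            row[i], col[i] = c
    return Trajectory(
        time_s=stream.timestamps_s,
        row=row,
        col=col,
        missing=missing,
        frame_shape=stream.frame_shape,
    )


def path_length(trajectory: Trajectory, pixel_to_cm: float | None = None) -> float:
    """Total Euclidean distance over consecutive non-missing samples.

    Distance is in pixels, or centimetres when ``pixel_to_cm`` (cm per
    pixel) is given.
    """
    valid = ~trajectory.missing
    if valid.sum() < 2:
        raise ValueError("need at least two non-missing samples")
    r = trajectory.row[valid]
    c = trajectory.col[valid]
    d = float(np.hypot(np.diff(r), np.diff(c)).sum())
    if pixel_to_cm is not None:
        d *= pixel_to_cm
    return d


def occupancy_map(
    trajectory: Trajectory,
    grid_shape: tuple[int, int],
    frame_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """2-D histogram of non-missing centroid positions.

    Bins partition the frame (taken from the trajectory if recorded);
    the counts sum to the number of non-missing samples.
    """
    if frame_shape is None:
        frame_shape = trajectory.frame_shape
    valid = ~trajectory.missing
    r = trajectory.row[valid]
    c = trajectory.col[valid]
    if frame_shape is None:
        if valid.sum() == 0:
            return np.zeros(grid_shape, dtype=int)
        frame_shape = (int(np.ceil(r.max())) + 1, int(np.ceil(c.max())) + 1)
    hist, _, _ = np.histogram2d(
        r,
        c,
        bins=grid_shape,
        range=[[0, frame_shape[0]], [0, frame_shape[1]]],
    )
    return hist.astype(int)
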