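"""Sleep/wake scoring from video motion, EMG, and LFP+EMG.

Three scorers, one contract: each returns a binary :class:`Hypnogram` on
a uniform 1-s epoch grid.

Video chain: the motion signal is low-pass filtered below 0.1 Hz with a
zero-phase (forward-backward) Chebyshev filter, locally detrended in
10-s windows with 5-s overlap to remove baseline variation across the
light/dark cycle, rectified and integrated over 20-s moving windows,
thresholded at its 50-60th percentile, and immobility must persist for
at least 40 s to count as sleep - shorter sub-threshold spells are quiet
wakefulness, not sleep.

EMG chain: band-pass 90-1000 Hz, rectify, 20-s moving-window integrate,
percentile threshold; low muscle tone scores sleep. No minimum-duration
rule is applied.

LFP+EMG chain: LFP band-passed 0.2-100 Hz and downsampled to 200 Hz;
delta (0.5-4 Hz) power and theta (6-10 Hz)/delta power ratio computed in
5-s windows stepped by 1 s; sleep requires quiet EMG (RMS below its
percentile) AND a sleep-like LFP (delta power above its percentile -
NREM - OR theta ratio above threshold - REM, theta with atonia).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import Hypnogram, MotionSignal, State, runs

__all__ = [
    "VideoScoringConfig",
    "EmgScoringConfig",
    "LfpScoringConfig",
    "zero_phase_lowpass",
    "zero_phase_bandpass",
    "local_detrend",
    "rectify_integrate",
    "percentile_threshold_states",
    "enforce_min_duration",
    "score_video",
    "score_emg",
    "score_lfp_emg",
]


@dataclass
class VideoScoringConfig:
    lowpass_cutoff_hz: float = 0.1
    detrend_window_s: float = 10.0
    detrend_overlap_s: float = 5.0
    integrate_window_s: float = 20.0
    threshold_percentile: float = 55.0
    min_sleep_s: float = 40.0
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        if self.lowpass_cutoff_hz <= 0:
            raise ValueError("lowpass cutoff must be positive")
        if not 0 < self.detrend_overlap_s < self.detrend_window_s:
            raise ValueError("need 0 < overlap < window for detrending")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")
        if self.min_sleep_s <= 0 or self.integrate_window_s <= 0 or self.epoch_s <= 0:
            raise ValueError("durations must be positive")


@dataclass
class EmgScoringConfig:
    band_hz: tuple[float, float] = (90.0, 1000.0)
    integrate_window_s: float = 20.0
    threshold_percentile: float = 55.0
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band_hz must satisfy 0 < low < high")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")


@dataclass
class LfpScoringConfig:
    lfp_band_hz: tuple[float, float] = (0.2, 100.0)
    lfp_fs_target: float = 200.0
    delta_band_hz: tuple[float, float] = (0.5, 4.0)
    theta_band_hz: tuple[float, float] = (6.0, 10.0)
    delta_percentile: float = 25.0
    theta_ratio_threshold: float = 0.35
    spectral_window_s: float = 5.0
    spectral_step_s: float = 1.0

    def __post_init__(self) -> None:
        for band in (self.delta_band_hz, self.theta_band_hz):
            if not 0 < band[0] < band[1]:
                raise ValueError("bands must be ordered and positive")
        if self.theta_band_hz[1] > self.lfp_fs_target / 2:
            raise ValueError("theta band exceeds Nyquist after downsampling")
        if not 0 < self.delta_percentile < 100:
            raise ValueError("delta_percentile must be in (0, 100)")


# ---------------------------------------------------------------------------
# filtering primitives

_CHEBY_ORDER = 4
_CHEBY_RIPPLE_DB = 0.5


def _cheby_sos(rate_hz: float, wn, btype: str) -> np.ndarray:
    return sps.cheby1(
        _CHEBY_ORDER, _CHEBY_RIPPLE_DB, wn, btype=btype, fs=rate_hz, output="sos"
    )


def zero_phase_lowpass(series, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Type-I Chebyshev low-pass (order 4, 0.5 dB ripple) applied forward
    then backward, so the output has zero net phase lag.

    The section gains are rescaled so the filter is exactly unity at DC
    (an even-order Chebyshev-I otherwise sits at -ripple there, which a
    forward-backward pass would square)."""
    series = np.asarray(series, dtype=float)
    if cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = _cheby_sos(rate_hz, cutoff_hz, "lowpass")
    dc_gain = np.prod(sos[:, :3].sum(axis=1) / sos[:, 3:].sum(axis=1))
    sos[0, :3] /= dc_gain
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(series) <= padlen:
        raise ValueError("series too short for the filter order")
    return sps.sosfiltfilt(sos, series)


def zero_phase_bandpass(series, rate_hz: float, band_hz: tuple[float, float]) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    lo, hi = band_hz
    if not 0 < lo < hi < rate_hz / 2:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    sos = _cheby_sos(rate_hz, (lo, hi), "bandpass")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(series) <= padlen:
        raise ValueError("series too short for the filter order")
    return sps.sosfiltfilt(sos, series)


def local_detrend(series, rate_hz: float, window_s: float, overlap_s: float) -> np.ndarray:
    """Remove a locally linear baseline (sliding-window least squares).

    Straight lines are fit in windows of ``window_s`` stepped by
    ``window_s - overlap_s``; the per-sample trend is the triangularly
    weighted combination of all window fits covering that sample, and the
    detrended series is the input minus that trend. A global linear ramp
    is removed exactly.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < overlap_s < window_s:
        raise ValueError("need 0 < overlap_s < window_s")
    n = len(series)
    n_w = int(round(window_s * rate_hz))
    if n_w < 3:
        raise ValueError("window too short at this sampling rate")
    if n < n_w:
        raise ValueError("series shorter than one detrending window")
    step = n_w - int(round(overlap_s * rate_hz))
    step = max(1, step)
    starts = list(range(0, n - n_w + 1, step))
    if starts[-1] != n - n_w:
        starts.append(n - n_w)
    starts = np.asarray(starts)

    idx = starts[:, None] + np.arange(n_w)[None, :]
    windows = series[idx]  # (n_windows, n_w)
    x = np.arange(n_w, dtype=float)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    means = windows.mean(axis=1)
    slopes = (windows @ xc) / denom
    trends = means[:, None] + slopes[:, None] * xc[None, :]

    w = np.bartlett(n_w)
    w = np.maximum(w, 1e-3)  # keep edge samples covered
    trend_acc = np.zeros(n)
    w_acc = np.zeros(n)
    np.add.at(trend_acc, idx.ravel(), (trends * w).ravel())
    np.add.at(w_acc, idx.ravel(), np.broadcast_to(w, trends.shape).ravel())
    return series - trend_acc / w_acc


def rectify_integrate(series, rate_hz: float, window_s: float) -> np.ndarray:
    """|x| followed by a centred moving average over ``window_s``.

    Near the edges the averaging window shrinks to the available samples,
    so output length equals input length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.abs(np.asarray(series, dtype=float))
    n = len(x)
    n_w = max(1, int(round(window_s * rate_hz)))
    if n_w >= 2 * n:
        return np.full(n, x.mean())
    half_l = (n_w - 1) // 2
    half_r = n_w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(0, i - half_l)
    hi = np.minimum(n, i + half_r + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# thresholding and the immobility-duration rule


def percentile_threshold_states(
    series, percentile: float, missing: np.ndarray | None = None
) -> np.ndarray:
    """Candidate-sleep mask: samples at or below the series' empirical
    percentile. Missing samples are excluded from the percentile and
    never flagged."""
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ValueError("empty series")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if missing is None:
        missing = np.zeros(len(series), dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)
    valid = series[~missing]
    if len(valid) == 0:
        raise ValueError("all samples missing")
    thr = np.percentile(valid, percentile)
    return (series <= thr) & ~missing


def _aggregate_to_epochs(
    candidate: np.ndarray, rate_hz: float, epoch_s: float, missing: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote per epoch; an epoch is missing when more than half
    its samples are. Ties resolve to candidate (sleep-side, matching the
    at-or-below threshold convention). Trailing partial epochs with fewer
    than half the nominal samples are dropped."""
    n = len(candidate)
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    spe = rate_hz * epoch_s
    epoch_idx = np.floor(np.arange(n) / spe).astype(int)
    n_epochs = int(np.floor(n / spe + 0.5))
    if n_epochs < 1:
        raise ValueError("series shorter than one epoch")
    keep = epoch_idx < n_epochs
    epoch_idx = epoch_idx[keep]
    cand = candidate[keep]
    miss = missing[keep]
    total = np.bincount(epoch_idx, minlength=n_epochs)
    n_miss = np.bincount(epoch_idx, weights=miss.astype(float), minlength=n_epochs)
    n_cand = np.bincount(
        epoch_idx, weights=(cand & ~miss).astype(float), minlength=n_epochs
    )
    n_valid = total - n_miss
    epoch_missing = n_miss * 2 > total
    epoch_cand = np.zeros(n_epochs, dtype=bool)
    ok = n_valid > 0
    epoch_cand[ok] = n_cand[ok] * 2 >= n_valid[ok]
    epoch_cand &= ~epoch_missing
    return epoch_cand, epoch_missing


def enforce_min_duration(
    candidate_sleep,
    rate_hz: float,
    min_sleep_s: float,
    t0_s: float = 0.0,
    missing: np.ndarray | None = None,
    epoch_s: float = 1.0,
) -> Hypnogram:
    """Keep only immobility runs of at least ``min_sleep_s`` as sleep.

    The candidate mask is first aggregated onto the epoch grid; maximal
    candidate runs shorter than the minimum are relabelled WAKE, runs of
    at least the minimum become SLEEP. Missing epochs stay MISSING and
    interrupt candidate runs.
    """
    if min_sleep_s <= 0:
        raise ValueError("min_sleep_s must be positive")
    candidate_sleep = np.asarray(candidate_sleep, dtype=bool)
    epoch_cand, epoch_missing = _aggregate_to_epochs(
        candidate_sleep, rate_hz, epoch_s, missing
    )
    min_epochs = int(np.ceil(min_sleep_s / epoch_s - 1e-9))
    states = np.full(len(epoch_cand), int(State.WAKE), dtype=np.int8)
    code = np.where(epoch_missing, 2, epoch_cand.astype(int))  # 0 wake, 1 cand, 2 missing
    for start, stop, value in runs(code):
        if value == 2:
            states[start:stop] = int(State.MISSING)
        elif value == 1 and (stop - start) >= min_epochs:
            states[start:stop] = int(State.SLEEP)
    return Hypnogram(states, epoch_s=epoch_s, t0_s=t0_s)


def _states_no_min_duration(
    candidate_sleep, rate_hz: float, t0_s: float, missing, epoch_s: float
) -> Hypnogram:
    epoch_cand, epoch_missing = _aggregate_to_epochs(
        np.asarray(candidate_sleep, dtype=bool), rate_hz, epoch_s, missing
    )
    states = np.where(
        epoch_missing,
        int(State.MISSING),
        np.where(epoch_cand, int(State.SLEEP), int(State.WAKE)),
    ).astype(np.int8)
    return Hypnogram(states, epoch_s=epoch_s, t0_s=t0_s)


def _interp_over_missing(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    if not missing.any():
        return values
    out = values.copy()
    good = np.flatnonzero(~missing)
    if len(good) == 0:
        raise ValueError("all samples missing")
    out[missing] = np.interp(np.flatnonzero(missing), good, values[good])
    return out


# ---------------------------------------------------------------------------
# scorers


def score_video(motion: MotionSignal, config: VideoScoringConfig | None = None) -> Hypnogram:
    """Video-only sleep/wake scoring of a uniform-rate motion signal."""
    config = config or VideoScoringConfig()
    rate = motion.rate_hz
    n = len(motion.values)
    if n < 2 * config.min_sleep_s * rate:
        raise ValueError("motion signal shorter than twice the minimum sleep bout")
    missing = motion.missing
    x = _interp_over_missing(motion.values, missing)
    x = zero_phase_lowpass(x, rate, config.lowpass_cutoff_hz)
    x = local_detrend(x, rate, config.detrend_window_s, config.detrend_overlap_s)
    env = rectify_integrate(x, rate, config.integrate_window_s)
    cand = percentile_threshold_states(env, config.threshold_percentile, missing)
    return enforce_min_duration(
        cand,
        rate,
        config.min_sleep_s,
        t0_s=motion.t0_s,
        missing=missing,
        epoch_s=config.epoch_s,
    )


def score_emg(emg, fs: float, config: EmgScoringConfig | None = None) -> Hypnogram:
    """EMG-only scoring: sleep wherever the rectified, integrated
    band-limited EMG envelope sits below its percentile threshold."""
    config = config or EmgScoringConfig()
    lo, hi = config.band_hz
    if hi >= fs / 2:
        raise ValueError("EMG band exceeds the Nyquist frequency")
    x = zero_phase_bandpass(np.asarray(emg, dtype=float), fs, (lo, hi))
    env = rectify_integrate(x, fs, config.integrate_window_s)
    cand = percentile_threshold_states(env, config.threshold_percentile)
    return _states_no_min_duration(cand, fs, 0.0, None, config.epoch_s)


def _band_power_windows(
    x: np.ndarray, fs: float, window_s: float, step_s: float, bands
) -> tuple[np.ndarray, ...]:
    """Mean periodogram power per frequency band in sliding windows."""
    n_w = int(round(window_s * fs))
    step = int(round(step_s * fs))
    n = len(x)
    if n < n_w:
        raise ValueError("signal shorter than one spectral window")
    starts = np.arange(0, n - n_w + 1, step)
    idx = starts[:, None] + np.arange(n_w)[None, :]
    segs = x[idx]
    spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2 / n_w
    freqs = np.fft.rfftfreq(n_w, d=1.0 / fs)
    out = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs <= hi)
        out.append(spec[:, sel].mean(axis=1))
    return tuple(out)


def score_lfp_emg(
    lfp,
    emg,
    fs: float,
    lfp_config: LfpScoringConfig | None = None,
    emg_config: EmgScoringConfig | None = None,
) -> Hypnogram:
    """Combined LFP+EMG scoring.

    Sleep requires low muscle tone AND a sleep-like hippocampal spectrum:
    EMG RMS at or below its percentile AND (delta power strictly above its
    percentile OR theta/delta ratio above the fixed threshold).
    """
    lfp_config = lfp_config or LfpScoringConfig()
    emg_config = emg_config or EmgScoringConfig()
    lfp = np.asarray(lfp, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if len(lfp) != len(emg):
        raise ValueError("LFP and EMG must have equal length")
    lo, hi = lfp_config.lfp_band_hz
    hi = min(hi, 0.45 * fs)
    filtered = zero_phase_bandpass(lfp, fs, (lo, hi))
    ratio = Fraction(lfp_config.lfp_fs_target / fs).limit_denominator(1000)
    lfp_ds = sps.resample_poly(filtered, ratio.numerator, ratio.denominator)
    fs_ds = fs * ratio.numerator / ratio.denominator

    delta, theta = _band_power_windows(
        lfp_ds,
        fs_ds,
        lfp_config.spectral_window_s,
        lfp_config.spectral_step_s,
        (lfp_config.delta_band_hz, lfp_config.theta_band_hz),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_ratio = np.where(delta > 0, theta / np.maximum(delta, 1e-30), 0.0)

    # EMG RMS in the same windows (centres aligned with the spectral windows)
    n_win = len(delta)
    w_emg = int(round(lfp_config.spectral_window_s * fs))
    ms = uniform_filter1d(emg**2, size=w_emg, mode="nearest")
    centres = (
        np.arange(n_win) * lfp_config.spectral_step_s + lfp_config.spectral_window_s / 2
    )
    centre_idx = np.clip((centres * fs).astype(int), 0, len(emg) - 1)
    rms = np.sqrt(ms[centre_idx])

    quiet = rms <= np.percentile(rms, emg_config.threshold_percentile)
    delta_high = delta > np.percentile(delta, lfp_config.delta_percentile)
    theta_high = theta_ratio > lfp_config.theta_ratio_threshold
    sleep = quiet & (delta_high | theta_high)
    states = np.where(sleep, int(State.SLEEP), int(State.WAKE)).astype(np.int8)
    return Hypnogram(states, epoch_s=lfp_config.spectral_step_s, t0_s=0.0)
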