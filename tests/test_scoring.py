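"""Tests of the scoring primitives and the three sleep/wake scorers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homecage as hc
from homecage.scoring import (
    EmgScoringConfig,
    LfpScoringConfig,
    VideoScoringConfig,
    enforce_min_duration,
    local_detrend,
    percentile_threshold_states,
    rectify_integrate,
    score_emg,
    score_lfp_emg,
    score_video,
    zero_phase_bandpass,
    zero_phase_lowpass,
)
from homecage.synthetic import EphysConfig
from homecage.types import MotionSignal, State, runs


def balanced_schedule(total_s=3600.0, bout_s=300.0):
    """Deterministic alternating schedule with exactly 50% sleep."""
    epochs = []
    t, state = 0.0, hc.State.WAKE
    while t < total_s:
        epochs.append((t, min(t + bout_s, total_s), state))
        t += bout_s
        state = hc.State.SLEEP if state is hc.State.WAKE else hc.State.WAKE
    return hc.StateSchedule(tuple(epochs), total_s)


class TestZeroPhaseLowpass:
    def test_dc_passes_unchanged(self):
        x = np.full(500, 3.7)
        y = zero_phase_lowpass(x, 10.0, 0.1)
        np.testing.assert_allclose(y, x, rtol=1e-6)

    def test_stopband_attenuation(self):
        rate = 10.0
        t = np.arange(3000) / rate
        x = np.sin(2 * np.pi * 1.0 * t)  # 10x the 0.1 Hz cutoff
        y = zero_phase_lowpass(x, rate, 0.1)
        mid = slice(500, 2500)
        assert np.abs(y[mid]).max() < 0.05

    def test_zero_lag_in_passband(self):
        rate = 10.0
        t = np.arange(30000) / rate
        x = np.sin(2 * np.pi * 0.01 * t)
        y = zero_phase_lowpass(x, rate, 0.1)
        xc = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            zero_phase_lowpass(np.zeros(100), 10.0, 6.0)

    def test_output_length_equals_input(self):
        x = np.random.default_rng(0).normal(size=777)
        assert len(zero_phase_lowpass(x, 10.0, 0.5)) == 777


class TestLocalDetrend:
    def test_removes_linear_ramp_exactly(self):
        rate = 10.0
        t = np.arange(600) / rate
        ramp = 5.0 + 2.0 * t
        resid = local_detrend(ramp, rate, 10.0, 5.0)
        assert np.abs(resid).max() < 1e-6 * np.ptp(ramp)

    def test_zero_in_zero_out(self):
        out = local_detrend(np.zeros(200), 10.0, 10.0, 5.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_preserves_fast_oscillation_on_ramp(self):
        rate = 10.0
        t = np.arange(1200) / rate
        sine = np.sin(2 * np.pi * 0.5 * t)
        resid = local_detrend(3.0 * t + sine, rate, 10.0, 5.0)
        r = np.corrcoef(resid, sine)[0, 1]
        assert r > 0.99

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            local_detrend(np.zeros(50), 10.0, 10.0, 5.0)

    def test_bad_overlap_rejected(self):
        with pytest.raises(ValueError):
            local_detrend(np.zeros(500), 10.0, 10.0, 12.0)


class TestRectifyIntegrate:
    def test_rectifies_constant_negative(self):
        out = rectify_integrate(np.full(50, -3.0), 1.0, 5.0)
        np.testing.assert_allclose(out, 3.0)

    def test_impulse_response_is_moving_average(self):
        """Unit impulse at 1 Hz with a 20-s window: a 1/20 plateau over the
        20 covering positions, shrinking-window values at the edges."""
        n = 101
        x = np.zeros(n)
        x[50] = 1.0
        out = rectify_integrate(x, 1.0, 20.0)
        covered = (np.arange(n) >= 50 - 20 // 2) & (np.arange(n) <= 50 + (20 - 1) // 2)
        np.testing.assert_allclose(out[covered], 1 / 20)
        np.testing.assert_allclose(out[~covered], 0.0)
        assert covered.sum() == 20

    def test_sinusoid_mean_absolute_value(self):
        rate = 100.0
        t = np.arange(20000) / rate
        a = 2.5
        x = a * np.sin(2 * np.pi * 5.0 * t)
        out = rectify_integrate(x, rate, 20.0)
        mid = slice(2000, 18000)
        np.testing.assert_allclose(out[mid], 2 * a / np.pi, rtol=0.01)

    def test_window_longer_than_series_gives_global_mean(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(rectify_integrate(x, 1.0, 100.0), 2.0)


class TestPercentileThreshold:
    def test_exact_count_on_permutation(self):
        series = np.arange(1.0, 101.0)
        flagged = percentile_threshold_states(series, 50.0)
        assert flagged.sum() == 50

    def test_constant_series_all_flagged(self):
        flagged = percentile_threshold_states(np.full(40, 7.0), 55.0)
        assert flagged.all()

    def test_bimodal_flagged_fraction(self):
        rng = np.random.default_rng(0)
        series = np.concatenate([rng.normal(0, 0.1, 550), rng.normal(10, 0.1, 450)])
        flagged = percentile_threshold_states(series, 55.0)
        assert abs(int(flagged.sum()) - 550) <= 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold_states(np.ones(5), 55.0, missing=np.ones(5, bool))


class TestEnforceMinDuration:
    def test_39s_immobility_is_wake(self):
        cand = np.zeros(120, bool)
        cand[40:79] = True  # 39 samples at 1 Hz
        hyp = enforce_min_duration(cand, 1.0, 40.0)
        assert not (hyp.states == int(State.SLEEP)).any()

    def test_41s_immobility_is_sleep(self):
        cand = np.zeros(120, bool)
        cand[40:81] = True  # 41 samples
        hyp = enforce_min_duration(cand, 1.0, 40.0)
        sleep = hyp.states == int(State.SLEEP)
        assert sleep.sum() == 41
        assert sleep[40:81].all()

    def test_exactly_40s_is_sleep(self):
        cand = np.zeros(120, bool)
        cand[10:50] = True
        hyp = enforce_min_duration(cand, 1.0, 40.0)
        assert (hyp.states == int(State.SLEEP)).sum() == 40

    def test_alternating_single_samples_all_wake(self):
        cand = np.zeros(100, bool)
        cand[::2] = True
        hyp = enforce_min_duration(cand, 1.0, 40.0)
        assert not (hyp.states == int(State.SLEEP)).any()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_no_short_sleep_bout_survives(self, seed):
        rng = np.random.default_rng(seed)
        cand = rng.random(300) < rng.uniform(0.2, 0.8)
        min_sleep = float(rng.integers(2, 60))
        hyp = enforce_min_duration(cand, 1.0, min_sleep)
        for start, stop, value in runs(hyp.states):
            if value == int(State.SLEEP):
                assert (stop - start) * hyp.epoch_s >= min_sleep


class TestScoreVideo:
    def _motion(self, values, rate=15.0, missing=None):
        return MotionSignal(values=values, rate_hz=rate, missing=missing)

    def test_all_zero_motion_is_one_sleep_bout(self):
        hyp = score_video(self._motion(np.zeros(15 * 600)))
        assert (hyp.states == int(State.SLEEP)).all()

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(1)
        v = np.abs(rng.normal(size=15 * 900)) * (rng.random(15 * 900) < 0.5)
        a = score_video(self._motion(v))
        b = score_video(self._motion(v * 37.2))
        np.testing.assert_array_equal(a.states, b.states)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            score_video(self._motion(np.zeros(100)))

    def test_no_sleep_bout_shorter_than_minimum(self):
        rng = np.random.default_rng(2)
        v = np.abs(rng.normal(size=15 * 1200)) * (rng.random(15 * 1200) < 0.6)
        cfg = VideoScoringConfig(min_sleep_s=40.0)
        hyp = score_video(self._motion(v), cfg)
        for start, stop, value in runs(hyp.states):
            if value == int(State.SLEEP):
                assert (stop - start) * hyp.epoch_s >= cfg.min_sleep_s

    def test_missing_spans_propagate(self):
        rng = np.random.default_rng(3)
        v = np.abs(rng.normal(size=15 * 600))
        missing = np.zeros(len(v), bool)
        missing[15 * 100 : 15 * 160] = True
        hyp = score_video(self._motion(v, missing=missing))
        assert (hyp.states[100:160] == int(State.MISSING)).all()

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        v = np.abs(rng.normal(size=15 * 600))
        a = score_video(self._motion(v))
        b = score_video(self._motion(v.copy()))
        np.testing.assert_array_equal(a.states, b.states)


class TestScoreEmg:
    def test_clean_bimodal_emg_recovers_schedule(self):
        """With a 10:1 wake/sleep amplitude ratio and a balanced schedule,
        EMG scoring recovers the ground truth almost everywhere."""
        sched = balanced_schedule(1800.0, 300.0)
        rec = hc.render_ephys(
            sched, EphysConfig(fs=2500, emg_wake_sd=10.0, emg_sleep_sd=1.0, seed=0)
        )
        # percentile matched to the schedule's 50% sleep occupancy
        hyp = score_emg(rec.emg, rec.fs, EmgScoringConfig(threshold_percentile=50.0))
        res = hc.accuracy(hyp, sched.to_hypnogram())
        assert res.accuracy >= 0.98

    def test_constant_sd_flags_percentile_fraction(self):
        rng = np.random.default_rng(0)
        fs = 2500.0
        emg = rng.normal(size=int(600 * fs))
        hyp = score_emg(emg, fs)
        sleep_frac = np.mean(hyp.states == int(State.SLEEP))
        assert sleep_frac == pytest.approx(0.55, abs=0.06)

    def test_band_exceeding_nyquist_rejected(self):
        with pytest.raises(ValueError):
            score_emg(np.zeros(10000), 1500.0)

    def test_deterministic_for_identical_input(self):
        sched = balanced_schedule(600.0, 150.0)
        rec = hc.render_ephys(sched, EphysConfig(fs=2500, seed=5))
        a = score_emg(rec.emg, rec.fs)
        b = score_emg(np.array(rec.emg, float), rec.fs)
        np.testing.assert_array_equal(a.states, b.states)


class TestScoreLfpEmg:
    def test_agrees_with_emg_only_scoring(self):
        sched = balanced_schedule(1800.0, 300.0)
        rec = hc.render_ephys(sched, EphysConfig(fs=2500, seed=1))
        ecfg = EmgScoringConfig(threshold_percentile=50.0)
        hyp_e = score_emg(rec.emg, rec.fs, ecfg)
        hyp_le = score_lfp_emg(rec.lfp, rec.emg, rec.fs, emg_config=ecfg)
        assert hc.accuracy(hyp_le, hyp_e).accuracy >= 0.95

    def test_flat_lfp_forces_wake_despite_quiet_emg(self):
        """The sleep rule is a conjunction: with a featureless (constant)
        LFP, neither the delta nor the theta condition can hold, so every
        epoch is WAKE no matter how quiet the EMG."""
        fs = 2500.0
        n = int(300 * fs)
        rng = np.random.default_rng(2)
        emg = rng.normal(0, 1.0, n)
        lfp = np.zeros(n)
        hyp = score_lfp_emg(lfp, emg, fs)
        assert (hyp.states == int(State.WAKE)).all()

    def test_true_sleep_epochs_scored_sleep(self):
        """On a mixed schedule, at least 95% of true-sleep epochs are
        recovered (quiet EMG + delta-dominated LFP)."""
        sched = balanced_schedule(1800.0, 300.0)
        rec = hc.render_ephys(sched, EphysConfig(fs=2500, seed=3))
        hyp = score_lfp_emg(rec.lfp, rec.emg, rec.fs)
        truth = sched.states_at(hyp.times_s + hyp.epoch_s / 2)
        in_sleep = truth == int(State.SLEEP)
        # exclude 20 s around transitions, where windows straddle states
        edges = np.flatnonzero(np.diff(truth)) + 1
        near_edge = np.zeros(len(truth), bool)
        for e in edges:
            near_edge[max(0, e - 20) : e + 20] = True
        sel = in_sleep & ~near_edge
        assert np.mean(hyp.states[sel] == int(State.SLEEP)) >= 0.95

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_lfp_emg(np.zeros(1000), np.zeros(999), 2500.0)
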