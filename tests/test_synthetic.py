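"""Tests of the synthetic-data generator: schedules, video, ephys."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import mannwhitneyu

import homecage as hc
from homecage.synthetic import EphysConfig, SceneConfig


class TestMakeSchedule:
    def test_single_forced_wake_epoch(self):
        sched = hc.make_schedule(
            100.0, {hc.State.SLEEP: 100.0, hc.State.WAKE: 1e9}, min_bout_s=100.0, seed=0
        )
        assert sched.epochs == ((0.0, 100.0, hc.State.WAKE),)

    def test_deterministic_for_fixed_seed(self):
        a = hc.make_schedule(7200, min_bout_s=60, seed=42)
        b = hc.make_schedule(7200, min_bout_s=60, seed=42)
        assert a.epochs == b.epochs

    def test_durations_sum_to_total(self):
        sched = hc.make_schedule(
            7200.0, {hc.State.SLEEP: 300.0, hc.State.WAKE: 300.0}, min_bout_s=60.0, seed=7
        )
        total = sum(end - start for start, end, _ in sched.epochs)
        assert total == pytest.approx(7200.0)

    def test_states_alternate_and_respect_minimum(self):
        sched = hc.make_schedule(7200.0, min_bout_s=60.0, seed=3)
        states = [s for _, _, s in sched.epochs]
        assert all(a != b for a, b in zip(states, states[1:]))
        # all but the clipped last bout obey the minimum
        for start, end, _ in sched.epochs[:-1]:
            assert end - start >= 60.0 - 1e-9

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_duration_rejected(self, bad):
        with pytest.raises(ValueError):
            hc.make_schedule(bad, min_bout_s=10, seed=0)

    def test_mean_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            hc.make_schedule(100, {hc.State.SLEEP: 5.0, hc.State.WAKE: 60.0}, min_bout_s=30)


class TestRenderVideo:
    def test_static_sleep_scene_frames_identical(self, scene_factory, sleep_schedule):
        stream, _ = hc.render_video(sleep_schedule, scene_factory(fps=2.0))
        frames = []
        for i, f in enumerate(stream):
            frames.append(f)
            if i >= 10:
                break
        for f in frames[1:]:
            np.testing.assert_array_equal(f, frames[0])

    def test_trajectory_stays_inside_frame(self, scene_factory):
        for seed in (0, 1, 2):
            sched = hc.make_schedule(60.0, min_bout_s=60.0, seed=seed)
            scene = scene_factory(seed=seed, wake_step_sd_px=8.0)
            _, traj = hc.render_video(sched, scene)
            rows_n, cols_n = scene.frame_size
            assert np.all((traj.row >= 0) & (traj.row <= rows_n - 1))
            assert np.all((traj.col >= 0) & (traj.col <= cols_n - 1))

    def test_wake_step_sd_matches_request(self, scene_factory):
        # constant speed, no pauses, so the empirical per-frame step SD is
        # directly comparable to the configured value
        sched = hc.make_schedule(100.0, {hc.State.SLEEP: 100.0, hc.State.WAKE: 1e9},
                                 min_bout_s=100.0, seed=5)
        scene = scene_factory(
            frame_size=(600, 600), fps=10.0, wake_step_sd_px=2.0,
            speed_mod_sigma=0.0, wake_pause_mean_s=1.0, wake_move_mean_s=1e6, seed=5,
        )
        _, traj = hc.render_video(sched, scene)
        steps = np.concatenate([np.diff(traj.row), np.diff(traj.col)])
        assert np.std(steps) == pytest.approx(2.0, rel=0.10)

    def test_stream_reiteration_is_reproducible(self, scene_factory, sleep_schedule):
        scene = scene_factory(pixel_noise_sd=3.0, fps=1.0)
        stream, _ = hc.render_video(sleep_schedule, scene)
        first = [f.copy() for _, f in zip(range(5), stream)]
        second = [f.copy() for _, f in zip(range(5), stream)]
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_sleep_changes_fewer_pixels_than_wake(self, scene_factory):
        """Breathing-only motion must change strictly fewer pixels per frame
        than locomotion (noise-free renders), so an area filter between the
        two is meaningful."""
        def changed_px(schedule, scene):
            stream, _ = hc.render_video(schedule, scene)
            it = iter(stream)
            prev = next(it).astype(int)
            counts = []
            for f in it:
                cur = f.astype(int)
                counts.append(np.count_nonzero(np.abs(cur - prev) > 25))
                prev = cur
            return np.asarray(counts)

        sleep = hc.StateSchedule(((0.0, 20.0, hc.State.SLEEP),), 20.0)
        wake = hc.make_schedule(20.0, {hc.State.SLEEP: 20.0, hc.State.WAKE: 1e9},
                                min_bout_s=20.0, seed=1)
        sleep_counts = changed_px(
            sleep, scene_factory(breathing_amplitude_px=0.5, seed=1)
        )
        wake_counts = changed_px(
            wake, scene_factory(wake_pause_mean_s=1.0, wake_move_mean_s=1e6, seed=1)
        )
        assert sleep_counts.max() < np.median(wake_counts)

    def test_blob_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(frame_size=(30, 30), mouse_axes=(20.0, 20.0))

    def test_distractor_bigger_than_mouse_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(distractor_spec=(((10.0, 10.0), 100.0, 0.0),))

    def test_trajectory_matches_rendered_centroid(self, scene_factory, wake_schedule):
        """The returned ground truth is the rendered blob's centre: the
        pixel-mask centroid of each noise-free frame agrees to <0.5 px."""
        scene = scene_factory(seed=2)
        stream, traj = hc.render_video(wake_schedule, scene)
        for i, frame in enumerate(stream):
            if i >= 20:
                break
            mask = frame < 100
            rr, cc = np.nonzero(mask)
            assert abs(rr.mean() - traj.row[i]) < 0.5
            assert abs(cc.mean() - traj.col[i]) < 0.5


class TestRenderEphys:
    def test_fixed_seed_reproducible(self, sleep_schedule):
        a = hc.render_ephys(sleep_schedule, EphysConfig(fs=2000, seed=9))
        b = hc.render_ephys(sleep_schedule, EphysConfig(fs=2000, seed=9))
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.lfp, b.lfp)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            EphysConfig(fs=500)

    def test_equal_sds_rejected_but_near_equal_emg_is_stateless(self):
        """With equal wake/sleep EMG amplitude the per-epoch RMS carries no
        state information (location test non-significant at alpha=0.01)."""
        with pytest.raises(ValueError):
            EphysConfig(emg_wake_sd=5.0, emg_sleep_sd=5.0)
        # construct the null by hand instead: 100 alternating 10-s bouts
        sched = hc.make_schedule(1000.0, {hc.State.SLEEP: 10.0, hc.State.WAKE: 10.0},
                                 min_bout_s=10.0, seed=0)
        cfg = EphysConfig(fs=2000, emg_wake_sd=5.0 + 1e-9, emg_sleep_sd=5.0, seed=0)
        rec = hc.render_ephys(sched, cfg)
        n_per = int(10 * rec.fs)
        n_epochs = len(rec.emg) // n_per
        rms = np.sqrt(
            (np.asarray(rec.emg[: n_epochs * n_per], float) ** 2)
            .reshape(n_epochs, n_per)
            .mean(axis=1)
        )
        labels = sched.states_at((np.arange(n_epochs) + 0.5) * 10.0)
        stat = mannwhitneyu(rms[labels == 0], rms[labels == 1])
        assert stat.pvalue > 0.01

    def test_sleep_lfp_delta_dominates_theta(self, sleep_schedule):
        rec = hc.render_ephys(sleep_schedule, EphysConfig(fs=2000, seed=4))
        freqs, psd = sps.welch(np.asarray(rec.lfp, float), fs=rec.fs, nperseg=4096)
        delta = psd[(freqs >= 0.5) & (freqs <= 4)].mean()
        theta = psd[(freqs >= 6) & (freqs <= 10)].mean()
        assert delta > theta

    def test_wake_lfp_theta_dominates_delta(self):
        sched = hc.StateSchedule(((0.0, 300.0, hc.State.WAKE),), 300.0)
        rec = hc.render_ephys(sched, EphysConfig(fs=2000, seed=4))
        freqs, psd = sps.welch(np.asarray(rec.lfp, float), fs=rec.fs, nperseg=4096)
        delta = psd[(freqs >= 0.5) & (freqs <= 4)].mean()
        theta = psd[(freqs >= 6) & (freqs <= 10)].mean()
        assert theta > delta

    def test_emg_amplitude_tracks_schedule(self):
        sched = hc.make_schedule(200.0, {hc.State.SLEEP: 100.0, hc.State.WAKE: 100.0},
                                 min_bout_s=100.0, seed=0)
        rec = hc.render_ephys(sched, EphysConfig(fs=2000, seed=1))
        emg = np.asarray(rec.emg, float)
        t = np.arange(len(emg)) / rec.fs
        wake = sched.states_at(t) == int(hc.State.WAKE)
        assert emg[wake].std() > 5 * emg[~wake].std()


class TestSharedTimebase:
    def test_all_products_agree_on_state_at_time(self, scene_factory):
        sched = hc.make_schedule(60.0, {hc.State.SLEEP: 20.0, hc.State.WAKE: 20.0},
                                 min_bout_s=20.0, seed=2)
        scene = scene_factory(fps=5.0)
        stream, traj = hc.render_video(sched, scene)
        rec = hc.render_ephys(sched, EphysConfig(fs=2000, seed=2))
        assert stream.timestamps_s[0] == 0.0
        assert traj.time_s[0] == 0.0
        assert rec.t0_s == 0.0
        hyp = sched.to_hypnogram()
        mid = np.asarray([10.0, 30.0, 50.0])
        np.testing.assert_array_equal(
            sched.states_at(mid), hyp.states[(mid / hyp.epoch_s).astype(int)]
        )
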