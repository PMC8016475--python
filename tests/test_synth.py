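"""Simulator: swap schedules, timelines, dot kinematics, cohort structure."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from pupilstyle import CohortConfig, ConfigError, StimulusConfig
from pupilstyle.synth import (build_timeline, dot_velocity, draw_cohort_params,
                              draw_swap_intervals, draw_swap_schedule,
                              foreground_velocity, make_timelines,
                              mean_surface_speed, simulate_cohort,
                              simulate_participant)
from conftest import quiet_observer

SQRT3 = math.sqrt(3.0)


class TestSwapIntervals:
    def test_main_component_moments(self, stim):
        """Flat-distribution component has mean 5 s and SD 2 s."""
        iv, outlier = draw_swap_intervals(stim, 10_000, 0, return_component=True)
        main = iv[~outlier]
        assert main.mean() == pytest.approx(5.0, abs=0.05)
        assert main.std(ddof=1) == pytest.approx(2.0, abs=0.05)

    def test_main_component_is_uniform_on_derived_support(self, stim):
        """KS test against uniform(5 - 2*sqrt(3), 5 + 2*sqrt(3)) does not reject."""
        iv, outlier = draw_swap_intervals(stim, 10_000, 3, return_component=True)
        main = iv[~outlier]
        lo, hi = 5.0 - 2.0 * SQRT3, 5.0 + 2.0 * SQRT3
        assert main.min() >= lo and main.max() <= hi
        p = sps.kstest(main, sps.uniform(loc=lo, scale=hi - lo).cdf).pvalue
        assert p > 0.01

    def test_outlier_component_fraction_and_range(self, stim):
        iv, outlier = draw_swap_intervals(stim, 10_000, 4, return_component=True)
        assert outlier.mean() == pytest.approx(0.10, abs=0.02)
        # outliers uniform on the range, clipped below at the ramp duration
        assert iv[outlier].min() >= stim.ramp_duration
        assert iv[outlier].max() <= stim.swap_outlier_hi

    def test_degenerate_distribution(self):
        cfg = StimulusConfig(swap_sd=0.0, swap_outlier_frac=0.0)
        iv = draw_swap_intervals(cfg, 100, 0)
        assert np.all(iv == 5.0)

    def test_overlapping_ramp_config_rejected(self):
        # lower bound 5 - 2.5*sqrt(3) < 1.2 would let ramps overlap
        with pytest.raises(ConfigError):
            draw_swap_intervals(StimulusConfig(swap_sd=2.5), 10, 0)

    def test_schedule_deterministic_and_seed_sensitive(self, stim):
        a = draw_swap_schedule(stim, 42)
        b = draw_swap_schedule(stim, 42)
        c = draw_swap_schedule(stim, 43)
        np.testing.assert_array_equal(a, b)
        assert a.shape != c.shape or not np.allclose(a, c)

    def test_every_ramp_completes_within_trial(self, stim):
        for seed in range(30):
            onsets = draw_swap_schedule(stim, seed)
            assert np.all(onsets + stim.ramp_duration <= stim.trial_duration)
            assert np.all(np.diff(onsets) >= stim.ramp_duration)


class TestTimeline:
    def test_ramp_span_and_disparity_extrema(self, stim):
        tl = build_timeline(stim, draw_swap_schedule(stim, 5), 0, "right", 5)
        for onset, end, _ in tl.swap_events:
            assert end - onset == pytest.approx(1.2)
        t = np.linspace(0, 60, 30_001)
        d = tl.disparity(t)
        assert d.max() == pytest.approx(15.0)
        assert d.min() == pytest.approx(-15.0)
        assert np.all(np.abs(d) <= 15.0)

    def test_disparity_linear_within_ramp(self, stim):
        tl = build_timeline(stim, np.array([10.0]), 0, "right", 1)
        mid = tl.ramp_onsets[0] + 0.6
        s0 = 1.0 if tl.initial_foreground == "black" else -1.0
        assert tl.disparity(np.array([mid]))[0] == pytest.approx(0.0)
        assert tl.disparity(np.array([10.3]))[0] == pytest.approx(s0 * 15.0 / 2)

    def test_foreground_flips_at_ramp_midpoints(self, stim):
        tl = build_timeline(stim, np.array([10.0, 20.0]), 0, "left", 2)
        s0 = tl.foreground_sign(np.array([0.0]))[0]
        assert tl.foreground_sign(np.array([10.59]))[0] == s0
        assert tl.foreground_sign(np.array([10.61]))[0] == -s0
        assert tl.foreground_sign(np.array([25.0]))[0] == s0

    def test_zero_swaps_constant_state(self, stim):
        tl = build_timeline(stim, np.array([]), 0, "right", 3)
        t = np.linspace(0, 60, 601)
        assert np.unique(tl.disparity(t)).size == 1
        assert np.unique(tl.foreground_sign(t)).size == 1

    def test_overlapping_schedule_rejected(self, stim):
        with pytest.raises(ConfigError):
            build_timeline(stim, np.array([10.0, 10.5]), 0, "right", 0)


class TestDotKinematics:
    def test_peak_speed_and_opposition(self, stim):
        t = np.linspace(0, 60, 100_000)
        v_front = dot_velocity(stim, t, "front")
        v_rear = dot_velocity(stim, t, "rear")
        assert np.abs(v_front).max() == pytest.approx(3.9, abs=1e-4)
        assert np.all(np.abs(v_front) <= 3.9 + 1e-12)
        np.testing.assert_allclose(v_front, -v_rear)

    def test_surface_average_speed(self, stim):
        """Mean dot speed over uniform phase is (2/pi) * peak."""
        phases = np.linspace(0, 2 * math.pi, 20_000, endpoint=False)
        speeds = np.abs(dot_velocity(stim, 0.0, "front", phases))
        assert speeds.mean() == pytest.approx(2 / math.pi * 3.9, rel=1e-3)
        assert mean_surface_speed(stim) == pytest.approx(2 / math.pi * 3.9)


class TestParticipant:
    def test_trial_geometry(self, stim, default_recording):
        """60 s trials at 500 Hz (30,000 samples), 30 per participant."""
        assert default_recording.pupil.shape == (30, 30_000)
        assert default_recording.gaze_x.shape == (30, 30_000)

    def test_step_model_pupil_levels(self, stim, step_recording):
        """Instantaneous-kernel pupil sits at baseline +- amp, switching at ramp end."""
        rec = step_recording
        t = rec.times()
        for i in (0, 1):
            tl = rec.timelines[i]
            drive = tl.foreground_sign(t - rec.observer.sustained_latency)
            np.testing.assert_allclose(rec.pupil[i], 4.0 + 0.1 * drive)

    def test_okn_slow_phase_tracks_foreground(self, stim):
        """With unit gain, slow-phase gaze velocity equals the foreground velocity."""
        obs = quiet_observer(okn_gain=1.0)
        tls = make_timelines(stim, 7)
        rec = simulate_participant(obs, stim, tls, "report", 8)
        t = rec.times()
        v = np.diff(rec.gaze_x[0]) * stim.sample_rate
        v_expect = foreground_velocity(stim, rec.timelines[0], t)[1:]
        slow = np.abs(v) < 50.0           # exclude fast resets
        assert slow.mean() > 0.95
        np.testing.assert_allclose(v[slow], v_expect[slow], atol=1e-6)
        # sign flips across a swap
        assert np.unique(np.sign(v_expect)).size == 2

    def test_no_report_mode_emits_nothing(self, stim):
        obs = quiet_observer()
        tls = make_timelines(stim, 1)
        rec = simulate_participant(obs, stim, tls, "no-report", 2)
        assert all(len(ev) == 0 for ev in rec.reports)

    def test_blinks_zero_pupil(self, stim):
        obs = quiet_observer(blink_rate=0.2)
        tls = make_timelines(stim, 3)
        rec = simulate_participant(obs, stim, tls, "report", 4)
        assert np.sum(rec.pupil == 0.0) > 0
        assert np.isnan(rec.gaze_x[rec.pupil == 0.0]).all()

    def test_mixed_time_fraction_on_target(self, stim):
        """Generated mixed-report time within 1 SE of the configured rate."""
        obs = quiet_observer(mixed_rate=0.0286, report_latency_sd=0.3)
        tls = make_timelines(stim, 5)
        rec = simulate_participant(obs, stim, tls, "report", 6)
        fracs = []
        for ev in rec.reports:
            ev = sorted(ev)
            times = [t for t, _ in ev] + [stim.trial_duration]
            mixed = sum(t1 - t0 for (t0, k), t1 in zip(ev, times[1:]) if k == "mixed")
            fracs.append(mixed / stim.trial_duration)
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / math.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.0286) <= max(se, 1e-4) + 1e-9


class TestCohort:
    def test_perfect_trait_correlation(self):
        cfg = CohortConfig(trait_correlation=1.0, amp_noise_sd=0.0, seed=1)
        aq, amp, _, _ = draw_cohort_params(cfg)
        # rounding/truncation of AQ only; the underlying link is exact
        r = np.corrcoef(aq, amp)[0, 1]
        assert r > 0.99

    def test_null_trait_correlation_large_cohort(self):
        cfg = CohortConfig(trait_correlation=0.0, n_participants=500, seed=2)
        aq, amp, _, _ = draw_cohort_params(cfg)
        assert abs(np.corrcoef(aq, amp)[0, 1]) < 0.15

    def test_default_cohort_size_and_reproducibility(self, stim):
        cfg = CohortConfig(n_participants=4, seed=9)
        small = StimulusConfig(trial_duration=10.0, trials_per_participant=2)
        a = simulate_cohort(cfg, small)
        b = simulate_cohort(cfg, small)
        assert CohortConfig().n_participants == 53
        assert len(a.recordings) == 4
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.pupil, rb.pupil)
            np.testing.assert_array_equal(ra.gaze_x, rb.gaze_x)
            assert ra.reports == rb.reports

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(trait_correlation=1.5).validate()
        with pytest.raises(ConfigError):
            CohortConfig(n_participants=2).validate()
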