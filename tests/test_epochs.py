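"""Epoch parsing, exclusion, baseline, indices, accuracy, split-half."""

import numpy as np
import pytest

from pupilstyle import AnalysisConfig
from pupilstyle.epochs import (Epoch, aggregate_and_index, baseline_correct,
                               exclude_epochs, mixed_fraction, parse_epochs,
                               participant_indices, report_accuracy,
                               split_half_indices)
from pupilstyle.preprocess import preprocess_recording
from pupilstyle.synth import make_timelines, simulate_participant

from conftest import quiet_observer


def _epoch(samples, label=1):
    return Epoch("P", 0, "swap", 30.0, label, np.asarray(samples, dtype=float))


class TestParse:
    def test_central_event_full_coverage(self):
        trace = np.arange(600, dtype=float)
        eps = parse_epochs(trace[None, :], [[(30.0, 1)]], "swap")
        assert len(eps) == 1
        assert eps[0].samples.size == 100
        np.testing.assert_array_equal(eps[0].samples, trace[250:350])

    def test_early_event_padded(self):
        trace = np.zeros((1, 600))
        eps = parse_epochs(trace, [[(3.0, -1)]], "swap")
        assert np.isnan(eps[0].samples[:20]).all()
        assert np.isfinite(eps[0].samples[20:]).all()

    def test_one_epoch_per_event_despite_overlap(self):
        events = [[(10.0 + 2.0 * k, (-1) ** k) for k in range(12)]]
        eps = parse_epochs(np.zeros((1, 600)), events, "swap")
        assert len(eps) == 12

    def test_out_of_trial_event_skipped(self):
        eps = parse_epochs(np.zeros((1, 600)), [[(-1.0, 1), (61.0, 1)]], "swap")
        assert eps == []


class TestExcludeAndBaseline:
    def test_threshold_is_strict(self):
        at_30 = _epoch(np.r_[np.full(30, np.nan), np.zeros(70)])
        at_31 = _epoch(np.r_[np.full(31, np.nan), np.zeros(69)])
        at_35 = _epoch(np.r_[np.full(35, np.nan), np.zeros(65)])
        clean = _epoch(np.zeros(100))
        kept = exclude_epochs([at_30, at_31, at_35, clean])
        assert kept == [at_30, clean]

    def test_constant_epoch_baselines_to_zero(self):
        out = baseline_correct(_epoch(np.full(100, 4.0)))
        np.testing.assert_array_equal(out.samples, np.zeros(100))

    def test_median_of_two_pre_event_bins(self):
        s = np.full(100, 4.3)
        s[48], s[49] = 3.9, 4.1           # the 200 ms before the event
        out = baseline_correct(_epoch(s))
        assert out.samples[50] == pytest.approx(0.3)

    def test_fallback_to_nearest_preceding_bin(self):
        s = np.full(100, 4.5)
        s[48] = s[49] = np.nan
        s[47] = 4.0
        out = baseline_correct(_epoch(s))
        assert out.samples[50] == pytest.approx(0.5)

    def test_no_valid_pre_event_bin_drops_epoch(self):
        s = np.full(100, np.nan)
        s[50:] = 4.0
        assert baseline_correct(_epoch(s)) is None

    def test_exclude_option_drops_instead_of_fallback(self):
        s = np.full(100, 4.0)
        s[48] = s[49] = np.nan
        cfg = AnalysisConfig(baseline_fallback="exclude")
        assert baseline_correct(_epoch(s), cfg) is None


class TestAggregate:
    def test_constructed_separation_is_exact(self):
        """+0.2 vs -0.2 mm traces give a 0.4 mm difference, exactly."""
        black = [_epoch(np.full(100, 0.2), 1) for _ in range(5)]
        white = [_epoch(np.full(100, -0.2), -1) for _ in range(4)]
        out = aggregate_and_index(black + white, (0.0, 2.0), (1.0, 2.0))
        assert out["diff"] == pytest.approx(0.4, rel=1e-12)
        assert out["mean_response"] == 0.0

    def test_identical_traces_zero_difference(self):
        eps = [_epoch(np.linspace(0, 1, 100), lab) for lab in (1, -1)]
        out = aggregate_and_index(eps, (0.0, 2.0), (1.0, 2.0))
        assert out["diff"] == pytest.approx(0.0)
        tr = np.linspace(0, 1, 100)
        assert out["mean_response"] == pytest.approx(tr[60:70].mean())

    def test_median_robust_to_epoch_duplication(self):
        """Duplicating every epoch in both labels leaves the index unchanged."""
        rng = np.random.default_rng(3)
        eps = [_epoch(rng.normal(size=100), lab) for lab in (1, 1, 1, -1, -1, -1)]
        a = aggregate_and_index(eps, (0.0, 2.0))["diff"]
        b = aggregate_and_index(eps + eps, (0.0, 2.0))["diff"]
        assert a == pytest.approx(b)

    def test_missing_label_undefined(self):
        eps = [_epoch(np.zeros(100), 1)]
        assert np.isnan(aggregate_and_index(eps, (0.0, 2.0))["diff"])


class TestAccuracy:
    def test_identical_channels(self):
        rng = np.random.default_rng(0)
        s = np.sign(rng.normal(size=600))
        acc, lat = report_accuracy(s, s)
        assert acc == pytest.approx(1.0)
        assert lat == 0.0

    def test_inverted_channels(self):
        # slow square wave (quarter period beyond the 5 s lag range) so the
        # autocorrelation stays positive over every scanned lag
        s = np.sign(np.sin(2 * np.pi * np.arange(600) / 250.0))
        acc, lat = report_accuracy(-s, s)
        assert acc <= 0.0
        assert np.corrcoef(-s, s)[0, 1] == pytest.approx(-1.0)

    def test_delayed_report_peaks_at_delay(self):
        rng = np.random.default_rng(2)
        s = np.sign(np.cumsum(rng.normal(size=1200)))
        lag = 10                           # 1.0 s at 10 Hz
        rep = np.r_[np.full(lag, np.nan), s[:-lag]]
        acc, lat = report_accuracy(rep, s)
        assert lat == pytest.approx(1.0)
        assert acc > 0.95

    def test_matches_bruteforce_lag_scan(self):
        """Exact agreement with an independent per-lag Pearson loop."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = np.sign(np.cumsum(rng.normal(size=400)))
            r = np.sign(np.cumsum(rng.normal(size=400)))
            if np.ptp(s) == 0 or np.ptp(r) == 0:
                continue              # degenerate draw: accuracy undefined
            acc, lat = report_accuracy(r, s)
            best, best_lag = -np.inf, None
            for k in range(0, 51):
                a, b = s[:400 - k] if k else s, r[k:]
                c = np.corrcoef(a, b)[0, 1]
                if c > best:
                    best, best_lag = c, k
            assert acc == best
            assert lat == best_lag * 0.1

    def test_constant_report_flagged(self):
        acc, lat = report_accuracy(np.ones(600), np.sign(np.sin(np.arange(600))))
        assert np.isnan(acc) and np.isnan(lat)


class TestMixedFraction:
    def test_no_mixed_presses(self):
        assert mixed_fraction([[(1.0, "cw"), (5.0, "ccw")]], 60.0) == 0.0

    def test_three_seconds_in_sixty(self):
        ev = [(0.0, "cw"), (10.0, "mixed"), (13.0, "ccw")]
        assert mixed_fraction([ev], 60.0) == pytest.approx(5.0)


class TestPipelineIndices:
    def test_step_model_recovers_04mm(self, stim):
        """Noiseless instantaneous-kernel simulant: pupil_diff = 0.4 mm.

        Ramp ends fall on 100 ms bin edges when intervals are exactly 5 s,
        so every epoch is an exact two-level step; the only residual is the
        interaction with per-trial line removal (order 1e-3 mm).
        """
        from pupilstyle import StimulusConfig

        cfg = StimulusConfig(swap_sd=0.0, swap_outlier_frac=0.0)
        obs = quiet_observer(sustained_amp=0.1, sustained_tau=0.0)
        tls = make_timelines(cfg, 31)
        rec = simulate_participant(obs, cfg, tls, "report", 32)
        ch = preprocess_recording(rec)
        idx = participant_indices(ch, rec)
        assert idx.pupil_diff == pytest.approx(0.4, abs=0.01)

    def test_positive_sign_convention(self, stim):
        """Dilating when black dots are in front gives pupil_diff > 0."""
        obs = quiet_observer(sustained_amp=0.08)
        tls = make_timelines(stim, 41)
        rec = simulate_participant(obs, stim, tls, "report", 42)
        ch = preprocess_recording(rec)
        idx = participant_indices(ch, rec)
        assert idx.pupil_diff > 0

    def test_gaze_velocity_difference_positive_for_front_tracker(self, stim):
        obs = quiet_observer(okn_gain=0.8)
        tls = make_timelines(stim, 51)
        rec = simulate_participant(obs, stim, tls, "report", 52)
        ch = preprocess_recording(rec)
        idx = participant_indices(ch, rec)
        # slow phases separate by ~2 * gain * mean surface speed
        assert idx.gaze_vel_diff > 0
        assert idx.gaze_vel_diff == pytest.approx(2 * 0.8 * (2 / np.pi) * 3.9,
                                                  rel=0.15)

    def test_split_half_identical_for_noiseless(self, stim):
        """With every trial statistically identical, odd == even indices."""
        from pupilstyle import StimulusConfig

        cfg = StimulusConfig(swap_sd=0.0, swap_outlier_frac=0.0)
        obs = quiet_observer(sustained_amp=0.1, sustained_tau=0.0)
        tls = make_timelines(cfg, 61)
        rec = simulate_participant(obs, cfg, tls, "report", 62)
        ch = preprocess_recording(rec)
        odd, even = split_half_indices(ch, rec)
        # residual difference comes only from the per-trial line removal
        # interacting with each half's label pattern (order 1e-3 mm)
        assert odd.pupil_diff == pytest.approx(even.pupil_diff, abs=0.005)

    def test_no_report_mode_has_no_switch_indices(self, stim):
        obs = quiet_observer(sustained_amp=0.05)
        tls = make_timelines(stim, 71)
        rec = simulate_participant(obs, stim, tls, "no-report", 72)
        ch = preprocess_recording(rec)
        idx = participant_indices(ch, rec)
        assert np.isnan(idx.pupil_diff_switch)
        assert np.isnan(idx.accuracy)
        assert np.isfinite(idx.pupil_diff)
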