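"""Event-locked epoch parsing and per-participant perceptual-style indices.

10 Hz traces are parsed into 10 s segments centered on either a stereo-depth
swap (reference: end of the disparity ramp) or a perceptual switch
(reference: the keypress). Segments are labeled by the post-event foreground
color (black/white in front — stereo-defined for swap alignment, reported
for switch alignment), screened for missing pupil data, baseline-corrected,
and aggregated into per-label median traces. Scalar indices summarize the
separation of the two traces (the perceptual-style measure), the overall
event-locked response, report accuracy/latency via cross-correlation, and
the mixed-percept rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .preprocess import Channels10Hz, nanmedian_lastaxis
from .synth import Recording, StimulusTimeline

__all__ = [
    "Epoch", "ParticipantIndices", "parse_epochs", "exclude_epochs",
    "baseline_correct", "aggregate_and_index", "report_accuracy",
    "mixed_fraction", "participant_indices", "split_half_indices",
]


@dataclass(eq=False)
class Epoch:
    """One event-locked 10 s segment on the [-5, +5) s 10 Hz grid."""

    participant: str
    trial_id: int
    alignment: str               # 'swap' | 'switch'
    t0: float                    # event reference time within the trial, s
    label: int                   # +1 black in front after the event, -1 white
    samples: np.ndarray          # 100 values, NaN = missing
    missing_frac: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.missing_frac = float(np.mean(~np.isfinite(self.samples)))


def parse_epochs(trace_by_trial: np.ndarray,
                 events: Sequence[Sequence[Tuple[float, int]]],
                 alignment: str, participant: str = "",
                 cfg: Optional[AnalysisConfig] = None,
                 bin_s: float = 0.1) -> List[Epoch]:
    """Cut event-locked epochs out of per-trial 10 Hz traces.

    ``events[i]`` lists ``(t0, label)`` pairs for trial ``i``. Epochs may
    overlap; portions outside the trial are padded with NaN; events outside
    the trial bounds are skipped.
    """
    cfg = cfg or AnalysisConfig()
    half_bins = int(round(cfg.epoch_halfwidth / bin_s))
    n_bins_epoch = 2 * half_bins
    out: List[Epoch] = []
    for trial_id, trial_events in enumerate(events):
        trace = np.asarray(trace_by_trial[trial_id], dtype=float)
        n = trace.size
        for t0, label in trial_events:
            if not 0.0 <= t0 < n * bin_s:
                continue
            i0 = int(math.floor(t0 / bin_s + 0.5)) - half_bins
            seg = np.full(n_bins_epoch, np.nan)
            j0, j1 = max(i0, 0), min(i0 + n_bins_epoch, n)
            if j1 > j0:
                seg[j0 - i0:j1 - i0] = trace[j0:j1]
            out.append(Epoch(participant, trial_id, alignment, float(t0),
                             int(label), seg))
    return out


def exclude_epochs(epochs: Iterable[Epoch], threshold: float = 0.30) -> List[Epoch]:
    """Drop epochs with strictly more than ``threshold`` missing pupil data."""
    return [e for e in epochs if e.missing_frac <= threshold]


def baseline_correct(epoch: Epoch, cfg: Optional[AnalysisConfig] = None,
                     bin_s: float = 0.1) -> Optional[Epoch]:
    """Subtract the median pupil of the 200 ms immediately preceding the event.

    If both baseline bins are missing, the nearest preceding valid bin is
    used instead (or the epoch is dropped, with ``baseline_fallback =
    'exclude'``). Returns None when no valid pre-event bin exists.
    """
    cfg = cfg or AnalysisConfig()
    half = int(round(cfg.epoch_halfwidth / bin_s))
    nb = int(round(cfg.baseline_window / bin_s))
    base = epoch.samples[half - nb:half]
    base = base[np.isfinite(base)]
    if base.size:
        b = float(np.median(base))
    elif cfg.baseline_fallback == "nearest":
        prior = epoch.samples[:half - nb]
        valid = np.flatnonzero(np.isfinite(prior))
        if valid.size == 0:
            return None
        b = float(prior[valid[-1]])
    else:
        return None
    return replace(epoch, samples=epoch.samples - b)


def _window_bins(window: Tuple[float, float], halfwidth: float, bin_s: float) -> slice:
    i0 = int(round((window[0] + halfwidth) / bin_s))
    i1 = int(round((window[1] + halfwidth) / bin_s))
    return slice(i0, i1)


def aggregate_and_index(epochs: Sequence[Epoch],
                        index_window: Tuple[float, float],
                        mean_window: Optional[Tuple[float, float]] = None,
                        cfg: Optional[AnalysisConfig] = None,
                        bin_s: float = 0.1) -> Dict[str, object]:
    """Per-label median traces and their scalar separation.

    Returns the black-front and white-front median traces (bin-wise across
    epochs, ignoring missing), ``diff`` = mean over the index window of
    (black - white), and ``mean_response`` = the two traces averaged
    together over ``mean_window``. Indices are NaN when a label has no
    epochs or its window is entirely missing.
    """
    cfg = cfg or AnalysisConfig()
    traces = {}
    for label in (1, -1):
        mat = [e.samples for e in epochs if e.label == label]
        traces[label] = (nanmedian_lastaxis(np.stack(mat, axis=0).T)
                         if mat else np.full(int(2 * cfg.epoch_halfwidth / bin_s), np.nan))
    win = _window_bins(index_window, cfg.epoch_halfwidth, bin_s)
    d = traces[1][win] - traces[-1][win]
    diff = float(np.nanmean(d)) if np.isfinite(d).any() else float("nan")
    mean_resp = float("nan")
    if mean_window is not None:
        mwin = _window_bins(mean_window, cfg.epoch_halfwidth, bin_s)
        m = 0.5 * (traces[1][mwin] + traces[-1][mwin])
        if np.isfinite(m).any():
            mean_resp = float(np.nanmean(m))
    return {"trace_black": traces[1], "trace_white": traces[-1],
            "diff": diff, "mean_response": mean_resp,
            "n_black": sum(e.label == 1 for e in epochs),
            "n_white": sum(e.label == -1 for e in epochs)}


def _interp_interior(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate interior NaNs; leading/trailing NaNs become edge values."""
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if not ok.any() or ok.all():
        return x.copy()
    idx = np.arange(x.size)
    return np.interp(idx, idx[ok], x[ok])


def report_accuracy(report_10hz: np.ndarray, stereo_10hz: np.ndarray,
                    cfg: Optional[AnalysisConfig] = None,
                    bin_s: float = 0.1) -> Tuple[float, float]:
    """Peak cross-correlation between report and stereo-depth state streams.

    Channels (per-trial rows or already-concatenated vectors, signed state
    coding) are concatenated in acquisition order, missing values filled by
    linear interpolation, and the normalized (Pearson) cross-correlation
    evaluated on the 10 Hz lag grid over [0, xcorr_max_lag] s (reports
    cannot precede the stimulus). Returns (peak value, lag of the peak in
    seconds); ties break toward the smallest lag. A constant report channel
    yields (nan, nan) — the participant is excluded from accuracy analyses.
    """
    cfg = cfg or AnalysisConfig()
    rep = _interp_interior(np.ravel(report_10hz))
    ste = _interp_interior(np.ravel(stereo_10hz))
    ok = np.isfinite(rep) & np.isfinite(ste)
    rep, ste = rep[ok], ste[ok]
    if rep.size < 3 or np.ptp(rep) == 0 or np.ptp(ste) == 0:
        return float("nan"), float("nan")
    max_lag = int(round(cfg.xcorr_max_lag / bin_s))
    best_r, best_lag = -np.inf, 0
    for lag in range(0, max_lag + 1):
        a = ste[:ste.size - lag] if lag else ste
        b = rep[lag:]
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        return float("nan"), float("nan")
    return best_r, best_lag * bin_s


def mixed_fraction(reports: Sequence[Sequence[Tuple[float, str]]],
                   trial_duration: float) -> float:
    """Percent of reporting time spent in the mixed-percept state.

    Reporting time runs from the first keypress of each trial to trial end;
    trials with no keypresses contribute nothing.
    """
    mixed = total = 0.0
    for ev in reports:
        if not ev:
            continue
        ev = sorted(ev, key=lambda e: e[0])
        times = [t for t, _ in ev] + [trial_duration]
        total += trial_duration - times[0]
        for (t0, key), t1 in zip(ev, times[1:]):
            if key == "mixed":
                mixed += t1 - t0
    return 100.0 * mixed / total if total > 0 else float("nan")


# ---------------------------------------------------------------------------
# Participant-level index pipeline
# ---------------------------------------------------------------------------

@dataclass
class ParticipantIndices:
    """Scalar perceptual-style indices of one participant."""

    participant: str
    aq: Optional[int]
    pupil_diff: float            # mm, black-front minus white-front (swap-aligned)
    mean_response: float         # mm, overall swap-locked response
    gaze_vel_diff: float         # deg/s, swap-aligned slow-phase separation
    pupil_diff_switch: float     # mm, switch-aligned counterpart
    mean_response_switch: float
    accuracy: float              # peak report/stereo cross-correlation
    latency: float               # s, lag of that peak
    mixed_pct: float
    n_swap_segments: int
    n_switch_segments: int


def _swap_events(tl: StimulusTimeline) -> List[Tuple[float, int]]:
    return [(end, 1 if color == "black" else -1) for _, end, color in tl.swap_events]


def _switch_events(events: Sequence[Tuple[float, str]],
                   tl: StimulusTimeline) -> List[Tuple[float, int]]:
    """CW<->CCW keypress transitions labeled by the reported foreground color."""
    dir_black_cw = tl.black_direction == "left"
    out: List[Tuple[float, int]] = []
    prev = None
    for t0, key in sorted(events, key=lambda e: e[0]):
        if key == "mixed":
            continue
        if prev is not None and key != prev:
            black_front = (key == "cw") == dir_black_cw
            out.append((t0, 1 if black_front else -1))
        prev = key
    return out


def _index_set(ch: Channels10Hz, events, alignment: str, cfg: AnalysisConfig,
               baseline_pupil: bool = True):
    """Pupil + gaze-velocity indices for one alignment."""
    if alignment == "swap":
        iw, mw = cfg.swap_index_window, cfg.swap_mean_window
    else:
        iw, mw = cfg.switch_index_window, cfg.switch_mean_window
    pupil_ep = parse_epochs(ch.pupil, events, alignment, ch.participant, cfg, ch.bin_s)
    pupil_ep = exclude_epochs(pupil_ep, cfg.missing_threshold)
    if baseline_pupil:
        pupil_ep = [b for e in pupil_ep
                    if (b := baseline_correct(e, cfg, ch.bin_s)) is not None]
    pupil_agg = aggregate_and_index(pupil_ep, iw, mw, cfg, ch.bin_s)
    gaze_ep = parse_epochs(ch.gaze_velocity, events, alignment, ch.participant,
                           cfg, ch.bin_s)
    gaze_agg = aggregate_and_index(gaze_ep, iw, None, cfg, ch.bin_s)
    return pupil_agg, gaze_agg, len(pupil_ep)


def participant_indices(ch: Channels10Hz, rec: Recording,
                        cfg: Optional[AnalysisConfig] = None,
                        trial_subset: Optional[Sequence[int]] = None) -> ParticipantIndices:
    """Compute every scalar index for one participant.

    ``trial_subset`` restricts the computation to the given trial indices
    (used by the split-half analysis); accuracy, latency and mixed rate are
    computed on the same subset.
    """
    cfg = cfg or AnalysisConfig()
    trials = list(trial_subset) if trial_subset is not None \
        else list(range(ch.n_trials))
    pupil = ch.pupil[trials]
    gazev = ch.gaze_velocity[trials]
    sub = Channels10Hz(ch.participant, pupil, gazev, ch.stereo[trials],
                       ch.report[trials], ch.bin_s)
    tls = [rec.timelines[i] for i in trials]
    reports = [rec.reports[i] for i in trials] if rec.reports else []

    swap_ev = [_swap_events(tl) for tl in tls]
    p_sw, g_sw, n_sw = _index_set(sub, swap_ev, "swap", cfg)

    has_reports = rec.mode == "report" and any(reports)
    if has_reports:
        switch_ev = [_switch_events(reports[k], tls[k]) for k in range(len(tls))]
        p_pc, _, n_pc = _index_set(sub, switch_ev, "switch", cfg)
        acc, lat = report_accuracy(sub.report, sub.stereo, cfg, ch.bin_s)
        mixed = mixed_fraction(reports, tls[0].trial_duration)
    else:
        p_pc = {"diff": float("nan"), "mean_response": float("nan")}
        n_pc, acc, lat, mixed = 0, float("nan"), float("nan"), float("nan")

    return ParticipantIndices(
        participant=ch.participant, aq=rec.aq,
        pupil_diff=p_sw["diff"], mean_response=p_sw["mean_response"],
        gaze_vel_diff=g_sw["diff"],
        pupil_diff_switch=p_pc["diff"], mean_response_switch=p_pc["mean_response"],
        accuracy=acc, latency=lat, mixed_pct=mixed,
        n_swap_segments=n_sw, n_switch_segments=n_pc)


def split_half_indices(ch: Channels10Hz, rec: Recording,
                       cfg: Optional[AnalysisConfig] = None
                       ) -> Tuple[ParticipantIndices, ParticipantIndices]:
    """Indices computed independently on odd and even trials (1-based order)."""
    odd = list(range(0, ch.n_trials, 2))    # trials 1, 3, 5, ... in 1-based order
    even = list(range(1, ch.n_trials, 2))
    return (participant_indices(ch, rec, cfg, odd),
            participant_indices(ch, rec, cfg, even))
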