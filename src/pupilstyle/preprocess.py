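"""Pupil and gaze signal conditioning.

Pupil channel: gross artifact removal (trial-median band, absolute floor),
fine artifact removal (physiologically implausible rates of change, purging
the surrounding 20 ms), then per-trial mean/linear-trend subtraction.
Gaze channel: recoding into black-dot coordinates, 20 ms box-car smoothing,
differentiation, and removal of speeds above the peak stimulus speed (which
strips saccadic fast phases, leaving OKN slow phases). All channels are then
median-downsampled onto a common 10 Hz grid, with empty bins set to NaN.

Missing samples are NaN throughout; arrays are one trial per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .config import AnalysisConfig, PreprocConfig
from .synth import Recording

__all__ = [
    "remove_pupil_artifacts", "detrend_trial", "recode_gaze",
    "slow_gaze_velocity", "downsample_10hz", "nanmedian_lastaxis",
    "Channels10Hz", "preprocess_recording",
]


def nanmedian_lastaxis(a: np.ndarray) -> np.ndarray:
    """Median over the last axis ignoring NaNs; all-NaN rows give NaN.

    Sort-based and vectorized (np.nanmedian is slow on many small slices).
    Even counts take the midpoint of the two central values.
    """
    a = np.asarray(a, dtype=float)
    s = np.sort(a, axis=-1)                       # NaNs sort to the end
    cnt = np.sum(np.isfinite(a), axis=-1)
    safe = np.maximum(cnt, 1)
    lo = np.take_along_axis(s, ((safe - 1) // 2)[..., None], axis=-1)[..., 0]
    hi = np.take_along_axis(s, (safe // 2)[..., None], axis=-1)[..., 0]
    med = 0.5 * (lo + hi)
    return np.where(cnt > 0, med, np.nan)


def remove_pupil_artifacts(pupil: np.ndarray, cfg: Optional[PreprocConfig] = None,
                           sample_rate: float = 500.0) -> np.ndarray:
    """Invalidate blink/artifact samples in one trial's pupil trace (-> NaN).

    Two passes, gross first:

    1. samples farther than ``pupil_median_band`` from the trial median
       (median over all finite samples) or below ``pupil_floor`` are removed;
    2. where the pupil changes faster than ``pupil_max_speed`` between
       adjacent retained samples (actual time difference, so gaps do not
       create spurious spikes), the 20 ms epoch surrounding the disturbance
       (±10 ms around the offending pair) is removed.
    """
    cfg = cfg or PreprocConfig()
    p = np.asarray(pupil, dtype=float).copy()
    finite = np.isfinite(p)
    if not finite.any():
        return p
    med = np.median(p[finite])
    bad = finite & ((np.abs(p - med) > cfg.pupil_median_band) | (p < cfg.pupil_floor))
    p[bad] = np.nan

    idx = np.flatnonzero(np.isfinite(p))
    if idx.size >= 2:
        dt = np.diff(idx) / sample_rate
        speed = np.abs(np.diff(p[idx])) / dt
        half = int(round(cfg.purge_epoch_ms / 2000.0 * sample_rate))
        for k in np.flatnonzero(speed > cfg.pupil_max_speed):
            j0 = max(idx[k] - half, 0)
            j1 = min(idx[k + 1] + half + 1, p.size)
            p[j0:j1] = np.nan
    return p


def detrend_trial(y: np.ndarray, t: Optional[np.ndarray] = None,
                  sample_rate: float = 500.0) -> np.ndarray:
    """Subtract the least-squares line (fit on valid samples) from one trial.

    Removes both the mean and the linear trend; NaNs stay NaN. Returns an
    all-NaN trace (flagged unusable upstream) if fewer than 2 valid samples.
    """
    y = np.asarray(y, dtype=float).copy()
    if t is None:
        t = np.arange(y.size) / sample_rate
    ok = np.isfinite(y)
    n = ok.sum()
    if n < 2:
        y[:] = np.nan
        return y
    # closed-form OLS on the valid subset
    tv, yv = t[ok], y[ok]
    tbar, ybar = tv.mean(), yv.mean()
    dt = tv - tbar
    denom = float(dt @ dt)
    if denom == 0:
        return y - ybar
    b = float(dt @ (yv - ybar)) / denom
    return y - (ybar + b * (t - tbar))


def recode_gaze(gaze_x: np.ndarray, black_direction: str) -> np.ndarray:
    """Flip horizontal gaze so positive deviations point along the black dots."""
    if black_direction not in ("left", "right"):
        raise ValueError("black_direction must be 'left' or 'right'")
    g = np.asarray(gaze_x, dtype=float)
    return -g if black_direction == "left" else g.copy()


def slow_gaze_velocity(gaze_x: np.ndarray, cfg: Optional[PreprocConfig] = None,
                       sample_rate: float = 500.0) -> np.ndarray:
    """Slow-phase gaze velocity (deg/s) from recoded horizontal gaze.

    Box-car smoothing (centered, truncated at trace edges and around gaps),
    first difference scaled by the sample rate (one-sided at the first
    sample), then removal of speeds above the stimulus peak, which excises
    the saccadic fast phases of the nystagmus. Missing gaze propagates.
    """
    cfg = cfg or PreprocConfig()
    g = np.asarray(gaze_x, dtype=float)
    w = max(int(round(cfg.boxcar_ms / 1000.0 * sample_rate)), 1)
    finite = np.isfinite(g)
    num = np.convolve(np.where(finite, g, 0.0), np.ones(w), mode="same")
    den = np.convolve(finite.astype(float), np.ones(w), mode="same")
    sm = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    sm[~finite] = np.nan                      # missing input stays missing

    v = np.empty_like(sm)
    v[1:] = (sm[1:] - sm[:-1]) * sample_rate
    v[0] = v[1] if sm.size > 1 else np.nan
    v[np.abs(v) > cfg.gaze_speed_cap] = np.nan
    return v


def downsample_10hz(x: np.ndarray, cfg: Optional[PreprocConfig] = None,
                    sample_rate: float = 500.0) -> np.ndarray:
    """Median-downsample a 500 Hz trace onto the 10 Hz grid.

    Non-overlapping half-open 100 ms windows, left-edge timestamped; each
    bin is the median of its retained (finite) samples, or NaN if none.
    Accepts a 1-D trial or a (trials, samples) array.
    """
    cfg = cfg or PreprocConfig()
    x = np.asarray(x, dtype=float)
    per = int(round(cfg.bin_ms / 1000.0 * sample_rate))
    n_bins = x.shape[-1] // per
    trimmed = x[..., :n_bins * per]
    shaped = trimmed.reshape(x.shape[:-1] + (n_bins, per))
    return nanmedian_lastaxis(shaped)


# ---------------------------------------------------------------------------
# Whole-recording pipeline
# ---------------------------------------------------------------------------

@dataclass
class Channels10Hz:
    """All four 10 Hz channels of one participant, one trial per row.

    ``stereo`` and ``report`` are signed state channels: +1 black dots in
    front (stereo-defined or reported), -1 white in front, 0 mixed percept,
    NaN before the first keypress of a trial (report channel only).
    """

    participant: str
    pupil: np.ndarray            # mm, detrended
    gaze_velocity: np.ndarray    # deg/s, black-dot coordinates
    stereo: np.ndarray
    report: np.ndarray
    bin_s: float = 0.1
    qc: Dict[str, float] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.pupil.shape[0]

    def bin_times(self) -> np.ndarray:
        return np.arange(self.pupil.shape[1]) * self.bin_s


def _report_state_500hz(events, timeline, n_samples: int, fs: float) -> np.ndarray:
    """Materialize keypress events as a signed perceived-foreground state trace."""
    dir_black_cw = timeline.black_direction == "left"
    code = {"mixed": 0.0, "cw": 1.0 if dir_black_cw else -1.0,
            "ccw": -1.0 if dir_black_cw else 1.0}
    ev = sorted(events, key=lambda e: e[0])
    times = np.array([t0 for t0, _ in ev])
    vals = np.array([np.nan] + [code[key] for _, key in ev])
    idx = np.searchsorted(times, np.arange(n_samples) / fs, side="right")
    return vals[idx]


def preprocess_recording(rec: Recording, cfg: Optional[PreprocConfig] = None) -> Channels10Hz:
    """Run the full conditioning pipeline on one raw recording.

    Order of operations: pupil — artifact removal, detrend, downsample;
    gaze — recode, smooth, differentiate, speed-cap, downsample; stimulus
    stereo-depth and perceptual-report state streams are materialized on the
    500 Hz grid and downsampled identically.
    """
    cfg = cfg or PreprocConfig()
    cfg.validate()
    fs = rec.sample_rate
    n_tr, n_s = rec.pupil.shape
    t = rec.times()

    pupil = np.empty_like(rec.pupil)
    gazev = np.empty_like(rec.pupil)
    stereo = np.empty_like(rec.pupil)
    report = np.empty_like(rec.pupil)
    n_invalid_gross = 0
    for i, tl in enumerate(rec.timelines):
        clean = remove_pupil_artifacts(rec.pupil[i], cfg, fs)
        n_invalid_gross += int(np.sum(~np.isfinite(clean)))
        pupil[i] = detrend_trial(clean, t, fs)
        gx = recode_gaze(rec.gaze_x[i], tl.black_direction)
        gazev[i] = slow_gaze_velocity(gx, cfg, fs)
        stereo[i] = tl.foreground_sign(t)
        report[i] = _report_state_500hz(rec.reports[i] if rec.reports else [],
                                        tl, n_s, fs)

    qc = {
        "frac_pupil_invalidated": n_invalid_gross / float(n_tr * n_s),
        "frac_gaze_velocity_missing": float(np.mean(~np.isfinite(gazev))),
    }
    return Channels10Hz(
        participant=rec.participant,
        pupil=downsample_10hz(pupil, cfg, fs),
        gaze_velocity=downsample_10hz(gazev, cfg, fs),
        stereo=downsample_10hz(stereo, cfg, fs),
        report=downsample_10hz(report, cfg, fs),
        bin_s=1.0 / cfg.out_rate, qc=qc)
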