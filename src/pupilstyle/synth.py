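"""Synthetic cohort generator for the bistable rotating-cylinder experiment.

Produces stimulus timelines (stochastic stereo-depth swap schedules with
linear disparity ramps), raw 500 Hz eye-tracker style recordings (pupil
diameter in mm, horizontal/vertical gaze in deg) and keypress report events,
with the statistical structure the downstream analysis assumes: a sustained
foreground-color-locked pupil modulation whose amplitude covaries with AQ
across the cohort, transient swap-locked constrictions and keypress-locked
dilations, blinks, and antagonistic OKN-like gaze.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import CohortConfig, ConfigError, ObserverModel, StimulusConfig

__all__ = [
    "StimulusTimeline", "Recording", "Cohort",
    "draw_swap_intervals", "draw_swap_schedule", "build_timeline",
    "dot_velocity", "mean_surface_speed", "foreground_velocity",
    "simulate_participant", "simulate_cohort",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stimulus timelines
# ---------------------------------------------------------------------------

@dataclass
class StimulusTimeline:
    """Stereo-depth state of one trial.

    ``ramp_onsets`` are the start times of the linear disparity transitions;
    each ramp lasts ``ramp_duration``. The perceived foreground color flips
    at the ramp midpoint (the disparity zero-crossing). ``black_direction``
    is the constant motion direction of the black dots in this trial.
    """

    trial_id: int
    black_direction: str                 # 'left' | 'right'
    ramp_onsets: np.ndarray              # s, strictly increasing
    ramp_duration: float
    trial_duration: float
    disparity_amp: float                 # arcmin
    initial_foreground: str              # 'black' | 'white'

    def __post_init__(self):
        self.ramp_onsets = np.asarray(self.ramp_onsets, dtype=float)
        if self.ramp_onsets.size and np.any(np.diff(self.ramp_onsets) < self.ramp_duration):
            raise ConfigError("overlapping disparity ramps in swap schedule")
        if self.black_direction not in ("left", "right"):
            raise ConfigError("black_direction must be 'left' or 'right'")
        if self.initial_foreground not in ("black", "white"):
            raise ConfigError("initial_foreground must be 'black' or 'white'")

    @property
    def ramp_ends(self) -> np.ndarray:
        return self.ramp_onsets + self.ramp_duration

    @property
    def flip_times(self) -> np.ndarray:
        """Perceptual flip times: disparity zero-crossings at ramp midpoints."""
        return self.ramp_onsets + 0.5 * self.ramp_duration

    @property
    def swap_events(self) -> List[Tuple[float, float, str]]:
        """(ramp_onset, ramp_end, post-swap foreground color) per swap."""
        s0 = 1.0 if self.initial_foreground == "black" else -1.0
        out = []
        for k, (a, b) in enumerate(zip(self.ramp_onsets, self.ramp_ends)):
            color = "black" if s0 * (-1.0) ** (k + 1) > 0 else "white"
            out.append((float(a), float(b), color))
        return out

    def foreground_sign(self, t) -> np.ndarray:
        """+1 where the black dots are in front, -1 where the white dots are."""
        t = np.asarray(t, dtype=float)
        s0 = 1.0 if self.initial_foreground == "black" else -1.0
        flips = np.searchsorted(self.flip_times, t, side="right")
        return s0 * (1.0 - 2.0 * (flips & 1))

    def disparity(self, t) -> np.ndarray:
        """Black-dot disparity in arcmin (positive = black in front), piecewise linear."""
        t = np.asarray(t, dtype=float)
        s0 = 1.0 if self.initial_foreground == "black" else -1.0
        a = self.disparity_amp
        k = np.searchsorted(self.ramp_onsets, t, side="right")  # ramps started so far
        out = s0 * (-1.0) ** k * a                              # plateau after k flips
        if self.ramp_onsets.size:
            on = self.ramp_onsets[np.clip(k - 1, 0, None)]
            in_ramp = (k > 0) & (t < on + self.ramp_duration)
            start = s0 * (-1.0) ** (k - 1) * a
            frac = np.clip((t - on) / self.ramp_duration, 0.0, 1.0)
            out = np.where(in_ramp, start * (1.0 - 2.0 * frac), out)
        return np.asarray(out, dtype=float)


def draw_swap_intervals(cfg: StimulusConfig, n: int, rng_seed,
                        return_component: bool = False):
    """Draw ``n`` i.i.d. inter-swap intervals.

    With probability ``1 - swap_outlier_frac`` an interval comes from the
    flat (uniform) distribution whose mean and SD are ``swap_mean`` and
    ``swap_sd`` (support ``swap_mean +- swap_sd*sqrt(3)``); otherwise it is
    uniform on the outlier range. Outlier intervals shorter than the ramp
    would make consecutive ramps overlap, so the outlier range is clipped
    below at ``ramp_duration``.
    """
    cfg.validate()
    rng = _as_rng(rng_seed)
    is_outlier = rng.random(n) < cfg.swap_outlier_frac
    main = rng.uniform(cfg.swap_lo, cfg.swap_hi, size=n)
    out_lo = max(cfg.swap_outlier_lo, cfg.ramp_duration)
    outlier = rng.uniform(out_lo, cfg.swap_outlier_hi, size=n)
    intervals = np.where(is_outlier, outlier, main)
    if return_component:
        return intervals, is_outlier
    return intervals


def draw_swap_schedule(cfg: StimulusConfig, rng_seed) -> np.ndarray:
    """Ramp-onset times of one trial, truncated so every ramp completes in-trial."""
    cfg.validate()
    rng = _as_rng(rng_seed)
    # enough intervals that their sum always exceeds the trial duration
    min_iv = min(cfg.swap_lo, max(cfg.swap_outlier_lo, cfg.ramp_duration))
    n = int(math.ceil(cfg.trial_duration / min_iv)) + 2
    onsets = np.cumsum(draw_swap_intervals(cfg, n, rng))
    return onsets[onsets + cfg.ramp_duration <= cfg.trial_duration]


def build_timeline(cfg: StimulusConfig, schedule: np.ndarray, trial_id: int,
                   black_direction: str, rng_seed) -> StimulusTimeline:
    """Assemble a trial timeline; the initial foreground color is randomized."""
    rng = _as_rng(rng_seed)
    initial = "black" if rng.random() < 0.5 else "white"
    return StimulusTimeline(
        trial_id=trial_id, black_direction=black_direction,
        ramp_onsets=np.asarray(schedule, dtype=float),
        ramp_duration=cfg.ramp_duration, trial_duration=cfg.trial_duration,
        disparity_amp=cfg.disparity_amp, initial_foreground=initial)


def make_timelines(cfg: StimulusConfig, rng_seed) -> List[StimulusTimeline]:
    """Timelines for one participant: fresh schedules, pseudo-random associations."""
    rng = _as_rng(rng_seed)
    # balanced association, shuffled: constant within, varied across trials
    n = cfg.trials_per_participant
    dirs = ["left", "right"] * ((n + 1) // 2)
    dirs = list(rng.permutation(dirs[:n]))
    return [build_timeline(cfg, draw_swap_schedule(cfg, rng), tid, dirs[tid], rng)
            for tid in range(n)]


# ---------------------------------------------------------------------------
# Dot kinematics
# ---------------------------------------------------------------------------

def dot_velocity(cfg: StimulusConfig, t, surface: str, phase: float = 0.0) -> np.ndarray:
    """Horizontal velocity (deg/s) of a dot on the front or rear surface.

    Dots follow a sinusoidal velocity profile (projection of uniform 3D
    rotation) peaking at ``peak_dot_speed``; the two surfaces move in
    opposite directions. ``phase`` is the dot's angular position offset.
    """
    if surface not in ("front", "rear"):
        raise ValueError("surface must be 'front' or 'rear'")
    sgn = 1.0 if surface == "front" else -1.0
    omega = math.radians(cfg.rotation_speed)
    return sgn * cfg.peak_dot_speed * np.cos(omega * np.asarray(t, dtype=float) + phase)


def mean_surface_speed(cfg: StimulusConfig) -> float:
    """Speed of a surface averaged over its dots (uniform phase): (2/pi) * peak."""
    return 2.0 / math.pi * cfg.peak_dot_speed


def foreground_velocity(cfg: StimulusConfig, timeline: StimulusTimeline, t) -> np.ndarray:
    """Screen-coordinate mean velocity of the foreground surface (deg/s, + = rightward)."""
    dir_black = 1.0 if timeline.black_direction == "right" else -1.0
    return dir_black * timeline.foreground_sign(t) * mean_surface_speed(cfg)


# ---------------------------------------------------------------------------
# Participant simulation
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Raw 500 Hz recording of one participant (all trials)."""

    participant: str
    mode: str                                  # 'report' | 'no-report'
    timelines: List[StimulusTimeline]
    pupil: np.ndarray                          # (n_trials, n_samples) mm, 0 during blinks
    gaze_x: np.ndarray                         # (n_trials, n_samples) deg, NaN during blinks
    gaze_y: np.ndarray
    reports: List[List[Tuple[float, str]]]     # per trial: (t, key in {cw, ccw, mixed})
    sample_rate: float
    aq: Optional[int] = None
    observer: Optional[ObserverModel] = None

    @property
    def n_trials(self) -> int:
        return len(self.timelines)

    def times(self) -> np.ndarray:
        return np.arange(self.pupil.shape[1]) / self.sample_rate


def _bump(t_rel: np.ndarray, duration: float) -> np.ndarray:
    """Gamma-like unit-peak bump: rises to 1 at duration/4, decays by ~duration."""
    a = duration / 4.0
    x = np.clip(t_rel / a, 0.0, None)
    return x * np.exp(1.0 - x)


def _add_transients(y: np.ndarray, times: Sequence[float], amp: float,
                    latency: float, duration: float, fs: float) -> None:
    n = y.size
    span = int(round(3.0 * duration * fs))
    rel = np.arange(span) / fs
    kern = amp * _bump(rel, duration)
    for t0 in times:
        i0 = int(round((t0 + latency) * fs))
        if i0 >= n:
            continue
        j0, j1 = max(i0, 0), min(i0 + span, n)
        y[j0:j1] += kern[j0 - i0:j1 - i0]


def _smooth_noise(rng: np.random.Generator, shape, sd: float,
                  smooth_s: float, fs: float) -> np.ndarray:
    """Gaussian-correlated noise with marginal SD ``sd`` (last axis = time).

    White noise convolved with a Gaussian kernel of std ``smooth_s`` and
    rescaled; with the default 100 ms scale the implied pupil rate of
    change stays well inside the physiological range, as in real traces.
    """
    if smooth_s <= 0:
        return sd * rng.standard_normal(shape)
    from scipy.signal import fftconvolve
    # synthesize on a coarse grid (the noise is band-limited anyway),
    # smooth there, then linearly upsample to the sample grid
    n = shape[-1]
    up = max(int(smooth_s * fs / 10.0), 1)
    n_c = n // up + 2
    s_c = smooth_s * fs / up
    raw = rng.standard_normal(shape[:-1] + (n_c,))
    half = int(4.0 * s_c)
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / s_c) ** 2)
    kern /= math.sqrt(np.sum(kern ** 2))          # unit output variance
    kern = kern.reshape((1,) * (raw.ndim - 1) + (-1,))
    filt = fftconvolve(raw, kern, mode="same", axes=-1)
    idx = np.arange(n)
    base, frac = idx // up, (idx % up) / up
    return sd * (filt[..., base] * (1.0 - frac) + filt[..., base + 1] * frac)


def _lowpass_step(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """First-order low-pass along the last axis, initialized at steady state."""
    if tau <= 0:
        return x
    from scipy.signal import lfilter
    alpha = 1.0 - math.exp(-1.0 / (tau * fs))
    zi = (1.0 - alpha) * np.asarray(x, dtype=float)[..., :1]
    y, _ = lfilter([alpha], [1.0, alpha - 1.0], x, axis=-1, zi=zi)
    return y


def _report_events(obs: ObserverModel, tl: StimulusTimeline,
                   rng: np.random.Generator) -> List[Tuple[float, str]]:
    """Keypress stream tracking the perceived foreground with lag and mixed episodes."""
    dir_black_cw = tl.black_direction == "left"   # front-left motion = clockwise

    def key_for(fg_sign: float) -> str:
        black_front = fg_sign > 0
        return "cw" if (black_front == dir_black_cw) else "ccw"

    flips = tl.flip_times
    n_states = flips.size + 1
    # deterministic per-switch mixed duration keeps the time fraction on target
    mixed_dur = obs.mixed_rate * tl.trial_duration / max(flips.size, 1)
    lat = obs.report_latency_mean + obs.report_latency_sd * rng.standard_normal(n_states)
    lat = np.maximum(lat, obs.report_latency_floor)
    events: List[Tuple[float, str]] = []
    # initial percept, reported shortly after trial start
    signs = tl.foreground_sign(np.concatenate(([0.0], flips + 1e-6)))
    events.append((float(lat[0]), key_for(signs[0])))
    for k, tf in enumerate(flips):
        t_sw = float(tf + lat[k + 1])
        if t_sw >= tl.trial_duration:
            continue
        s = signs[k + 1]
        if mixed_dur > 0:
            events.append((t_sw, "mixed"))
            t_key = t_sw + mixed_dur
            if t_key < tl.trial_duration:
                events.append((t_key, key_for(s)))
        else:
            events.append((t_sw, key_for(s)))
    events.sort(key=lambda e: e[0])
    return events


def simulate_participant(obs: ObserverModel, cfg: StimulusConfig,
                         timelines: Sequence[StimulusTimeline],
                         mode: str = "report", rng_seed=0,
                         participant: str = "P00") -> Recording:
    """Render raw pupil/gaze samples and report events for one observer.

    Pupil model per trial: baseline + linear drift + sustained component
    (foreground sign convolved with a first-order low-pass) + swap-locked
    constrictions + (report mode) keypress-locked dilations + white noise;
    blinks zero the pupil channel. Gaze is an OKN sawtooth whose slow-phase
    velocity is ``okn_gain`` times the foreground surface velocity.
    """
    obs.validate()
    cfg.validate()
    if mode not in ("report", "no-report"):
        raise ConfigError("mode must be 'report' or 'no-report'")
    rng = _as_rng(rng_seed)
    n_tr, n_s = len(timelines), cfg.samples_per_trial
    fs = cfg.sample_rate
    t = np.arange(n_s) / fs
    # sustained pupil drive: foreground sign delayed by the response latency
    s = np.stack([tl.foreground_sign(t - obs.sustained_latency)
                  for tl in timelines])
    pupil = obs.pupil_baseline + obs.drift * (t / cfg.trial_duration)
    pupil = np.broadcast_to(pupil, (n_tr, n_s)).copy()
    pupil += obs.sustained_amp * _lowpass_step(s, obs.sustained_tau, fs)

    reports: List[List[Tuple[float, str]]] = []
    for i, tl in enumerate(timelines):
        _add_transients(pupil[i], tl.flip_times, -obs.constrict_amp,
                        obs.constrict_latency, obs.constrict_duration, fs)
        ev = _report_events(obs, tl, rng) if mode == "report" else []
        if mode == "report" and obs.report_dilation_amp != 0.0:
            _add_transients(pupil[i], [e[0] for e in ev], obs.report_dilation_amp,
                            obs.report_dilation_latency, obs.report_dilation_duration, fs)
        reports.append(ev)
    if obs.noise_sd > 0:
        pupil += _smooth_noise(rng, (n_tr, n_s), obs.noise_sd,
                               obs.noise_smooth_s, fs)

    dir_black = np.array([1.0 if tl.black_direction == "right" else -1.0
                          for tl in timelines])
    fg = np.stack([tl.foreground_sign(t) for tl in timelines])
    v = obs.okn_gain * dir_black[:, None] * fg * mean_surface_speed(cfg)
    gaze_x = np.cumsum(v, axis=-1) / fs
    if obs.gaze_noise_sd > 0:
        from scipy.ndimage import uniform_filter1d
        w = 25  # 50 ms smoothing keeps positional noise differentiable
        raw = rng.standard_normal((n_tr, n_s))
        gaze_x = gaze_x + obs.gaze_noise_sd * math.sqrt(w) \
            * uniform_filter1d(raw, w, axis=-1, mode="nearest")
        gaze_y = obs.gaze_noise_sd * rng.standard_normal((n_tr, n_s))
    else:
        gaze_y = np.zeros((n_tr, n_s))
    amp = 1.5  # deg, OKN excursion before a fast reset
    gaze_x = np.mod(gaze_x + amp, 2.0 * amp) - amp

    if obs.blink_rate > 0:
        dur = int(round(obs.blink_duration * fs))
        for i in range(n_tr):
            n_blinks = rng.poisson(obs.blink_rate * cfg.trial_duration)
            for b in rng.uniform(0, cfg.trial_duration, size=n_blinks):
                j0 = int(b * fs)
                pupil[i, j0:j0 + dur] = 0.0
                gaze_x[i, j0:j0 + dur] = np.nan
                gaze_y[i, j0:j0 + dur] = np.nan

    return Recording(participant=participant, mode=mode, timelines=list(timelines),
                     pupil=pupil, gaze_x=gaze_x, gaze_y=gaze_y, reports=reports,
                     sample_rate=fs, aq=obs.aq, observer=obs)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    recordings: List[Recording]
    participants: "object" = None   # pandas.DataFrame: participant, aq, sustained_amp, okn_gain
    mode: str = "report"
    seed: int = 0


def draw_cohort_params(cohort: CohortConfig):
    """Per-participant generative parameters: AQ, sustained amplitude, OKN gain.

    AQ scores come from a truncated, rounded normal; sustained amplitudes
    combine the trait-linked term (``trait_correlation`` times the
    standardized continuous AQ draw) with calibrated independent noise, so
    corr(AQ, amplitude) equals ``trait_correlation`` in expectation.
    Returns (aq, amp, okn_gain, per-participant SeedSequences).
    """
    cohort.validate()
    ss = np.random.SeedSequence(cohort.seed)
    master = np.random.default_rng(ss)
    n = cohort.n_participants
    rho = cohort.trait_correlation
    z = master.standard_normal(n)
    eta = master.standard_normal(n)
    if cohort.amp_noise_sd is None:
        noise_term = cohort.amp_scale * math.sqrt(max(0.0, 1.0 - rho * rho)) * eta
    else:
        noise_term = cohort.amp_noise_sd * eta
    amp = cohort.amp_mean + cohort.amp_scale * rho * z + noise_term
    aq = np.clip(np.rint(cohort.aq_mean + cohort.aq_sd * z), 0, 50).astype(int)
    front = master.random(n) < cohort.okn_front_frac
    gain_mag = np.clip(np.abs(cohort.okn_gain_mean
                              + cohort.okn_gain_sd * master.standard_normal(n)), 0.1, 1.5)
    okn = np.where(front, gain_mag, -gain_mag)
    return aq, amp, okn, ss.spawn(n)


def iter_cohort(cohort: CohortConfig, cfg: StimulusConfig,
                participant_ids: Optional[Sequence[str]] = None):
    """Yield one :class:`Recording` at a time (memory-light cohort stream)."""
    cfg.validate()
    aq, amp, okn, seeds = draw_cohort_params(cohort)
    if participant_ids is None:
        participant_ids = [f"P{i:02d}" for i in range(cohort.n_participants)]
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        obs = replace(cohort.observer_template, aq=int(aq[i]),
                      sustained_amp=float(amp[i]), okn_gain=float(okn[i]))
        tls = make_timelines(cfg, rng)
        yield simulate_participant(obs, cfg, tls, mode=cohort.mode,
                                   rng_seed=rng, participant=participant_ids[i])


def simulate_cohort(cohort: CohortConfig, cfg: StimulusConfig,
                    participant_ids: Optional[Sequence[str]] = None) -> Cohort:
    """Generate a full cohort with the configured AQ-amplitude correlation.

    Fully reproducible: every participant and trial derives its RNG stream
    from the single cohort seed. For large cohorts prefer
    :func:`iter_cohort`, which does not hold all raw traces at once.
    """
    import pandas as pd

    aq, amp, okn, _ = draw_cohort_params(cohort)
    if participant_ids is None:
        participant_ids = [f"P{i:02d}" for i in range(cohort.n_participants)]
    recordings = list(iter_cohort(cohort, cfg, participant_ids))
    table = pd.DataFrame({
        "participant": list(participant_ids), "aq": aq,
        "sustained_amp": amp, "okn_gain": okn, "mode": cohort.mode,
    })
    return Cohort(recordings=recordings, participants=table,
                  mode=cohort.mode, seed=cohort.seed)
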