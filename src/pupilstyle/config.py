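"""Configuration objects for stimulus, observer, cohort, preprocessing and analysis.

Every numeric constant of the experimental design and of the preprocessing
recipe lives here, once, as a named default. ``RunConfig`` aggregates the
sections and serializes them as a flat ``section.key: value`` YAML document;
unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

SQRT3 = math.sqrt(3.0)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class StimulusConfig:
    """Geometry and timing of the rotating-cylinder stereo stimulus.

    The stimulus is a structure-from-motion cylinder: 150 white and black
    dots moving in opposite directions with a sinusoidal velocity profile,
    disambiguated by binocular disparity (one color in front, the other
    behind). Stereo-depths swap stochastically; each swap is a linear
    disparity ramp.
    """

    trial_duration: float = 60.0        # s
    trials_per_participant: int = 30
    swap_mean: float = 5.0              # s, mean of the flat inter-swap distribution
    swap_sd: float = 2.0                # s, SD of the flat inter-swap distribution
    swap_outlier_frac: float = 0.10     # fraction of intervals drawn uniform on the outlier range
    swap_outlier_lo: float = 0.5        # s
    swap_outlier_hi: float = 60.0       # s
    ramp_duration: float = 1.2          # s, linear disparity transition
    disparity_amp: float = 15.0         # arcmin
    peak_dot_speed: float = 3.9         # deg/s
    rotation_speed: float = 60.0        # deg/s (3D rotation; informational)
    n_dots: int = 150
    dot_diameter: float = 0.30          # deg
    sample_rate: float = 500.0          # Hz

    @property
    def swap_lo(self) -> float:
        """Lower bound of the flat inter-swap distribution, mean - SD*sqrt(3)."""
        return self.swap_mean - self.swap_sd * SQRT3

    @property
    def swap_hi(self) -> float:
        return self.swap_mean + self.swap_sd * SQRT3

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))

    def validate(self) -> None:
        for name in ("trial_duration", "swap_mean", "ramp_duration",
                     "disparity_amp", "peak_dot_speed", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0.0 <= self.swap_outlier_frac <= 1.0:
            raise ConfigError("swap_outlier_frac must lie in [0, 1]")
        if self.swap_sd < 0:
            raise ConfigError("swap_sd must be non-negative")
        if self.swap_lo < 0:
            raise ConfigError("flat inter-swap distribution has a negative lower bound")
        if self.swap_lo < self.ramp_duration:
            raise ConfigError(
                "flat inter-swap lower bound is shorter than the disparity ramp; "
                "ramps would overlap")
        if self.trial_duration <= self.ramp_duration:
            raise ConfigError("trial_duration must exceed ramp_duration")


@dataclass
class PreprocConfig:
    """Thresholds for pupil/gaze cleaning and the common 10 Hz grid."""

    pupil_median_band: float = 1.5   # mm, max deviation from the trial median
    pupil_floor: float = 0.2         # mm, anything smaller is signal loss
    pupil_max_speed: float = 2.5     # mm/s, physiological ceiling of pupil change
    purge_epoch_ms: float = 20.0     # ms removed around a speed violation
    boxcar_ms: float = 20.0          # ms, gaze smoothing window
    gaze_speed_cap: float = 3.9      # deg/s, peak stimulus speed
    out_rate: float = 10.0           # Hz
    bin_ms: float = 100.0            # ms, downsampling window

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"{f.name} must be strictly positive")
        if abs(self.bin_ms * self.out_rate - 1000.0) > 1e-9:
            raise ConfigError("bin_ms * out_rate must equal 1000 ms*Hz")


@dataclass
class ObserverModel:
    """Generative parameters of one simulated observer.

    The pupil trace is a sum of three components: a sustained, foreground-
    color-locked modulation (``sustained_amp``, positive = dilated when the
    black dots are in front), a transient constriction locked to each
    perceptual change, and (report mode only) a transient dilation locked to
    each keypress — plus baseline, slow drift, Gaussian noise and blinks.
    Gaze shows antagonistic optokinetic nystagmus: slow phases at
    ``okn_gain`` times the foreground surface velocity, with fast resets.
    """

    aq: int = 18                        # Autism-Spectrum Quotient total, 0-50
    sustained_amp: float = 0.03         # mm, signed color-locked offset
    sustained_tau: float = 0.8          # s, low-pass time constant of the sustained component
    sustained_latency: float = 0.6      # s, lag of the pupil drive behind the perceptual
                                        # flip (pupil responses trail their trigger by
                                        # ~0.5-1 s; 0.6 s puts the drive at the ramp end)
    constrict_amp: float = 0.03         # mm, swap-locked transient constriction
    constrict_latency: float = 0.5      # s after the perceptual flip
    constrict_duration: float = 1.0     # s, effective bump length
    report_dilation_amp: float = 0.03   # mm, keypress-locked transient dilation
    report_dilation_latency: float = 0.4  # s after the keypress
    report_dilation_duration: float = 1.0  # s
    pupil_baseline: float = 4.0         # mm
    noise_sd: float = 0.05              # mm, slow measurement/physiological noise
    noise_smooth_s: float = 0.1         # s, Gaussian correlation scale of that noise
                                        # (0 = white; real pupil traces are smooth at
                                        # the sample level, far below 2.5 mm/s)
    drift: float = 0.1                  # mm linear drift over one trial
    blink_rate: float = 0.1             # Hz
    blink_duration: float = 0.15        # s
    okn_gain: float = 0.8               # slow-phase gaze velocity / foreground velocity
    gaze_noise_sd: float = 0.03         # deg, smoothed positional noise
    report_latency_mean: float = 1.0    # s
    report_latency_sd: float = 0.3      # s
    report_latency_floor: float = 0.2   # s
    mixed_rate: float = 0.0286          # proportion of trial time reported as mixed

    def validate(self) -> None:
        if not 0 <= self.aq <= 50:
            raise ConfigError("aq must lie in [0, 50]")
        if self.blink_rate < 0:
            raise ConfigError("blink_rate must be non-negative")
        if not 0.0 <= self.mixed_rate <= 1.0:
            raise ConfigError("mixed_rate must lie in [0, 1]")
        if self.pupil_baseline <= 0.2:
            raise ConfigError("pupil_baseline must exceed 0.2 mm")


@dataclass
class CohortConfig:
    """Population-level generative settings linking AQ to pupil modulation.

    ``sustained_amp_i = amp_mean + amp_scale * (rho * z_i + sqrt(1-rho^2) * eta_i)``
    with ``z_i`` the observer's standardized AQ and ``eta_i`` standard normal,
    so that corr(AQ, sustained_amp) equals ``trait_correlation`` in
    expectation and SD(sustained_amp) = ``amp_scale``. Passing an explicit
    ``amp_noise_sd`` replaces the calibrated noise term.
    """

    n_participants: int = 53
    aq_mean: float = 18.0
    aq_sd: float = 7.0
    trait_correlation: float = 0.45
    amp_mean: float = 0.03              # mm, cohort-average sustained amplitude
    amp_scale: float = 0.04             # mm per AQ standard deviation (total amp SD)
    amp_noise_sd: Optional[float] = None  # mm; None = calibrated to hit trait_correlation
    okn_front_frac: float = 0.85        # fraction tracking the front surface (okn_gain > 0)
    okn_gain_mean: float = 0.8
    okn_gain_sd: float = 0.15
    seed: int = 0
    mode: str = "report"                # "report" | "no-report"
    observer_template: ObserverModel = field(default_factory=ObserverModel)

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ConfigError("n_participants must be at least 3")
        if abs(self.trait_correlation) > 1:
            raise ConfigError("|trait_correlation| must not exceed 1")
        if self.amp_noise_sd is not None and self.amp_noise_sd < 0:
            raise ConfigError("amp_noise_sd must be non-negative")
        if self.mode not in ("report", "no-report"):
            raise ConfigError("mode must be 'report' or 'no-report'")
        if not 0.0 <= self.okn_front_frac <= 1.0:
            raise ConfigError("okn_front_frac must lie in [0, 1]")
        self.observer_template.validate()


@dataclass
class AnalysisConfig:
    """Epoch windows, exclusion thresholds and index definitions."""

    epoch_halfwidth: float = 5.0        # s, epochs span [-5, +5) around the event
    missing_threshold: float = 0.30     # epochs with more missing pupil data are dropped
    baseline_window: float = 0.2        # s immediately preceding the event
    baseline_fallback: str = "nearest"  # "nearest" preceding valid bin | "exclude"
    swap_index_window: tuple = (0.0, 2.0)     # s relative to ramp end
    switch_index_window: tuple = (-1.0, 1.0)  # s relative to the keypress
    swap_mean_window: tuple = (1.0, 2.0)      # s, overall-response window (swap)
    switch_mean_window: tuple = (0.0, 1.0)    # s, overall-response window (switch)
    xcorr_max_lag: float = 5.0          # s, report-vs-stereo lag scan range

    def validate(self) -> None:
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ConfigError("missing_threshold must lie in [0, 1]")
        if self.baseline_fallback not in ("nearest", "exclude"):
            raise ConfigError("baseline_fallback must be 'nearest' or 'exclude'")
        if self.epoch_halfwidth <= 0 or self.xcorr_max_lag < 0:
            raise ConfigError("epoch_halfwidth must be positive, xcorr_max_lag non-negative")


_SECTIONS = {
    "stimulus": StimulusConfig,
    "preproc": PreprocConfig,
    "cohort": CohortConfig,
    "analysis": AnalysisConfig,
}


@dataclass
class RunConfig:
    """All settings of a full run, serializable to a flat YAML document."""

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        self.stimulus.validate()
        self.preproc.validate()
        self.cohort.validate()
        self.analysis.validate()

    def to_flat_dict(self) -> dict:
        flat = {}
        for section, cls in _SECTIONS.items():
            obj = getattr(self, section)
            for f in dataclasses.fields(cls):
                if f.name == "observer_template":
                    for g in dataclasses.fields(ObserverModel):
                        flat[f"cohort.observer.{g.name}"] = getattr(obj.observer_template, g.name)
                else:
                    v = getattr(obj, f.name)
                    flat[f"{section}.{f.name}"] = list(v) if isinstance(v, tuple) else v
        return flat

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise ConfigError("config document must be a flat key: value mapping")
        cfg = cls()
        known = set(cfg.to_flat_dict())
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in flat.items():
            parts = key.split(".")
            if parts[:2] == ["cohort", "observer"]:
                target, name = cfg.cohort.observer_template, parts[2]
            else:
                target, name = getattr(cfg, parts[0]), parts[1]
            if isinstance(getattr(target, name), tuple):
                value = tuple(value)
            setattr(target, name, value)
        cfg.validate()
        return cfg
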