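import numpy as np
import pytest

from pupilstyle import ObserverModel, StimulusConfig
from pupilstyle.synth import make_timelines, simulate_participant


@pytest.fixture(scope="session")
def stim() -> StimulusConfig:
    return StimulusConfig()


@pytest.fixture(scope="session")
def small_stim() -> StimulusConfig:
    """Short trials for fast unit tests (same rates and thresholds)."""
    return StimulusConfig(trial_duration=20.0, trials_per_participant=4)


def quiet_observer(**kw) -> ObserverModel:
    """Observer with every stochastic nuisance source switched off."""
    base = dict(noise_sd=0.0, gaze_noise_sd=0.0, blink_rate=0.0, drift=0.0,
                constrict_amp=0.0, report_dilation_amp=0.0, mixed_rate=0.0,
                report_latency_sd=0.0)
    base.update(kw)
    return ObserverModel(**base)


@pytest.fixture(scope="session")
def default_recording(stim):
    """One default-observer report-mode recording, shared across tests."""
    tls = make_timelines(stim, 11)
    return simulate_participant(ObserverModel(sustained_amp=0.1), stim, tls,
                                "report", 12)


@pytest.fixture(scope="session")
def step_recording(stim):
    """Noiseless step-model simulant: instantaneous sustained kernel."""
    tls = make_timelines(stim, 21)
    obs = quiet_observer(sustained_amp=0.1, sustained_tau=0.0)
    return simulate_participant(obs, stim, tls, "report", 22)
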