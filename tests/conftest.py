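import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from revlearn.schedule import generate_trial_schedule
from revlearn.simulate import SimulationConfig, simulate_trace

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_schedule():
    """The 5-acquisition / 2-reversal conditioning protocol (14 trials)."""
    return generate_trial_schedule(5, 2)


@pytest.fixture(scope="session")
def mock_schedule():
    return generate_trial_schedule(5, 2, mock=True)


@pytest.fixture()
def clean_config():
    """Noise-free, motion-free configuration with shared bleach."""
    return SimulationConfig(seed=0, noise_sd_G=0.0, noise_sd_T=0.0, motion_sd=0.0)


@pytest.fixture()
def clean_trace(clean_config, standard_schedule):
    return simulate_trace(clean_config, standard_schedule)
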