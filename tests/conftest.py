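import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoeeg import (
    CALIBRATED_GENERATOR,
    ProtocolConfig,
    make_temperature_profile,
    synthesize_eeg,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolConfig:
    """A compressed 5-min version of the ramp protocol (same 37-42 °C span)."""
    return ProtocolConfig(
        baseline_duration=60.0,
        ramp_rate=2.5,       # 37 -> 42 in 120 s
        hold_duration=60.0,
        cooldown_rate=5.0,   # back to 37 in 60 s
    )


@pytest.fixture(scope="session")
def short_session(short_protocol):
    """One synthetic session on the compressed protocol at 500 Hz."""
    gen = CALIBRATED_GENERATOR.replace(sampling_rate=500.0, seed=42)
    profile = make_temperature_profile(short_protocol)
    return synthesize_eeg(profile, gen, session_id="short_42")


@pytest.fixture(scope="session")
def default_session():
    """One full-length session with the shipped calibrated generator."""
    profile = make_temperature_profile()
    return synthesize_eeg(profile, CALIBRATED_GENERATOR.replace(seed=7),
                          session_id="default_7")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
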