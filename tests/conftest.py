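import numpy as np
import pytest

from skimu import (
    LocationProfile,
    SimulationConfig,
    load_fixture,
    pelvis_only_config,
    simulate_session,
)


@pytest.fixture(scope="session")
def ref_turns():
    return load_fixture("reference_turns")


@pytest.fixture(scope="session")
def ref_attempts():
    return load_fixture("reference_attempts")


@pytest.fixture(scope="session")
def noiseless_config():
    """Three-location noiseless session config (gain > 0 everywhere)."""
    profiles = {
        loc: LocationProfile(loc, gain=g, artifact_noise_sd=0.0)
        for loc, g in [("pelvis", 1.0), ("head", 0.3), ("hand_l", 0.05)]
    }
    return SimulationConfig(noise_sd=0.0, seed=3, location_profiles=profiles)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_config):
    return simulate_session(noiseless_config)


@pytest.fixture(scope="session")
def default_session():
    """Full 16-location session with one excluded attempt, default conditions."""
    return simulate_session(SimulationConfig(seed=42), missing_attempts=[2])


@pytest.fixture(scope="session")
def fast_config():
    return pelvis_only_config(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
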