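import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dualadapt as da

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_noise():
    return da.NoiseParams(aim_sd_deg=0.0, seed=1)


@pytest.fixture(scope="session")
def default_learner():
    return da.calibrate_defaults()


@pytest.fixture(scope="session")
def single_reach_noiseless(default_learner, noiseless_noise):
    """Full noiseless SINGLE_REACH session (schedule seed 0)."""
    design = da.build_session("SINGLE_REACH", 0)
    return design, da.simulate_session(design, default_learner, noiseless_noise)


@pytest.fixture(scope="session")
def single_track_noiseless(default_learner, noiseless_noise):
    design = da.build_session("SINGLE_TRACK", 0)
    return design, da.simulate_session(design, default_learner, noiseless_noise)


@pytest.fixture(scope="session")
def dual_noiseless(default_learner, noiseless_noise):
    design = da.build_session("DUAL", 0)
    return design, da.simulate_session(design, default_learner, noiseless_noise)


@pytest.fixture(scope="session")
def mini_designs():
    """Miniature 5-trial-phase sessions for fast structural tests."""
    return da.make_fixtures(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
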