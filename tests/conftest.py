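import numpy as np
import pytest

from bsfdeb import DebParams, Scenario, simulate_deb


@pytest.fixture(scope="session")
def chicken_params():
    """Default parameter set calibrated to larvae reared on chicken feed."""
    return DebParams()


@pytest.fixture(scope="session")
def default_scenario():
    return Scenario()


@pytest.fixture(scope="session")
def chicken_traj(chicken_params, default_scenario):
    return simulate_deb(chicken_params, default_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
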