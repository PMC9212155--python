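import numpy as np
import pytest

from phagehost import SimulationParams, normalize


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def default_nparams(default_params):
    return normalize(default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
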