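import numpy as np
import pytest

import ctlsim.geometry as geo
from ctlsim import SimulationConfig, TissueWorld


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast tissue for unit tests."""
    return SimulationConfig(n_rows=16, n_cols=16)


@pytest.fixture
def small_world(small_config):
    return TissueWorld.from_config(small_config)


@pytest.fixture
def nonsus_world():
    """16x16 tissue of non-susceptible cells (surveillance setting)."""
    return TissueWorld.uniform(16, 16, state=geo.NON_SUSCEPTIBLE)
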