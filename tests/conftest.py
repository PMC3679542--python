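import numpy as np
import pytest

from iftmotion.config import SimConfig, TrapSimConfig


@pytest.fixture
def quiet_sim_config():
    """Low-traffic, pause-free simulation used by geometry/extraction tests."""
    return SimConfig(duration=60, injection_rate_antero=0.3,
                     injection_rate_retro=0.3, pause_rate_max=0.0,
                     pause_rate_residual=0.0, seed=2)


@pytest.fixture
def trap_config():
    return TrapSimConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
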