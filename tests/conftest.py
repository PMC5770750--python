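import numpy as np
import pytest
from hypothesis import settings

from reachopt import ArmParams, CostConfig, EstimatorConfig, build_layout

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ArmParams()


@pytest.fixture(scope="session")
def cost_cfg():
    return CostConfig()


@pytest.fixture(scope="session")
def est_cfg():
    return EstimatorConfig()


@pytest.fixture(scope="session")
def layout_w40(params):
    return build_layout(params.arm_length, 0.04, params=params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
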