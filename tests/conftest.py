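import logging

import numpy as np
import pytest

from mcrelease import MCSModel, SimulationConfig

# the Weibull fitter warns whenever it drops the t=0 point; keep test output clean
logging.getLogger("mcrelease.fitting").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_diffusion_config():
    return SimulationConfig(n0=200, R0=10, H=20, seed=42)


@pytest.fixture
def small_erosion_config():
    return SimulationConfig(
        n0=200, R0=10, H=20, mcs=MCSModel(mode="erosion", lambda_=0.1), seed=42
    )


@pytest.fixture
def small_walk_config():
    return SimulationConfig(n0=40, R0=6, H=12, kernel="walk", max_steps=20000, seed=42)
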