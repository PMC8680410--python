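import numpy as np
import pytest
from hypothesis import settings

from oxyvasc import ModelParameters, ScenarioConfig, default_parameters

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture
def small_cfg() -> ScenarioConfig:
    """A 21x21 scenario cheap enough for per-test simulation."""
    return ScenarioConfig(grid_nx=21, grid_ny=21, t_end=1.0, dt=1e-3,
                          output_interval=0.25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
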