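import numpy as np
import pytest
from hypothesis import settings

from setpointnet import LearningParams, PhysiologyParams, SimulationConfig

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


@pytest.fixture
def phys():
    return PhysiologyParams()


@pytest.fixture
def learn():
    return LearningParams()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def tiny_config():
    """Small, fast closed-loop configuration for plumbing tests."""
    return SimulationConfig(n_tissues=5, iterations=50, seed=7)
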