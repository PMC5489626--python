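import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pigletgfr import DEFAULT_AGE_GROUPS, KineticsSpec, SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def kinetics():
    return KineticsSpec()


@pytest.fixture
def mono_kinetics():
    """alpha == beta limit: single-exponential disposition."""
    return KineticsSpec(alpha_per_min=0.004, beta_per_min=0.004, fast_fraction=0.4)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def groups():
    return DEFAULT_AGE_GROUPS
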