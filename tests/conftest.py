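import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psygrs import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
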