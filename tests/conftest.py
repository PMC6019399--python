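import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_spec():
    """The reference juvenile population: Normal(30, 5), one million fish."""
    from scsim import PopulationSpec

    return PopulationSpec(mean=30.0, sd=5.0, size=1_000_000)


@pytest.fixture(scope="session")
def big_normal_draw():
    """10**7 standard-normal draws shared by the Monte-Carlo moment oracles."""
    rng = np.random.default_rng(20_240_101)
    return rng.standard_normal(10_000_000)
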