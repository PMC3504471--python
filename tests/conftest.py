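import pytest
from hypothesis import HealthCheck, settings

from cortexclock import SpeciesFAParams, default_registry

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def rat(registry) -> SpeciesFAParams:
    return registry["rat"].require_fa()


@pytest.fixture(scope="session")
def ferret(registry) -> SpeciesFAParams:
    return registry["ferret"].require_fa()


@pytest.fixture(scope="session")
def human(registry) -> SpeciesFAParams:
    return registry["human"].require_fa()
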