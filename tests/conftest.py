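import pytest
from hypothesis import HealthCheck, settings

from basilar.pipeline import Pipeline

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pipeline():
    """Default-configuration pipeline shared across tests (read-only use)."""
    return Pipeline()


@pytest.fixture(scope="session")
def bank(pipeline):
    return pipeline.bank
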