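import pytest
from hypothesis import HealthCheck, settings

from fatds.experiments import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """Reference 20-cell wild-type configuration."""
    return SimulationConfig.default()
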