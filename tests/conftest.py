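import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


from backsplice.simulate import SimConfig, simulate_gene  # noqa: E402


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def gene(default_config):
    return simulate_gene(default_config)
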