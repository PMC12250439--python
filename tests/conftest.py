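import pytest
from hypothesis import HealthCheck, settings

from waitcea.fixtures import FixtureSpec, generate_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def egypt_run():
    """The five-surgery illustrative model run."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def randomized_run():
    return generate_fixture(FixtureSpec(seed=7, n_cohorts=3, profile="randomized"))
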