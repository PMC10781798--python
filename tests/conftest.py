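import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from blistercalc import CohortConfig, generate_cohort, worked_example_fixture


@pytest.fixture(scope="session")
def default_cohort():
    """The 45-product synthetic cohort under study conditions, seed 7."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """n = 1000 cohort used for parameter-recovery checks, seed 11."""
    return generate_cohort(CohortConfig.with_size(1000, seed=11))


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()
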