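import pytest
from hypothesis import HealthCheck, settings

from brcarisk import (
    TrainConfig,
    build_catalogue,
    build_rulebase,
    generate_cohort,
    train,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalogue():
    return build_catalogue()


@pytest.fixture(scope="session")
def cohort(catalogue):
    """Default synthetic study cohort (268 patients, fixed seed)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def rulebase(cohort, catalogue):
    return build_rulebase(cohort, catalogue)


@pytest.fixture(scope="session")
def trained(cohort, catalogue):
    """One trained network + report shared by the slower tests."""
    return train(cohort, catalogue, TrainConfig(seed=1))
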