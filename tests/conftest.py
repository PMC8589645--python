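import pytest
from hypothesis import settings, HealthCheck

from cnvburden.simulate import fixture_genes, fixture_regions, scenario, \
    simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def regions():
    return fixture_regions()


@pytest.fixture(scope="session")
def genes():
    return fixture_genes()


@pytest.fixture(scope="session")
def null_bundle():
    """Small synthetic cohort with CNV call data under the null scenario."""
    return simulate_cohort(scenario("null", 1500), seed=11)
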