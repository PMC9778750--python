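import pytest

from ricerisk import (
    AgeGroupExposure,
    ExposureTable,
    FittedDistribution,
    RiskConstants,
    generate_exposure_table,
)


@pytest.fixture(scope="session")
def constants():
    return RiskConstants()


@pytest.fixture(scope="session")
def default_table():
    """The 27-bin synthetic exposure table under default study conditions."""
    return generate_exposure_table()


@pytest.fixture
def single_group():
    """A single lifetime-spanning bin with the adult survey factors."""
    return AgeGroupExposure(
        label="lifetime",
        age_start=0.0,
        age_end=70.0,
        exposure_duration=70.0,
        ingestion_rate=167.0,
        body_weight=60.0,
        exposure_frequency=312.85,
    )


@pytest.fixture
def single_group_table(single_group):
    return ExposureTable([single_group])


@pytest.fixture
def white_dist():
    """White-rice concentration model: zero-truncated Normal(100.17, 44.62) ng/g."""
    return FittedDistribution("normal", {"mean": 100.17, "sd": 44.62})


@pytest.fixture
def brown_dist():
    """Brown-rice concentration model: Lognormal(mu=4.1, sigma=0.9) on the log scale."""
    return FittedDistribution("lognormal", {"mu": 4.1, "sigma": 0.9})
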