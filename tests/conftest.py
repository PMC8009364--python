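import pytest

from chronocollide.classify import annotate_records
from chronocollide.config import StudyConfig
from chronocollide.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def synthetic_records(config):
    """Default 5-year synthetic record set (the shared workhorse fixture)."""
    return generate(SyntheticConfig(seed=42), config)


@pytest.fixture(scope="session")
def annotated(synthetic_records, config):
    return annotate_records(synthetic_records, config)


@pytest.fixture(scope="session")
def small_records(config):
    """Two-year, low-rate record set for fast pipeline-level tests."""
    sconfig = SyntheticConfig(years=(2002, 2003), base_daily_rate=4.0, seed=7)
    return generate(sconfig, config.replace(study_years=(2002, 2003)))
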