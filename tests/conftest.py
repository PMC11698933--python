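import pytest
from hypothesis import HealthCheck, settings

from fluorisk import (
    DEFAULT_COHORTS,
    SiteRecord,
    SiteSummary,
    default_site_specs,
    exposure_table,
)

settings.register_profile(
    "fluorisk",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fluorisk")


@pytest.fixture(scope="session")
def site_specs():
    """The packaged 17-site district configuration."""
    return default_site_specs()


@pytest.fixture(scope="session")
def district_sites(site_specs):
    """Summary-mode site records for the 17-site district."""
    return [
        SiteRecord.from_summary(
            s.site_id, s.location_name, SiteSummary(s.min, s.max, s.mean, s.std)
        )
        for s in site_specs
    ]


@pytest.fixture(scope="session")
def cohorts():
    return DEFAULT_COHORTS


@pytest.fixture(scope="session")
def district_results(district_sites, cohorts):
    return exposure_table(district_sites, cohorts)
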