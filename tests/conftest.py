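import pytest

from nephrotrack.config import default_config
from nephrotrack.simulate import observe, simulate_cohort


@pytest.fixture(scope="session")
def cfg_long():
    return default_config("partial_iri_long", seed=7)


@pytest.fixture(scope="session")
def cfg_short():
    return default_config("partial_iri_short", seed=7)


@pytest.fixture(scope="session")
def cfg_laser():
    return default_config("laser", seed=7)


@pytest.fixture(scope="session")
def cohort_long(cfg_long):
    return simulate_cohort(cfg_long)


@pytest.fixture(scope="session")
def obs_long(cohort_long):
    return observe(cohort_long)


@pytest.fixture(scope="session")
def cohort_short(cfg_short):
    return simulate_cohort(cfg_short)


@pytest.fixture(scope="session")
def obs_short(cohort_short):
    return observe(cohort_short)


@pytest.fixture(scope="session")
def cohort_laser(cfg_laser):
    return simulate_cohort(cfg_laser)


@pytest.fixture(scope="session")
def obs_laser(cohort_laser):
    return observe(cohort_laser)


@pytest.fixture
def mini_config():
    """One mouse, a handful of nephrons: fast unit-test cohort."""
    return default_config("partial_iri_long", seed=3).replace(
        cohort={"n_mice": 1, "nephrons_per_region": {"IR": 4, "Mid": 3, "Not-IR": 2}}
    )
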