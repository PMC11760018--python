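import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icuews import CohortConfig, GapSpec, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with gaps and an ineligible record."""
    config = CohortConfig(
        n_cohort1=6,
        n_cohort2=20,
        duration_log_median_s=np.log(3 * 3600.0),
        duration_log_sd=0.3,
        include_ineligible=1,
    )
    records, store = generate_cohort(config, seed=11)
    return config, records, store


@pytest.fixture(scope="session")
def stationary_cohort():
    """Control-only cohort (constant decay rate, no ramp)."""
    config = CohortConfig(
        n_cohort1=0,
        n_cohort2=30,
        duration_log_median_s=np.log(2.5 * 3600.0),
        duration_log_sd=0.2,
        gap_spec=GapSpec.none(),
    )
    records, store = generate_cohort(config, seed=5)
    return config, records, store
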