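import datetime as dt

import pytest

from statindisparity import CohortConfig, generate_analysis_frame, generate_cohort

WINDOW = (dt.date(2000, 1, 1), dt.date(2011, 12, 31))


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_patients=4000, seed=424242)


@pytest.fixture(scope="session")
def small_frame(small_config):
    return generate_analysis_frame(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def big_frame():
    """A 50,000-patient cohort at the default calibration, shared by the
    marginal-calibration and coefficient-recovery tests."""
    return generate_analysis_frame(CohortConfig(n_patients=50_000, seed=777))
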