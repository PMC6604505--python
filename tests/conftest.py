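import numpy as np
import pytest

from stepgoals import ScheduleParams, SimParams, StudyDesign, simulate_cohort


@pytest.fixture(scope="session")
def design():
    return StudyDesign.default()


@pytest.fixture(scope="session")
def default_schedule():
    return ScheduleParams()


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated 29x40 cohort at default generative settings."""
    records, outcomes = simulate_cohort(SimParams(seed=11))
    return records, outcomes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
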