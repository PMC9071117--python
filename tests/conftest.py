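import datetime as dt

import pytest

from d2care import CohortConfig, StudyWindow, simulate_cohort


@pytest.fixture(scope="session")
def window() -> StudyWindow:
    """Canonical cycle: in-care 2017, OOC Jan-Jun 2018, data request Aug 1."""
    return StudyWindow.from_start(dt.date(2017, 1, 1))


@pytest.fixture(scope="session")
def small_cohort(window):
    """A 400-patient cohort at the default (study) margins."""
    return simulate_cohort(CohortConfig(n_patients=400, seed=11, window=window))
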