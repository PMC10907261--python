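import numpy as np
import pytest

import empathlearn as el
from empathlearn.io import cohort_trials_frame


@pytest.fixture(scope="session")
def default_schedule():
    return el.generate_schedule(el.TrialScheduleSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Six high + six low participants at recovery-regime noise (cached)."""
    return el.simulate_cohort(6, seed=42)


@pytest.fixture(scope="session")
def small_cohort_trials(small_cohort):
    return cohort_trials_frame(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
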