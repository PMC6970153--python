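import numpy as np
import pytest

from matchingpennies import (
    CohortSpec,
    DEFAULT_PAYOFF,
    ScheduleSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def payoff():
    return DEFAULT_PAYOFF


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated participants on the full schedule, fixed seed."""
    spec = CohortSpec(n_participants=5, master_seed=11)
    return simulate_cohort(spec, ScheduleSpec(), DEFAULT_PAYOFF)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
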