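import numpy as np
import pytest

from misripe import (CohortTruth, default_instrument, frequency_grid,
                     generate_cohort)


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    """The default 9-point 100 kHz – 3 MHz logarithmic sweep."""
    return frequency_grid()


@pytest.fixture(scope="session")
def clean_instrument(grid):
    """Instrument with gain/phase/background errors but no noise or drift."""
    return default_instrument(grid, snr_db=None, drift_rate=0.0)


@pytest.fixture(scope="session")
def default_cohort() -> CohortTruth:
    """The study-sized cohort: 60 fruit, 8 A / 4 B / 48 C, 22 days."""
    return generate_cohort(60, {"A": 8, "B": 4, "C": 48}, rng_seed=1)


@pytest.fixture(scope="session")
def empty_truth() -> CohortTruth:
    return CohortTruth(trajectories=(), proportions={}, seed=0)
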