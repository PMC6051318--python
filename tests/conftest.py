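import numpy as np
import pytest

from aphasiamap import generate_cohort

SMALL_GRID = (20, 24, 20)


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients on a desk-scale grid; shared by read-only tests."""
    return generate_cohort(n=40, grid_shape=SMALL_GRID, rng_seed=7)


@pytest.fixture(scope="session")
def medium_cohort():
    """70 patients on the desk-scale grid (study-sized)."""
    return generate_cohort(n=70, grid_shape=SMALL_GRID, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
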