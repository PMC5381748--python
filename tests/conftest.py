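import numpy as np
import pytest

from insulafc.atlas import build_atlas, default_roi_table
from insulafc.cohort import CohortConfig, generate_cohort
from insulafc.grid import GridSpec


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()


@pytest.fixture(scope="session")
def short_grid():
    """Default spatial grid with a short (80-volume) time axis for fast tests."""
    return GridSpec(n_volumes=80)


@pytest.fixture(scope="session")
def atlas(default_grid):
    return build_atlas(default_roi_table(), default_grid)


@pytest.fixture(scope="session")
def small_cohort(short_grid):
    """3+3 subjects, 80 volumes: enough to exercise every downstream stage."""
    config = CohortConfig(n_expert=3, n_amateur=3, grid=short_grid, seed=11)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
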