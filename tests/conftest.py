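import numpy as np
import pytest

from dentaleis import (
    DM_PARAMS,
    ND_PARAMS,
    generate_labeled_dataset,
    simulate_spectrum,
    standard_grid,
)


@pytest.fixture(scope="session")
def grid():
    return standard_grid()


@pytest.fixture(scope="session")
def nd_spectrum(grid):
    return simulate_spectrum(ND_PARAMS, grid, label="ND")


@pytest.fixture(scope="session")
def dm_spectrum(grid):
    return simulate_spectrum(DM_PARAMS, grid, label="DM")


@pytest.fixture(scope="session")
def default_dataset():
    """Balanced 24-tooth dataset under the default population/noise model."""
    return generate_labeled_dataset(n_per_class=12)
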