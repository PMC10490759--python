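import numpy as np
import pytest

from ramandense.io import AxisGrid
from ramandense.synth import (
    NoiseModel,
    PostureModel,
    generate_dataset,
    make_class_signatures,
)

#: Small grid used throughout the unit tests: same spectral range as the
#: native axis, coarser sampling, so renders and training stay fast.
SMALL_GRID = AxisGrid(170.0, 3200.0, 259)


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_GRID


@pytest.fixture(scope="session")
def signatures():
    return make_class_signatures(4, rng_seed=7, grid=SMALL_GRID)


@pytest.fixture(scope="session")
def small_dataset():
    """8 classes x 12 spectra on the small grid, default conditions."""
    return generate_dataset(
        n_classes=8, spectra_per_class=12, rng_seed=3, grid=SMALL_GRID
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
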