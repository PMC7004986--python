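import numpy as np
import pytest

from romtflow.grid import ImageGrid, ScalarField, VectorField


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid6():
    return ImageGrid((6, 6, 6))


@pytest.fixture
def grid16():
    return ImageGrid((16, 16, 16))


@pytest.fixture
def line3():
    """3-cell 1D line grid used by the hand-computed stencil checks."""
    return ImageGrid((3, 1, 1))


def random_density(grid: ImageGrid, rng, low=0.0, high=1.0) -> ScalarField:
    return ScalarField(grid, rng.uniform(low, high, grid.dims))


def random_velocity(grid: ImageGrid, rng, vmax=1.0) -> VectorField:
    return VectorField(grid, rng.uniform(-vmax, vmax, (3, *grid.dims)))
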