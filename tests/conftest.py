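import numpy as np
import pytest

from mmtrack.grid import Grid2D, ScalarField, VectorField
from mmtrack.phantom import PhantomParams, generate_sequence


def sine_product(n: int) -> tuple[Grid2D, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-square eigenfunction sampled on an n x n grid (grid units h=1)."""
    grid = Grid2D(n, n)
    x = np.linspace(0.0, 1.0, n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    return grid, X, Y, np.sin(np.pi * X) * np.sin(np.pi * Y)


@pytest.fixture(scope="session")
def small_phantom_params() -> PhantomParams:
    """Scaled-down study for fast unit tests (not the acceptance conditions)."""
    return PhantomParams(
        image_size=(64, 64),
        spacing_mm=(2.0, 2.0),
        n_pretreatment=5,
        n_treatment=4,
        si_amplitude_mm=6.0,
        ap_amplitude_mm=2.0,
        tumor_center_mm=(70.0, 80.0),
        tumor_semiaxes_mm=(7.0, 5.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_params):
    return generate_sequence(small_phantom_params)


@pytest.fixture(scope="session")
def default_phantom():
    """The full protocol-scale study; shared across acceptance tests."""
    return generate_sequence(PhantomParams(seed=11))


def random_scalar(grid: Grid2D, rng: np.random.Generator) -> ScalarField:
    return ScalarField(grid, rng.standard_normal(grid.shape))


def random_vector(grid: Grid2D, rng: np.random.Generator) -> VectorField:
    return VectorField(grid, rng.standard_normal(grid.shape), rng.standard_normal(grid.shape))
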