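"""Regular-grid containers and discrete differential operators.

Everything downstream (the div-curl solver, the deformation ODE, the
image-matching loop) is built on the small set of primitives defined
here: scalar and vector fields on a regular 2D grid, centered-difference
derivatives, and bilinear interpolation.

Conventions
-----------
* Arrays are indexed ``(row, col)``, 0-based.
* Continuous coordinates are measured in grid units with node ``i`` at
  coordinate ``i``; the grid spacing is normalized to ``h = 1``.
  Physical pixel spacing in mm enters only in :mod:`mmtrack.metrics`.
* By default the row axis maps to the patient superior-inferior (S-I)
  direction and the column axis to anterior-posterior (A-P); the
  mapping is configurable where it matters (metrics reporting).
* Derivatives use centered differences in the interior and first-order
  one-sided differences on the edges (the behaviour of
  :func:`numpy.gradient`).
* Interpolation is bilinear; queries outside the domain are clamped to
  the boundary (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Grid2D:
    """A regular 2D grid of nodes.

    Parameters
    ----------
    n_rows, n_cols : int
        Number of nodes along each axis; at least 3 so that interior
        centered differences exist.
    spacing_row_mm, spacing_col_mm : float
        Physical distance between adjacent nodes along each axis, in mm.
        Carried as metadata; all on-grid computations use ``h = 1``.
    """

    n_rows: int
    n_cols: int
    spacing_row_mm: float = 1.0
    spacing_col_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValidationError(
                f"grid must be at least 3x3, got {self.n_rows}x{self.n_cols}"
            )
        if not (self.spacing_row_mm > 0 and self.spacing_col_mm > 0):
            raise ValidationError("grid spacings must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return (self.spacing_row_mm, self.spacing_col_mm)

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of node coordinates, shape ``(n_rows, n_cols)`` each."""
        return np.meshgrid(
            np.arange(self.n_rows, dtype=float),
            np.arange(self.n_cols, dtype=float),
            indexing="ij",
        )


def _check_values(grid: Grid2D, values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValidationError(
            f"{name} shape {arr.shape} does not match grid shape {grid.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ScalarField:
    """A real value per grid node (monitor function, curl field, ...)."""

    grid: Grid2D
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.grid, self.values, "values"))


@dataclass(frozen=True)
class VectorField:
    """A two-component field per grid node, stored as (row, col) components."""

    grid: Grid2D
    row_component: np.ndarray
    col_component: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "row_component", _check_values(self.grid, self.row_component, "row_component")
        )
        object.__setattr__(
            self, "col_component", _check_values(self.grid, self.col_component, "col_component")
        )

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.row_component, self.col_component)


def divergence(field: VectorField) -> ScalarField:
    """Discrete divergence  d(row_comp)/d(row) + d(col_comp)/d(col).

    Centered differences in the interior, first-order one-sided at the
    edges, grid spacing ``h = 1``.
    """
    d = np.gradient(field.row_component, axis=0) + np.gradient(field.col_component, axis=1)
    return ScalarField(field.grid, d)


def curl2d(field: VectorField) -> ScalarField:
    """Scalar curl  d(col_comp)/d(row) - d(row_comp)/d(col).

    This is the out-of-plane component of the 3D curl under the
    (row, col) axis convention; for a rotation field
    ``(row_comp, col_comp) = (-c, r)`` it equals 2.
    """
    c = np.gradient(field.col_component, axis=0) - np.gradient(field.row_component, axis=1)
    return ScalarField(field.grid, c)


def gradient(field: ScalarField) -> VectorField:
    """Gradient of a scalar field, components along (row, col)."""
    gr = np.gradient(field.values, axis=0)
    gc = np.gradient(field.values, axis=1)
    return VectorField(field.grid, gr, gc)


def perpendicular_gradient(field: ScalarField) -> VectorField:
    """Rotated gradient  (-dB/dcol, dB/drow): divergence-free, curl = Laplacian(B)."""
    gr = np.gradient(field.values, axis=0)
    gc = np.gradient(field.values, axis=1)
    return VectorField(field.grid, -gc, gr)


def interpolate_values(values: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2D array at continuous (row, col) positions.

    ``positions`` has shape ``(2, n)`` (row coordinates first).  Queries
    outside the domain are clamped to the nearest boundary value.  At
    integer node coordinates the node value is reproduced exactly.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(positions)):
        raise ValidationError("interpolation positions must be finite")
    return map_coordinates(np.asarray(values, dtype=float), positions, order=1, mode="nearest")


def interpolate(field: ScalarField | VectorField, positions: np.ndarray):
    """Interpolate a scalar or vector field at continuous (row, col) positions.

    Returns an array of shape ``(n,)`` for a scalar field and ``(2, n)``
    for a vector field.  An empty position list yields an empty result.
    """
    positions = np.asarray(positions, dtype=float)
    if isinstance(field, ScalarField):
        return interpolate_values(field.values, positions)
    if positions.size == 0:
        return np.empty((2, 0))
    return np.stack(
        [
            interpolate_values(field.row_component, positions),
            interpolate_values(field.col_component, positions),
        ]
    )


def bilinear_sample_many(arrays: tuple[np.ndarray, ...], positions: np.ndarray) -> list[np.ndarray]:
    """Bilinear sampling of several same-shaped arrays at shared positions.

    Computes the corner indices and weights once and gathers each array,
    which is substantially cheaper than repeated ``map_coordinates``
    calls when the same trajectory points sample multiple fields (the
    inner loop of the velocity ODE).  Positions outside the domain are
    clamped, matching :func:`interpolate_values`.
    """
    n, m = arrays[0].shape
    r = np.clip(positions[0], 0.0, n - 1.0)
    c = np.clip(positions[1], 0.0, m - 1.0)
    r0 = np.minimum(r.astype(np.intp), n - 2)
    c0 = np.minimum(c.astype(np.intp), m - 2)
    fr = r - r0
    fc = c - c0
    w00 = (1.0 - fr) * (1.0 - fc)
    w01 = (1.0 - fr) * fc
    w10 = fr * (1.0 - fc)
    w11 = fr * fc
    base = r0 * m + c0
    out = []
    for a in arrays:
        flat = a.ravel()
        out.append(
            w00 * flat[base]
            + w01 * flat[base + 1]
            + w10 * flat[base + m]
            + w11 * flat[base + m + 1]
        )
    return out


def clamp_positions(positions: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Clamp continuous (row, col) positions, shape (2, n), into the grid domain."""
    out = np.empty_like(positions)
    np.clip(positions[0], 0.0, grid.n_rows - 1.0, out=out[0])
    np.clip(positions[1], 0.0, grid.n_cols - 1.0, out=out[1])
    return out
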