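"""Diffeomorphic deformation with a prescribed Jacobian (moving-mesh method).

A positive, mean-one monitor function ``mu`` prescribes the local area
change of the sought transformation ``phi``: the goal is

    det(Jacobian(phi))(xi) = mu(xi).

The construction follows the moving-mesh deformation method: solve the
div-curl system

    div rho = mu - 1,   curl rho = gamma,   rho = 0 on the boundary,

then integrate every grid node through the time-dependent velocity

    v_t(p) = rho(p) / (t + (1 - t) * mu(p)),   t in [0, 1],

from t = 0 to t = 1 and set phi(xi) = psi(xi, 1).  The scalar field
``gamma`` prescribes the rotational part of ``rho`` and makes the
construction unique; it does not affect the Jacobian target.

Integration uses the classical fixed-step 4th-order Runge-Kutta scheme
(deterministic; 10 steps by default), with ``rho`` and ``mu`` evaluated
bilinearly along trajectories and positions clamped to the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divcurl import DivCurlSolution, solve_divcurl
from .grid import (
    Grid2D,
    ScalarField,
    ValidationError,
    VectorField,
    bilinear_sample_many,
    clamp_positions,
    interpolate_values,
)

DEFAULT_MU_BOUNDS = (0.2, 5.0)
"""Default clipping bounds for the monitor function.

The lower bound keeps the velocity denominator ``t + (1 - t) mu``
strictly positive; together they bound local compression/expansion to
[0.2, 5] per registration step, which in practice keeps the Jacobian
positive everywhere.
"""


@dataclass(frozen=True)
class MonitorField:
    """A validated monitor function: positive, bounded, discrete mean one."""

    field: ScalarField
    mu_min: float = DEFAULT_MU_BOUNDS[0]
    mu_max: float = DEFAULT_MU_BOUNDS[1]

    def __post_init__(self) -> None:
        v = self.field.values
        if not (0 < self.mu_min <= 1 <= self.mu_max):
            raise ValidationError("monitor bounds must satisfy 0 < mu_min <= 1 <= mu_max")
        tol = 1e-9
        if v.min() < self.mu_min - tol or v.max() > self.mu_max + tol:
            raise ValidationError("monitor values outside declared bounds")
        if abs(v.mean() - 1.0) > 1e-12:
            raise ValidationError("monitor mean must equal 1 within 1e-12")

    @property
    def values(self) -> np.ndarray:
        return self.field.values

    @property
    def grid(self) -> Grid2D:
        return self.field.grid


def normalize_monitor(
    raw: ScalarField,
    mu_min: float = DEFAULT_MU_BOUNDS[0],
    mu_max: float = DEFAULT_MU_BOUNDS[1],
    max_rounds: int = 50,
) -> MonitorField:
    """Clip a raw field into [mu_min, mu_max] and rescale to discrete mean one.

    Clipping and rescaling are iterated to a joint fixed point (at most
    ``max_rounds`` rounds; convergence is typically immediate because
    admissible monitors stay close to 1).  Degenerate input — a field
    whose clipped mean is zero or non-finite — is rejected.
    """
    v = np.asarray(raw.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("monitor input contains non-finite values")
    if np.all(v == 0):
        raise ValidationError("degenerate monitor input (all values zero)")
    for _ in range(max_rounds):
        v = np.clip(v, mu_min, mu_max)
        mean = v.mean()
        if not np.isfinite(mean) or mean <= 0:
            raise ValidationError("degenerate monitor input (non-positive mean)")
        v = v / mean
        if v.min() >= mu_min and v.max() <= mu_max and abs(v.mean() - 1.0) <= 1e-12:
            break
    # final exact rescale so the mean-one invariant holds bit-tight
    v = v / v.mean()
    v = np.clip(v, mu_min, mu_max)
    v = v / v.mean()
    return MonitorField(ScalarField(raw.grid, v), mu_min, mu_max)


def velocity(
    rho: VectorField,
    mu: MonitorField | ScalarField,
    t: float,
    positions: np.ndarray,
) -> np.ndarray:
    """Moving-mesh velocity  v_t(p) = rho(p) / (t + (1 - t) mu(p)).

    ``positions`` has shape (2, n); the result matches.  ``rho`` and
    ``mu`` are evaluated bilinearly at the query points.  At t = 1 the
    denominator is identically 1 and the velocity equals ``rho``.
    """
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"algorithmic time t must lie in [0, 1], got {t}")
    positions = np.asarray(positions, dtype=float)
    mu_values = mu.values if isinstance(mu, MonitorField) else mu.values
    denom = t + (1.0 - t) * interpolate_values(mu_values, positions)
    vr = interpolate_values(rho.row_component, positions) / denom
    vc = interpolate_values(rho.col_component, positions) / denom
    return np.stack([vr, vc])


@dataclass(frozen=True)
class Transformation:
    """A dense map from grid nodes to continuous (row, col) coordinates."""

    grid: Grid2D
    map_row: np.ndarray
    map_col: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, arr in (("map_row", self.map_row), ("map_col", self.map_col)):
            a = np.asarray(arr, dtype=float)
            if a.shape != self.grid.shape:
                raise ValidationError(f"{name} shape does not match grid")
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name} contains non-finite values")
            object.__setattr__(self, name, a)

    @classmethod
    def identity(cls, grid: Grid2D) -> "Transformation":
        rr, cc = grid.node_coordinates()
        return cls(grid, rr, cc)

    def as_positions(self) -> np.ndarray:
        """Flattened (2, n_nodes) position array, row coordinates first."""
        return np.stack([self.map_row.ravel(), self.map_col.ravel()])

    def max_boundary_displacement(self) -> float:
        """Largest displacement of any boundary node, in grid units."""
        rr, cc = self.grid.node_coordinates()
        dr = self.map_row - rr
        dc = self.map_col - cc
        edge = np.zeros(self.grid.shape, dtype=bool)
        edge[0, :] = edge[-1, :] = True
        edge[:, 0] = edge[:, -1] = True
        return float(np.hypot(dr[edge], dc[edge]).max())


def build_transformation(
    mu: MonitorField,
    gamma: ScalarField,
    n_steps: int = 10,
    method: str = "fft",
    rho: VectorField | None = None,
) -> Transformation:
    """Build phi from (mu, gamma) by RK4 integration of the velocity ODE.

    The intermediate field ``rho`` is obtained from the div-curl solve of
    (mu - 1, gamma) unless supplied (callers that already solved the
    system can pass it to avoid recomputation).  Every grid node is
    integrated from t = 0 to t = 1 in ``n_steps`` fixed RK4 steps;
    positions are clamped to the domain after each stage.

    A non-positive Jacobian determinant at any interior node is recorded
    in ``diagnostics`` (key ``"jacobian_warning"``) rather than raised:
    it signals monitor bounds too loose for the grid, not a programming
    error.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    grid = mu.grid
    if gamma.grid.shape != grid.shape:
        raise ValidationError("mu and gamma must share a grid")

    solution: DivCurlSolution | None = None
    if rho is None:
        f = ScalarField(grid, mu.values - 1.0)
        solution = solve_divcurl(f, gamma, method=method)
        rho = solution.rho

    rr, cc = grid.node_coordinates()
    pos = np.stack([rr.ravel(), cc.ravel()])

    if float(rho.magnitude().max()) == 0.0:
        phi = Transformation(grid, rr, cc, diagnostics={"identity": True})
        return phi

    fields = (rho.row_component, rho.col_component, mu.values)

    def vel(t: float, p: np.ndarray) -> np.ndarray:
        vr, vc, mu_p = bilinear_sample_many(fields, p)
        denom = t + (1.0 - t) * mu_p
        return np.stack([vr / denom, vc / denom])

    h = 1.0 / n_steps
    for k in range(n_steps):
        t = k * h
        k1 = vel(t, pos)
        k2 = vel(t + 0.5 * h, clamp_positions(pos + 0.5 * h * k1, grid))
        k3 = vel(t + 0.5 * h, clamp_positions(pos + 0.5 * h * k2, grid))
        k4 = vel(t + h, clamp_positions(pos + h * k3, grid))
        pos = clamp_positions(pos + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), grid)

    map_row = pos[0].reshape(grid.shape)
    map_col = pos[1].reshape(grid.shape)

    diagnostics: dict = {}
    if solution is not None:
        diagnostics["div_residual_max"] = solution.div_residual_max
        diagnostics["curl_residual_max"] = solution.curl_residual_max

    phi = Transformation(grid, map_row, map_col, diagnostics=diagnostics)
    jac = jacobian_determinant(phi).values
    min_jac = float(jac[1:-1, 1:-1].min())
    diagnostics["min_jacobian"] = min_jac
    if min_jac <= 0:
        diagnostics["jacobian_warning"] = (
            f"non-positive Jacobian determinant (min {min_jac:.4g}); "
            "monitor bounds may be too loose for this grid"
        )
    return phi


def jacobian_determinant(phi: Transformation) -> ScalarField:
    """Determinant of the centered-difference Jacobian of the map.

    Computed at interior nodes; the boundary ring is copied from the
    nearest interior node (edge replication), so downstream statistics
    over the full grid are well defined.
    """
    drr = np.gradient(phi.map_row, axis=0)
    drc = np.gradient(phi.map_row, axis=1)
    dcr = np.gradient(phi.map_col, axis=0)
    dcc = np.gradient(phi.map_col, axis=1)
    det = drr * dcc - drc * dcr
    # one-sided edge derivatives are only first order; replicate interior
    det[0, :] = det[1, :]
    det[-1, :] = det[-2, :]
    det[:, 0] = det[:, 1]
    det[:, -1] = det[:, -2]
    return ScalarField(phi.grid, det)
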