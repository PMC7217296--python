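"""Intensity-based registration in the moving-mesh parameterization.

The correspondence between a fixed frame ``F`` and a moving frame ``M``
is the transformation ``phi`` minimizing the L2 dissimilarity

    E(F, M, phi) = mean_xi ( F(xi) - M(phi(xi)) )^2

over the moving-mesh family: ``phi`` is always rebuilt from a monitor
function ``mu`` (prescribed Jacobian, positive, mean one) and a curl
field ``gamma``, never updated free-form, so every iterate inherits the
boundary-preservation and positive-Jacobian guarantees of the
deformation module.

The optimizer is a demons-style projected descent with a backtracking
line search: the residual-times-gradient force field is smoothed,
turned into a displacement-space step ``u = -alpha * force``, and
projected into the parameterization by taking its divergence and curl
(the exact inverse direction of the div-curl solve that realizes
``rho`` from ``(mu - 1, gamma)``).  A candidate ``(mu', gamma')`` is
accepted only if the cost decreases, so the accepted cost trace is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .deformation import (
    DEFAULT_MU_BOUNDS,
    MonitorField,
    Transformation,
    build_transformation,
    normalize_monitor,
)
from .grid import (
    Grid2D,
    ScalarField,
    ValidationError,
    VectorField,
    curl2d,
    divergence,
    interpolate_values,
)
from .image import ImageFrame


@dataclass(frozen=True)
class RegistrationConfig:
    """Tunable parameters of the registration loop.

    grid_size
        Registration grid nodes per side; frames are resampled to this
        resolution before matching.
    max_iterations
        Cap on descent iterations.
    step_size_init
        Initial displacement-space step length alpha (grid units per
        unit force); adapted by the backtracking line search.
    force_smoothing_sigma
        Gaussian smoothing of the force field, in grid units.
    mu_bounds
        Clipping bounds for the monitor function.
    n_steps
        RK4 steps for each transformation build.
    rel_tol
        Convergence threshold on the relative cost decrease, sustained
        over 5 consecutive accepted iterations.
    seed
        Recorded for provenance; the descent itself is deterministic.
    """

    grid_size: int = 101
    max_iterations: int = 100
    step_size_init: float = 2.0
    force_smoothing_sigma: float = 2.0
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS
    n_steps: int = 10
    rel_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 17:
            raise ValidationError("grid_size must be >= 17")
        if self.max_iterations < 1 or self.n_steps < 1:
            raise ValidationError("iteration counts must be positive")
        if not (self.step_size_init > 0 and self.force_smoothing_sigma > 0 and self.rel_tol > 0):
            raise ValidationError("step size, smoothing sigma and rel_tol must be positive")


@dataclass
class RegistrationResult:
    """Outcome of a registration run."""

    phi: Transformation
    mu: MonitorField
    gamma: ScalarField
    cost_trace: list[float]
    converged: bool
    iterations: int
    notes: list[str] = field(default_factory=list)


def resample_to_grid(frame: ImageFrame, grid_size: int) -> np.ndarray:
    """Bilinearly resample a frame onto a grid_size x grid_size node grid.

    Node (i, j) of the registration grid maps to pixel position
    (i*(R-1)/(G-1), j*(C-1)/(G-1)) of the source frame, so the image
    corners coincide with the grid corners.
    """
    r, c = frame.shape
    ii = np.linspace(0.0, r - 1.0, grid_size)
    jj = np.linspace(0.0, c - 1.0, grid_size)
    rr, cc = np.meshgrid(ii, jj, indexing="ij")
    out = map_coordinates(frame.values, np.stack([rr.ravel(), cc.ravel()]), order=1, mode="nearest")
    return out.reshape(grid_size, grid_size)


def _as_array(image) -> np.ndarray:
    return np.asarray(image.values if isinstance(image, ImageFrame) else image, dtype=float)


def l2_dissimilarity(fixed, moving, phi: Transformation) -> float:
    """Mean squared intensity difference  mean(( fixed - moving(phi) )^2)."""
    fixed = _as_array(fixed)
    moving = _as_array(moving)
    if fixed.shape != phi.grid.shape or moving.shape != phi.grid.shape:
        raise ValidationError("image shapes must match the transformation grid")
    warped = interpolate_values(moving, phi.as_positions()).reshape(phi.grid.shape)
    return float(np.mean((fixed - warped) ** 2))


def warp_image(image, phi: Transformation) -> np.ndarray:
    """Sample  image(phi(xi))  bilinearly with boundary clamping."""
    image = _as_array(image)
    if image.shape != phi.grid.shape:
        raise ValidationError("image shape must match the transformation grid")
    return interpolate_values(image, phi.as_positions()).reshape(phi.grid.shape)


def force_field(fixed, warped, sigma: float, grid: Grid2D) -> VectorField:
    """Smoothed image force  (warped - fixed) * grad(warped).

    Each component is convolved with a normalized Gaussian of standard
    deviation ``sigma`` grid units (truncated at 4 sigma) and the
    boundary ring is zeroed so the force never pushes boundary nodes.
    """
    fixed = _as_array(fixed)
    warped = _as_array(warped)
    if fixed.shape != warped.shape:
        raise ValidationError("fixed and warped shapes must match")
    residual = warped - fixed
    gr = np.gradient(warped, axis=0)
    gc = np.gradient(warped, axis=1)
    fr = gaussian_filter(residual * gr, sigma, truncate=4.0, mode="nearest")
    fc = gaussian_filter(residual * gc, sigma, truncate=4.0, mode="nearest")
    for comp in (fr, fc):
        comp[0, :] = comp[-1, :] = 0.0
        comp[:, 0] = comp[:, -1] = 0.0
    return VectorField(grid, fr, fc)


def project_update(force: VectorField, alpha: float) -> tuple[ScalarField, ScalarField]:
    """Project a displacement step  u = -alpha * force  into (mu, gamma) space.

    Returns ``(delta_mu, delta_gamma) = (div u, curl u)`` — the same pair
    from which the div-curl solve would reconstruct ``u`` (up to its
    harmonic part), so descent steps stay inside the moving-mesh family.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    u = VectorField(force.grid, -alpha * force.row_component, -alpha * force.col_component)
    return divergence(u), curl2d(u)


def register(fixed: ImageFrame, moving: ImageFrame, config: RegistrationConfig) -> RegistrationResult:
    """Minimize the L2 dissimilarity over (mu, gamma); see module docstring.

    Frames are resampled to ``config.grid_size`` and min-max normalized
    per frame.  The returned ``phi`` maps fixed-frame grid coordinates
    onto the moving frame, so a contour drawn on the fixed frame is
    propagated forward as ``phi(vertex)``.
    """
    g = config.grid_size
    grid = Grid2D(g, g, fixed.spacing_mm[0], fixed.spacing_mm[1])

    fx = ImageFrame(resample_to_grid(fixed, g), fixed.spacing_mm).normalized()
    mv = ImageFrame(resample_to_grid(moving, g), moving.spacing_mm).normalized()

    mu = normalize_monitor(ScalarField(grid, np.ones(grid.shape)), *config.mu_bounds)
    gamma = ScalarField(grid, np.zeros(grid.shape))
    phi = Transformation.identity(grid)
    cost = l2_dissimilarity(fx, mv, phi)
    trace = [cost]
    notes: list[str] = []

    if np.ptp(fixed.values) == 0 or np.ptp(moving.values) == 0:
        notes.append("constant image: zero gradient everywhere, returning identity")
        return RegistrationResult(phi, mu, gamma, trace, True, 0, notes)

    alpha = config.step_size_init
    flat_streak = 0
    converged = False
    iterations = 0
    warped = warp_image(mv, phi)

    for iterations in range(1, config.max_iterations + 1):
        force = force_field(fx, warped, config.force_smoothing_sigma, grid)

        accepted = False
        for attempt in range(6):  # initial try + up to 5 halvings
            d_mu, d_gamma = project_update(force, alpha)
            cand_mu = normalize_monitor(
                ScalarField(grid, mu.values + d_mu.values), *config.mu_bounds
            )
            cand_gamma = ScalarField(grid, gamma.values + d_gamma.values)
            cand_phi = build_transformation(cand_mu, cand_gamma, n_steps=config.n_steps)
            cand_warped = warp_image(mv, cand_phi)
            cand_cost = float(np.mean((fx - cand_warped) ** 2))
            if cand_cost < cost:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            notes.append(f"line search stalled after iteration {iterations - 1}")
            converged = True
            break

        rel_drop = (cost - cand_cost) / max(cost, 1e-30)
        mu, gamma, phi, cost, warped = cand_mu, cand_gamma, cand_phi, cand_cost, cand_warped
        trace.append(cost)
        if attempt == 0:
            alpha *= 2.0  # first-try acceptance: the trust step can afford to grow

        flat_streak = flat_streak + 1 if rel_drop < config.rel_tol else 0
        if flat_streak >= 5:
            converged = True
            break

    if "jacobian_warning" in phi.diagnostics:
        notes.append(phi.diagnostics["jacobian_warning"])

    return RegistrationResult(phi, mu, gamma, trace, converged, iterations, notes)
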