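"""Dissimilarity, image force, projected update, and the registration loop."""

import numpy as np
import pytest

from mmtrack.deformation import Transformation, build_transformation, normalize_monitor
from mmtrack.grid import Grid2D, ScalarField, ValidationError, VectorField
from mmtrack.image import ImageFrame
from mmtrack.phantom import PhantomParams, render_frame
from mmtrack.registration import (
    RegistrationConfig,
    force_field,
    l2_dissimilarity,
    project_update,
    register,
    resample_to_grid,
    warp_image,
)


class TestL2Dissimilarity:
    def test_identical_images_identity_map(self):
        grid = Grid2D(9, 9)
        img = np.random.default_rng(0).random((9, 9))
        assert l2_dissimilarity(img, img, Transformation.identity(grid)) == 0.0

    def test_constant_offset(self):
        grid = Grid2D(9, 9)
        phi = Transformation.identity(grid)
        assert l2_dissimilarity(np.zeros((9, 9)), np.ones((9, 9)), phi) == 1.0

    def test_hand_computed_three_by_three(self):
        grid = Grid2D(3, 3)
        fixed = np.array([[0.0, 0, 0], [0, 1, 0], [0, 0, 0]])
        assert l2_dissimilarity(fixed, np.zeros((3, 3)), Transformation.identity(grid)) == pytest.approx(
            1.0 / 9.0
        )

    def test_shape_mismatch_rejected(self):
        grid = Grid2D(4, 4)
        with pytest.raises(ValidationError):
            l2_dissimilarity(np.zeros((5, 5)), np.zeros((4, 4)), Transformation.identity(grid))


class TestWarpImage:
    def test_identity_returns_input(self):
        grid = Grid2D(8, 8)
        img = np.random.default_rng(1).random((8, 8))
        assert np.array_equal(warp_image(img, Transformation.identity(grid)), img)

    def test_unit_column_shift(self):
        grid = Grid2D(6, 6)
        rr, cc = grid.node_coordinates()
        phi = Transformation(grid, rr, np.clip(cc + 1.0, 0, 5))
        img = np.random.default_rng(2).random((6, 6))
        out = warp_image(img, phi)
        assert np.array_equal(out[:, :-1], img[:, 1:])
        assert np.array_equal(out[:, -1], img[:, -1])  # clamped

    def test_exact_on_bilinear_ramp(self):
        # bilinear sampling is exact for images linear in coordinates
        grid = Grid2D(16, 16)
        rr, cc = grid.node_coordinates()
        img = 0.3 * rr + 0.1 * cc + 2.0
        phi = Transformation(grid, np.clip(rr + 0.37, 0, 15), np.clip(cc + 0.61, 0, 15))
        out = warp_image(img, phi)
        expected = 0.3 * phi.map_row + 0.1 * phi.map_col + 2.0
        assert np.allclose(out, expected, atol=1e-12)


def _direct_gaussian_smooth(field: np.ndarray, sigma: float) -> np.ndarray:
    """Independent dense convolution with the sampled, truncated, normalized kernel."""
    radius = int(4.0 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k = k / k.sum()
    padded = np.pad(field, radius, mode="edge")
    out = np.zeros_like(field)
    n, m = field.shape
    for i, wi in enumerate(k):
        for j, wj in enumerate(k):
            out += wi * wj * padded[i : i + n, j : j + m]
    return out


class TestForceField:
    def test_zero_residual_gives_zero_force(self):
        grid = Grid2D(16, 16)
        img = np.random.default_rng(3).random((16, 16))
        f = force_field(img, img, 2.0, grid)
        assert np.all(f.row_component == 0.0) and np.all(f.col_component == 0.0)

    def test_constant_residual_proportional_to_gradient(self):
        grid = Grid2D(24, 24)
        rng = np.random.default_rng(4)
        fixed = rng.random((24, 24))
        f1 = force_field(fixed, fixed + 1.0, 1.5, grid)
        f2 = force_field(fixed, fixed + 2.0, 1.5, grid)
        # residual factors out of the force product before smoothing... up to the
        # gradient of the warped image itself, identical here; ratio must be 2
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(f2.row_component[inner], 2.0 * f1.row_component[inner], atol=1e-12)

    def test_hot_pixel_matches_direct_convolution(self):
        grid = Grid2D(33, 33)
        rr, cc = grid.node_coordinates()
        fixed = 0.1 * rr  # smooth ramp: constant gradient
        warped = fixed.copy()
        warped[16, 16] += 0.05  # single interior hot residual
        sigma = 2.0
        f = force_field(fixed, warped, sigma, grid)
        residual = warped - fixed
        expected_r = _direct_gaussian_smooth(residual * np.gradient(warped, axis=0), sigma)
        expected_c = _direct_gaussian_smooth(residual * np.gradient(warped, axis=1), sigma)
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(f.row_component[inner], expected_r[inner], atol=1e-12)
        assert np.allclose(f.col_component[inner], expected_c[inner], atol=1e-12)

    def test_boundary_ring_zeroed(self):
        grid = Grid2D(16, 16)
        rng = np.random.default_rng(5)
        f = force_field(rng.random((16, 16)), rng.random((16, 16)), 2.0, grid)
        for comp in (f.row_component, f.col_component):
            assert np.all(comp[0] == 0) and np.all(comp[-1] == 0)
            assert np.all(comp[:, 0] == 0) and np.all(comp[:, -1] == 0)


class TestProjectUpdate:
    def test_zero_force(self):
        grid = Grid2D(9, 9)
        zero = VectorField(grid, np.zeros((9, 9)), np.zeros((9, 9)))
        d_mu, d_gamma = project_update(zero, 1.0)
        assert np.all(d_mu.values == 0.0) and np.all(d_gamma.values == 0.0)

    def test_linear_in_alpha(self):
        grid = Grid2D(9, 9)
        rng = np.random.default_rng(6)
        f = VectorField(grid, rng.standard_normal((9, 9)), rng.standard_normal((9, 9)))
        d1_mu, d1_g = project_update(f, 1.0)
        d2_mu, d2_g = project_update(f, 2.0)
        assert np.allclose(d2_mu.values, 2.0 * d1_mu.values, atol=1e-14)
        assert np.allclose(d2_g.values, 2.0 * d1_g.values, atol=1e-14)

    def test_rotational_force_is_pure_curl(self):
        grid = Grid2D(33, 33)
        rr, cc = grid.node_coordinates()
        f = VectorField(grid, -(cc - 16.0), rr - 16.0)
        d_mu, d_gamma = project_update(f, 1.0)
        assert np.abs(d_mu.values[1:-1, 1:-1]).max() <= 1e-10
        assert np.abs(d_gamma.values[1:-1, 1:-1]).max() > 0.1


@pytest.fixture(scope="module")
def clean_frame():
    params = PhantomParams()
    return ImageFrame(render_frame(params, 3.0, 1.0), params.spacing_mm)


class TestRegister:
    def test_self_registration_is_identity(self, clean_frame):
        cfg = RegistrationConfig(grid_size=33, max_iterations=20)
        res = register(clean_frame, clean_frame, cfg)
        rr, cc = res.phi.grid.node_coordinates()
        assert res.cost_trace[-1] <= 1e-6
        assert np.abs(res.phi.map_row - rr).max() <= 1e-6
        assert np.abs(res.phi.map_col - cc).max() <= 1e-6
        assert res.converged

    def test_constant_image_returns_identity_with_note(self):
        cfg = RegistrationConfig(grid_size=17, max_iterations=5)
        flat = ImageFrame(np.full((32, 32), 0.7))
        res = register(flat, flat, cfg)
        assert res.converged and res.iterations == 0
        assert any("constant image" in n for n in res.notes)

    def test_recovers_known_ground_truth_warp(self, clean_frame):
        g = 65
        grid = Grid2D(g, g)
        rr, cc = grid.node_coordinates()
        # bump centered on the tumor, in registration-grid coordinates
        tr = 100.0 / 2.0 / 127.0 * (g - 1)
        tc = 120.0 / 2.0 / 127.0 * (g - 1)
        bump = np.exp(-0.5 * ((rr - tr) ** 2 + (cc - tc) ** 2) / 8.0**2)
        mu_star = normalize_monitor(ScalarField(grid, 1.0 + 0.2 * bump))
        phi_star = build_transformation(mu_star, ScalarField(grid, np.zeros((g, g))))

        base = resample_to_grid(clean_frame, g)
        fixed = ImageFrame(warp_image(base, phi_star), clean_frame.spacing_mm)
        moving = ImageFrame(base, clean_frame.spacing_mm)
        res = register(fixed, moving, RegistrationConfig(grid_size=g, max_iterations=100))

        tumor = bump > 0.3
        epe = np.hypot(res.phi.map_row - phi_star.map_row, res.phi.map_col - phi_star.map_col)
        assert epe[tumor].mean() <= 1.0
        assert res.cost_trace[-1] <= 0.1 * res.cost_trace[0]
        assert all(b < a for a, b in zip(res.cost_trace, res.cost_trace[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_accepted_cost_trace_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        fixed = ImageFrame(gaussian_filter(rng.random((33, 33)), 2.0))
        moving = ImageFrame(gaussian_filter(rng.random((33, 33)), 2.0))
        res = register(fixed, moving, RegistrationConfig(grid_size=33, max_iterations=15))
        assert all(b <= a for a, b in zip(res.cost_trace, res.cost_trace[1:]))

    def test_monitor_invariants_hold_at_result(self, clean_frame):
        shifted = ImageFrame(np.roll(clean_frame.values, 2, axis=0), clean_frame.spacing_mm)
        cfg = RegistrationConfig(grid_size=33, max_iterations=10, mu_bounds=(0.2, 5.0))
        res = register(clean_frame, shifted, cfg)
        assert abs(res.mu.values.mean() - 1.0) <= 1e-12
        assert res.mu.values.min() >= 0.2 and res.mu.values.max() <= 5.0
        assert res.phi.max_boundary_displacement() <= 1e-6
        from mmtrack.deformation import jacobian_determinant

        assert jacobian_determinant(res.phi).values[1:-1, 1:-1].min() > 0.0
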