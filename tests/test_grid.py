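"""Differential operators and interpolation on the registration grid."""

import numpy as np
import pytest

from mmtrack.grid import (
    Grid2D,
    ScalarField,
    ValidationError,
    VectorField,
    bilinear_sample_many,
    curl2d,
    divergence,
    gradient,
    interpolate,
    interpolate_values,
)

from conftest import random_scalar, random_vector, sine_product


@pytest.fixture
def grid9() -> Grid2D:
    return Grid2D(9, 9)


class TestValidation:
    def test_rejects_tiny_grids_and_bad_spacing(self):
        with pytest.raises(ValidationError):
            Grid2D(2, 5)
        with pytest.raises(ValidationError):
            Grid2D(5, 5, spacing_row_mm=0.0)

    def test_rejects_non_finite_fields(self, grid9):
        values = np.zeros((9, 9))
        values[3, 3] = np.nan
        with pytest.raises(ValidationError):
            ScalarField(grid9, values)
        with pytest.raises(ValidationError):
            VectorField(grid9, values, np.zeros((9, 9)))

    def test_rejects_shape_mismatch(self, grid9):
        with pytest.raises(ValidationError):
            ScalarField(grid9, np.zeros((8, 9)))


class TestDivergence:
    def test_zero_field(self, grid9):
        f = VectorField(grid9, np.zeros((9, 9)), np.zeros((9, 9)))
        assert np.all(divergence(f).values == 0.0)

    def test_linear_field_has_unit_divergence(self, grid9):
        rr, _ = grid9.node_coordinates()
        f = VectorField(grid9, rr, np.zeros((9, 9)))
        assert np.allclose(divergence(f).values, 1.0)

    @pytest.mark.parametrize("n", [33, 65])
    def test_gradient_field_divergence_matches_laplacian(self, n):
        # rho = grad(sin(pi x) sin(pi y)) => div rho = -2 pi^2 sin sin, O(h^2)
        grid, X, Y, s = sine_product(n)
        h = 1.0 / (n - 1)
        rho = VectorField(
            grid,
            np.pi * np.cos(np.pi * X) * np.sin(np.pi * Y) * h,
            np.pi * np.sin(np.pi * X) * np.cos(np.pi * Y) * h,
        )
        target = -2.0 * np.pi**2 * s * h * h
        err = np.abs(divergence(rho).values - target)[1:-1, 1:-1].max()
        # second-order: constant C measured by a separate convergence check below
        assert err <= 10.0 * h**2 * h**2 * np.pi**4

    def test_second_order_convergence(self):
        errs = {}
        for n in (33, 65):
            grid, X, Y, s = sine_product(n)
            h = 1.0 / (n - 1)
            rho = VectorField(
                grid,
                np.pi * np.cos(np.pi * X) * np.sin(np.pi * Y) * h,
                np.pi * np.sin(np.pi * X) * np.cos(np.pi * Y) * h,
            )
            target = -2.0 * np.pi**2 * s * h * h
            # compare on the physical scale so the ratio isolates the stencil error
            errs[n] = np.abs(divergence(rho).values - target)[1:-1, 1:-1].max() / (h * h)
        ratio = errs[33] / errs[65]
        assert 3.0 <= ratio <= 5.0


class TestCurl:
    def test_zero_field(self, grid9):
        f = VectorField(grid9, np.zeros((9, 9)), np.zeros((9, 9)))
        assert np.all(curl2d(f).values == 0.0)

    def test_curl_of_gradient_vanishes(self):
        n = 33
        grid, X, Y, s = sine_product(n)
        h = 1.0 / (n - 1)
        g = gradient(ScalarField(grid, s))
        c = curl2d(g).values[1:-1, 1:-1]
        assert np.abs(c).max() <= 1e-10  # exact for commuting centered stencils

    def test_rotation_field_has_curl_two(self, grid9):
        rr, cc = grid9.node_coordinates()
        f = VectorField(grid9, -(cc - 4.0), rr - 4.0)
        assert np.allclose(curl2d(f).values, 2.0)


class TestGradient:
    def test_constant_field(self, grid9):
        g = gradient(ScalarField(grid9, np.full((9, 9), 3.5)))
        assert np.all(g.row_component == 0.0) and np.all(g.col_component == 0.0)

    def test_row_ramp(self, grid9):
        rr, _ = grid9.node_coordinates()
        g = gradient(ScalarField(grid9, rr))
        assert np.allclose(g.row_component, 1.0)
        assert np.all(g.col_component == 0.0)

    def test_analytic_gradient_second_order(self):
        n = 33
        grid, X, Y, s = sine_product(n)
        h = 1.0 / (n - 1)
        g = gradient(ScalarField(grid, s))
        exact_r = np.pi * np.cos(np.pi * X) * np.sin(np.pi * Y) * h
        exact_c = np.pi * np.sin(np.pi * X) * np.cos(np.pi * Y) * h
        err = max(
            np.abs(g.row_component - exact_r)[1:-1, 1:-1].max(),
            np.abs(g.col_component - exact_c)[1:-1, 1:-1].max(),
        )
        assert err / h <= np.pi**3 * h**2  # |f'''|/6 * h^2 bound with slack


def test_operators_are_linear():
    rng = np.random.default_rng(7)
    grid = Grid2D(17, 13)
    a, b = 2.3, -0.7
    f, g = random_vector(grid, rng), random_vector(grid, rng)
    s, t = random_scalar(grid, rng), random_scalar(grid, rng)
    comb_v = VectorField(
        grid,
        a * f.row_component + b * g.row_component,
        a * f.col_component + b * g.col_component,
    )
    comb_s = ScalarField(grid, a * s.values + b * t.values)
    assert np.allclose(
        divergence(comb_v).values, a * divergence(f).values + b * divergence(g).values, atol=1e-12
    )
    assert np.allclose(
        curl2d(comb_v).values, a * curl2d(f).values + b * curl2d(g).values, atol=1e-12
    )
    assert np.allclose(
        gradient(comb_s).row_component,
        a * gradient(s).row_component + b * gradient(t).row_component,
        atol=1e-12,
    )


class TestInterpolation:
    def test_exact_at_nodes(self):
        rng = np.random.default_rng(1)
        grid = Grid2D(7, 11)
        f = random_scalar(grid, rng)
        assert interpolate(f, np.array([[3.0], [5.0]]))[0] == f.values[3, 5]

    def test_midpoint_of_four_nodes(self):
        grid = Grid2D(3, 3)
        values = np.array([[0.0, 0.0, 9.0], [1.0, 1.0, 9.0], [9.0, 9.0, 9.0]])
        v = interpolate(ScalarField(grid, values), np.array([[0.5], [0.5]]))
        assert v[0] == pytest.approx(0.5)

    def test_exact_for_bilinear_functions(self):
        # bilinear interpolation reproduces a*r + b*c + d exactly
        rng = np.random.default_rng(42)
        grid = Grid2D(12, 15)
        a, b, d = 1.7, -2.2, 0.31
        rr, cc = grid.node_coordinates()
        f = ScalarField(grid, a * rr + b * cc + d)
        pos = np.stack([rng.uniform(0, 11, 100), rng.uniform(0, 14, 100)])
        expected = a * pos[0] + b * pos[1] + d
        assert np.allclose(interpolate(f, pos), expected, atol=1e-12)

    def test_bounded_by_surrounding_nodes(self):
        rng = np.random.default_rng(5)
        grid = Grid2D(9, 9)
        f = random_scalar(grid, rng)
        pos = np.stack([rng.uniform(0, 8, 200), rng.uniform(0, 8, 200)])
        vals = interpolate(f, pos)
        r0 = np.minimum(pos[0].astype(int), 7)
        c0 = np.minimum(pos[1].astype(int), 7)
        corners = np.stack(
            [f.values[r0, c0], f.values[r0 + 1, c0], f.values[r0, c0 + 1], f.values[r0 + 1, c0 + 1]]
        )
        assert np.all(vals >= corners.min(axis=0) - 1e-12)
        assert np.all(vals <= corners.max(axis=0) + 1e-12)

    def test_out_of_domain_clamped(self):
        grid = Grid2D(5, 5)
        rr, _ = grid.node_coordinates()
        f = ScalarField(grid, rr)
        v = interpolate(f, np.array([[-3.0, 10.0], [2.0, 2.0]]))
        assert v[0] == 0.0 and v[1] == 4.0

    def test_empty_positions(self):
        grid = Grid2D(5, 5)
        f = ScalarField(grid, np.zeros((5, 5)))
        assert interpolate(f, np.empty((2, 0))).size == 0

    def test_vector_field_interpolation(self):
        grid = Grid2D(5, 5)
        rr, cc = grid.node_coordinates()
        f = VectorField(grid, rr, cc)
        out = interpolate(f, np.array([[1.5], [2.5]]))
        assert out.shape == (2, 1)
        assert out[0, 0] == pytest.approx(1.5) and out[1, 0] == pytest.approx(2.5)

    def test_rejects_non_finite_positions(self):
        with pytest.raises(ValidationError):
            interpolate_values(np.zeros((5, 5)), np.array([[np.nan], [1.0]]))

    def test_fast_sampler_matches_map_coordinates(self):
        rng = np.random.default_rng(9)
        a = rng.random((21, 17))
        b = rng.random((21, 17))
        pos = np.stack([rng.uniform(-2, 23, 300), rng.uniform(-2, 19, 300)])
        fast_a, fast_b = bilinear_sample_many((a, b), pos)
        assert np.allclose(fast_a, interpolate_values(a, pos), atol=1e-13)
        assert np.allclose(fast_b, interpolate_values(b, pos), atol=1e-13)
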