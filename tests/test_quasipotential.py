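"""Potential accumulation over grids, error maps, and the quadrature oracle."""

import numpy as np
import pytest

from quasiscape import (
    DomainEvaluationError,
    RectGrid,
    VectorFieldModel,
    compute,
    delta_V,
    error_map,
    four_well,
    four_well_exact_potential,
    oracle_line_integral,
    rotation,
    sweep_grid,
)


def square_grid(lo, hi, n):
    return RectGrid.from_bounds([[lo, hi], [lo, hi]], [n, n])


class TestRectGrid:
    def test_one_dimensional_grids_rejected(self):
        with pytest.raises(ValueError, match="at least 2 dimensions"):
            RectGrid(axes=(np.linspace(0, 1, 5),))

    def test_nonuniform_axis_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            RectGrid(axes=(np.array([0.0, 1.0, 2.5]), np.linspace(0, 1, 3)))

    def test_decreasing_axis_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            RectGrid(axes=(np.array([1.0, 0.0]), np.linspace(0, 1, 3)))

    def test_resolution_below_two_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            RectGrid.from_bounds([[0, 1], [0, 1]], [1, 5])

    def test_spacing_and_nodes(self):
        grid = square_grid(-2.0, 2.0, 41)
        np.testing.assert_allclose(grid.spacing, [0.1, 0.1])
        np.testing.assert_allclose(grid.node((0, 40)), [-2.0, 2.0])


class TestDeltaV:
    def test_quadratic_bowl_step(self):
        assert delta_V([0, 0], -np.eye(2), [1, 1]) == pytest.approx(1.0)

    def test_zero_displacement_is_zero(self):
        assert delta_V([0.3, -0.2], np.eye(2), [0, 0]) == 0.0

    def test_four_well_small_step_against_closed_form(self):
        # field (0,0) and symmetric Jacobian diag(1,1) at the origin
        model = four_well(False)
        origin = np.zeros(2)
        dv = delta_V(model(origin), model.jacobian(origin), [0.1, 0.0])
        assert dv == pytest.approx(-0.005)
        exact = four_well_exact_potential(0.1, 0.0) - four_well_exact_potential(0, 0)
        assert abs(dv - exact) < 2 * 0.1**3  # O(|dx|^3) local error

    def test_raw_asymmetric_jacobian_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            delta_V([0, 0], np.array([[0.0, -1.0], [1.0, 0.0]]), [0.1, 0.1])


class TestSweepGrid:
    def test_linear_field_exact_on_unit_grid(self, linear_sink):
        grid = RectGrid.from_bounds([[0, 1], [0, 1]], [2, 2])
        V = sweep_grid(linear_sink, grid, mode="x_first")
        np.testing.assert_allclose(V, [[0.0, 0.5], [0.5, 1.0]], atol=1e-15)

    def test_linear_field_exact_at_any_spacing(self, linear_sink):
        # the linearized step integrates a linear field exactly
        for n in (3, 11, 27):
            grid = square_grid(-3.0, 3.0, n)
            V = sweep_grid(linear_sink, grid)
            X, Y = np.meshgrid(grid.axes[0], grid.axes[1], indexing="ij")
            exact = (X**2 + Y**2) / 2.0
            np.testing.assert_allclose(V, exact - exact[0, 0], atol=1e-12)

    def test_four_well_matches_closed_form(self):
        model = four_well(False)
        grid = square_grid(-2.0, 2.0, 81)  # spacing 0.05
        V = sweep_grid(model, grid)
        X, Y = np.meshgrid(grid.axes[0], grid.axes[1], indexing="ij")
        exact = four_well_exact_potential(X, Y)
        dev = V - (exact - exact[0, 0])
        assert np.max(np.abs(dev)) < 1.1e-2  # leading O(h^2) constant

    def test_four_well_second_order_convergence(self):
        model = four_well(False)
        errs = []
        for n in (81, 161):
            grid = square_grid(-2.0, 2.0, n)
            V = sweep_grid(model, grid)
            X, Y = np.meshgrid(grid.axes[0], grid.axes[1], indexing="ij")
            exact = four_well_exact_potential(X, Y)
            errs.append(np.max(np.abs(V - (exact - exact[0, 0]))))
        assert 3.5 < errs[0] / errs[1] < 4.5

    def test_rotation_sweeps_are_path_dependent(self):
        grid = square_grid(-2.0, 2.0, 21)
        Vx = sweep_grid(rotation(), grid, mode="x_first")
        Vy = sweep_grid(rotation(), grid, mode="y_first")
        interior = np.abs(Vx - Vy)[1:, 1:]
        assert interior.max() > 0.1  # no potential exists; paths disagree

    def test_average_mode_is_mean_of_both_orders(self):
        grid = square_grid(-1.0, 1.0, 9)
        Vx = sweep_grid(rotation(), grid, mode="x_first")
        Vy = sweep_grid(rotation(), grid, mode="y_first")
        Va = sweep_grid(rotation(), grid, mode="average")
        np.testing.assert_allclose(Va, (Vx + Vy) / 2.0, atol=1e-14)

    def test_gradient_field_sweep_orders_agree_at_order_h2(self, gradient_cubic):
        diffs = []
        for n in (21, 41):
            grid = square_grid(-1.0, 1.0, n)
            Vx = sweep_grid(gradient_cubic, grid, mode="x_first")
            Vy = sweep_grid(gradient_cubic, grid, mode="y_first")
            diffs.append(np.max(np.abs(Vx - Vy)))
        assert diffs[0] > 0  # paths genuinely differ before convergence
        assert 3.0 < diffs[0] / diffs[1] < 5.0

    def test_gradient_sweep_agrees_with_quadrature_oracle(self, gradient_cubic):
        grid = square_grid(-1.0, 1.0, 41)
        V = sweep_grid(gradient_cubic, grid, mode="x_first")
        origin = grid.node((0, 0))
        for index in [(40, 40), (10, 30), (25, 5)]:
            target = grid.node(index)
            corner = np.array([target[0], origin[1]])  # axis-aligned L path
            ref = oracle_line_integral(
                gradient_cubic, [origin, corner, target], refinement=400
            )
            assert V[index] == pytest.approx(ref, abs=5e-3)

    def test_reference_shift_changes_v_by_constant_only(self, gradient_cubic):
        bounds, res = [[-1, 1], [-1, 1]], [15, 15]
        g0 = RectGrid.from_bounds(bounds, res)
        g1 = RectGrid.from_bounds(bounds, res, origin_index=(7, 3))
        V0 = sweep_grid(gradient_cubic, g0)
        V1 = sweep_grid(gradient_cubic, g1)
        assert V1[7, 3] == 0.0
        shifted = V1 - V1[0, 0]
        assert np.max(np.abs(shifted - V0)) < 1e-9

    def test_three_dimensional_sweep_against_separable_potential(self):
        def comp(k):
            return lambda s: -s[k] ** 3 + s[k]

        model = VectorFieldModel(
            dimension=3,
            components=tuple(comp(k) for k in range(3)),
            analytic_jacobian=lambda s: np.diag(1.0 - 3.0 * np.asarray(s) ** 2),
            name="three_well_axes",
        )
        grid = RectGrid.from_bounds([[-1.2, 1.2]] * 3, [25] * 3)
        V = sweep_grid(model, grid)
        a = grid.axes[0]
        pot1d = a**4 / 4.0 - a**2 / 2.0
        exact = (
            pot1d[:, None, None] + pot1d[None, :, None] + pot1d[None, None, :]
        )
        dev = np.abs(V - (exact - exact[0, 0, 0]))
        assert dev.max() < 5e-2  # O(h^2) with h = 0.1

    def test_unknown_mode_rejected(self, linear_sink):
        with pytest.raises(ValueError, match="sweep mode"):
            sweep_grid(linear_sink, square_grid(0, 1, 3), mode="diagonal")

    def test_non_finite_field_names_the_node(self):
        model = VectorFieldModel(
            dimension=2,
            components=(lambda s: 1.0 / (s[0] - 0.5), lambda s: -s[1]),
            name="pole",
        )
        with pytest.raises(DomainEvaluationError, match="grid node"):
            sweep_grid(model, square_grid(0.0, 1.0, 3))


class TestErrorMap:
    def test_rotation_error_is_one_everywhere(self):
        err = error_map(rotation(), square_grid(-2, 2, 25))
        np.testing.assert_array_equal(err, 1.0)

    def test_uncoupled_four_well_error_is_zero_everywhere(self):
        err = error_map(four_well(False), square_grid(-2, 2, 25))
        np.testing.assert_array_equal(err, 0.0)

    def test_equal_weights_give_half(self, mixed_linear):
        err = error_map(mixed_linear, square_grid(-1, 1, 9))
        np.testing.assert_allclose(err, 0.5, atol=1e-15)

    def test_constant_field_counts_as_gradient(self):
        model = VectorFieldModel(
            dimension=2,
            components=(lambda s: 1.0, lambda s: -2.0),
            analytic_jacobian=lambda s: np.zeros((2, 2)),
            name="drift",
        )
        np.testing.assert_array_equal(
            error_map(model, square_grid(0, 1, 5)), 0.0
        )

    @pytest.mark.parametrize(
        "model",
        [four_well(False), four_well(True), rotation()],
        ids=lambda m: m.name,
    )
    def test_error_always_in_unit_interval(self, model):
        err = error_map(model, square_grid(-2, 2, 31))
        assert np.all(err >= 0.0) and np.all(err <= 1.0)


class TestCompute:
    def test_bundles_are_consistent_and_deterministic(self, gradient_cubic):
        grid = square_grid(-1, 1, 13)
        r1 = compute(gradient_cubic, grid)
        r2 = compute(gradient_cubic, grid)
        np.testing.assert_array_equal(r1.V, r2.V)
        np.testing.assert_array_equal(r1.err, r2.err)
        assert r1.V[grid.origin_index] == r1.reference_value == 0.0
        assert np.all(np.isfinite(r1.V)) and np.all(np.isfinite(r1.err))
        assert r1.model_name == "gradient_cubic"

    def test_gradient_fixture_error_zero_and_mode_independent(self, gradient_cubic):
        grid = square_grid(-1, 1, 41)
        res_x = compute(gradient_cubic, grid, mode="x_first")
        res_y = compute(gradient_cubic, grid, mode="y_first")
        np.testing.assert_array_equal(res_x.err, 0.0)
        h = grid.spacing[0]
        assert np.max(np.abs(res_x.V - res_y.V)) < 5.0 * h**2

    def test_trusted_mask_threshold(self, mixed_linear):
        res = compute(mixed_linear, square_grid(-1, 1, 5))
        assert not res.trusted_mask(0.2).any()  # err = 0.5 everywhere
        assert res.trusted_mask(0.6).all()
        with pytest.raises(ValueError):
            res.trusted_mask(1.5)


class TestOracleLineIntegral:
    def test_quadratic_bowl_l_path(self, linear_sink):
        value = oracle_line_integral(
            linear_sink, [(0, 0), (1, 0), (1, 1)], refinement=1000
        )
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_four_well_diagonal_path(self):
        value = oracle_line_integral(
            four_well(False), [(0, 0), (1, 1)], refinement=10_000
        )
        assert value == pytest.approx(-0.5, abs=1e-4)

    def test_rotation_loop_integral_witnesses_no_potential(self):
        theta = np.linspace(0.0, 2.0 * np.pi, 10_001)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        value = oracle_line_integral(rotation(), circle, refinement=1)
        # -circulation: the counterclockwise loop integral of (-y, x) is 2*pi
        assert value == pytest.approx(-2.0 * np.pi, abs=1e-3)

    def test_path_needs_two_vertices(self, linear_sink):
        with pytest.raises(ValueError, match="two vertices"):
            oracle_line_integral(linear_sink, [(0, 0)], refinement=10)
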