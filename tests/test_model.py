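"""Finite-volume solver tests: closed forms, conservation, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemofit import (
    ModelParams,
    NoSteadyStateError,
    SpatialGrid,
    chemotactic_sensitivity,
    rhs,
    simulate,
    steady_state_alpha,
)
from chemofit.model import boundary_influx


def analytic_steady_alpha(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Closed-form steady cytokine profile for nu > 0 (independent oracle).

    Two-region linear two-point BVP: in the matrix channel
    ``D1 a'' + eta1 - nu a = 0`` and in the epithelial channel
    ``D2 a'' - nu a = 0``, with the Robin condition ``a'(0) = zeta a(0)``,
    zero flux at x = 1, and continuity of value and diffusive flux at x_t.
    Solved in a cosh/sinh basis via a 3x3 linear system.
    """
    D1 = params.D_alpha_bar
    D2 = params.D_alpha_bar / params.mu_alpha
    nu, eta1, zeta, xt = params.nu, params.eta1, params.zeta, params.x_t
    l1, l2 = np.sqrt(nu / D1), np.sqrt(nu / D2)
    # region 1: a = eta1/nu + A cosh(l1 x) + B sinh(l1 x)
    # region 2: a = C cosh(l2 (1 - x))   (already satisfies a'(1) = 0)
    M = np.array([
        [-zeta, l1, 0.0],
        [np.cosh(l1 * xt), np.sinh(l1 * xt), -np.cosh(l2 * (1 - xt))],
        [D1 * l1 * np.sinh(l1 * xt), D1 * l1 * np.cosh(l1 * xt),
         D2 * l2 * np.sinh(l2 * (1 - xt))],
    ])
    b = np.array([zeta * eta1 / nu, -eta1 / nu, 0.0])
    A, B, C = np.linalg.solve(M, b)
    return np.where(
        x < xt,
        eta1 / nu + A * np.cosh(l1 * x) + B * np.sinh(l1 * x),
        C * np.cosh(l2 * (1 - x)),
    )


class TestChemotacticSensitivity:
    def test_receptor_law_closed_forms(self):
        p = ModelParams(chi_bar=1.0, k=1.0, mu_rho=4.0)
        # alpha = 0 in the matrix channel: chi_tilde / k
        assert chemotactic_sensitivity(0.1, 0.0, p) == pytest.approx(1.0)
        # top channel: divided by mu_rho
        p2 = ModelParams(chi_bar=2.0, k=1.0, mu_rho=4.0)
        assert chemotactic_sensitivity(0.9, 0.0, p2) == pytest.approx(0.5)

    def test_vanishes_at_saturating_concentration(self):
        p = ModelParams()
        assert chemotactic_sensitivity(0.2, 1e9, p) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_alpha(self):
        p = ModelParams()
        alphas = np.linspace(0, 50, 200)
        vals = chemotactic_sensitivity(np.full_like(alphas, 0.2), alphas, p)
        assert np.all(np.diff(vals) < 0)

    def test_rejects_negative_alpha(self):
        with pytest.raises(ValueError):
            chemotactic_sensitivity(0.5, -1.0, ModelParams())


class TestSteadyStateAlpha:
    def test_no_production_gives_zero(self, generic_params):
        p = generic_params.replace(eta1=0.0)
        grid = SpatialGrid.for_params(p, 100)
        assert np.allclose(steady_state_alpha(p, grid), 0.0, atol=1e-14)

    def test_uniform_production_no_outflux_gives_flat_profile(self):
        # production (nearly) everywhere, no boundary outflux: a = eta1/nu
        # x_t snaps to the last interior face, so the final cell has no
        # production and the discrete profile dips slightly below eta1/nu
        p = ModelParams(eta1=0.3, nu=0.15, zeta=0.0, x_t=0.995, mu_alpha=4.0)
        grid = SpatialGrid(n_cells=200, x_t=p.x_t)
        alpha = steady_state_alpha(p, grid)
        assert np.allclose(alpha, 0.3 / 0.15, rtol=0.02)
        assert np.all(alpha <= 0.3 / 0.15 + 1e-9)

    def test_singular_balance_raises(self):
        p = ModelParams(eta1=0.1, nu=0.0, zeta=0.0)
        with pytest.raises(NoSteadyStateError):
            steady_state_alpha(p, SpatialGrid.for_params(p, 50))

    def test_matches_analytic_piecewise_solution(self, generic_params):
        grid = SpatialGrid.for_params(generic_params, 200)
        fv = steady_state_alpha(generic_params, grid)
        exact = analytic_steady_alpha(generic_params, grid.cell_centers)
        rel = np.max(np.abs(fv - exact)) / np.max(np.abs(exact))
        assert rel < 1e-3

    def test_convergence_order_at_least_1p8(self, generic_params):
        errs = []
        ns = [50, 100, 200, 400]
        for n in ns:
            grid = SpatialGrid.for_params(generic_params, n)
            fv = steady_state_alpha(generic_params, grid)
            exact = analytic_steady_alpha(generic_params, grid.cell_centers)
            errs.append(np.max(np.abs(fv - exact)) / np.max(np.abs(exact)))
        order = -np.polyfit(np.log(ns), np.log(errs), 1)[0]
        assert order >= 1.8

    def test_profile_nonnegative(self, generic_params):
        grid = SpatialGrid.for_params(generic_params, 100)
        assert np.all(steady_state_alpha(generic_params, grid) >= 0)


class TestRhs:
    def test_trivial_equilibrium(self, generic_params):
        p = generic_params.replace(eta1=0.0)
        grid = SpatialGrid.for_params(p, 80)
        z = np.zeros(80)
        drho, dalpha = rhs(z, z, p, grid)
        assert np.allclose(drho, 0) and np.allclose(dalpha, 0)

    def test_steady_alpha_is_stationary(self, generic_params):
        grid = SpatialGrid.for_params(generic_params, 120)
        alpha = steady_state_alpha(generic_params, grid)
        _, dalpha = rhs(np.zeros(120), alpha, generic_params, grid)
        assert np.max(np.abs(dalpha)) < 1e-8

    def test_pure_sink_on_uniform_density(self):
        p = ModelParams(chi_bar=0.0, eta1=0.0, eta2=0.0, xi=0.3, nu=0.1)
        grid = SpatialGrid.for_params(p, 60)
        rho = np.full(60, 2.5)
        drho, _ = rhs(rho, np.zeros(60), p, grid)
        assert np.allclose(drho, -0.3 * 2.5)

    def test_rejects_non_finite_state(self, generic_params):
        grid = SpatialGrid.for_params(generic_params, 10)
        bad = np.full(10, np.nan)
        with pytest.raises(FloatingPointError):
            rhs(bad, np.zeros(10), generic_params, grid)


class TestSimulate:
    def test_no_chemotaxis_means_no_infiltration(self, generic_params):
        p = generic_params.replace(chi_bar=0.0)
        grid = SpatialGrid.for_params(p, 80)
        sol = simulate(p, grid, [0.0, 12.0, 24.0])
        assert np.allclose(sol.rho, 0.0, atol=1e-12)

    def test_no_macrophages_means_nothing_happens(self, generic_params):
        p = generic_params.replace(eta1=0.0)
        grid = SpatialGrid.for_params(p, 80)
        sol = simulate(p, grid, [0.0, 12.0, 24.0])
        assert np.allclose(sol.rho, 0.0, atol=1e-12)
        assert np.allclose(sol.alpha, 0.0, atol=1e-12)

    def test_initial_density_zero(self, control_solution):
        assert np.allclose(control_solution.rho[0], 0.0)

    def test_mass_budget_closes_without_sink(self, generic_params):
        p = generic_params.replace(xi=0.0)
        grid = SpatialGrid.for_params(p, 200)
        times = np.arange(0.0, 24.1, 0.5)
        sol = simulate(p, grid, times)
        total = sol.total_cells()[-1]
        influx_integral = np.trapezoid(sol.influx_record, times)
        assert total == pytest.approx(influx_integral, rel=5e-3)

    def test_sink_only_loses_mass(self, generic_params):
        times = np.arange(0.0, 24.1, 2.0)
        grid = SpatialGrid.for_params(generic_params, 150)
        sol = simulate(generic_params, grid, times)
        influx_integral = np.trapezoid(sol.influx_record, times)
        assert sol.total_cells()[-1] <= influx_integral * (1 + 1e-6)

    def test_grid_convergence_monotone(self, generic_params):
        sols = {}
        for n in (50, 100, 200, 400):
            grid = SpatialGrid.for_params(generic_params, n)
            sols[n] = simulate(generic_params, grid, [0.0, 48.0])
        diffs = []
        for n in (50, 100, 200):
            coarse = sols[n]
            fine = sols[2 * n]
            x = coarse.grid.cell_centers
            fine_on_coarse = np.interp(x, fine.grid.cell_centers, fine.rho[-1])
            diffs.append(np.max(np.abs(coarse.rho[-1] - fine_on_coarse)))
        assert diffs[0] > diffs[1] > diffs[2]

    def test_rejects_bad_output_times(self, generic_params):
        grid = SpatialGrid.for_params(generic_params, 50)
        with pytest.raises(ValueError):
            simulate(generic_params, grid, [2.0, 4.0])   # must start at 0
        with pytest.raises(ValueError):
            simulate(generic_params, grid, [0.0, 4.0, 4.0])

    def test_influx_record_matches_boundary_formula(self, control,
                                                    control_solution):
        sol = control_solution
        expected = [boundary_influx(sol.alpha[i], control, sol.grid)
                    for i in range(len(sol.times))]
        assert np.allclose(sol.influx_record, expected)


@st.composite
def admissible_params(draw):
    """Random parameter sets within physically plausible ranges."""
    return ModelParams(
        D_rho_bar=draw(st.floats(1e-4, 0.02)),
        D_alpha_bar=draw(st.floats(0.01, 0.2)),
        chi_bar=draw(st.floats(0.0, 4.0)),
        mu_rho=draw(st.floats(2.0, 1000.0)),
        mu_alpha=draw(st.floats(1.5, 100.0)),
        xi=draw(st.floats(0.0, 0.2)),
        eta1=draw(st.floats(0.0, 0.5)),
        eta2=draw(st.floats(0.0, 0.05)),
        kappa=draw(st.floats(0.0, 1e-3)),
        nu=draw(st.floats(0.0, 0.5)),
        k=draw(st.floats(0.5, 20.0)),
        zeta=draw(st.floats(0.05, 1.0)),
        rho_tilde=draw(st.floats(1.0, 300.0)),
        x_t=draw(st.sampled_from([0.3, 0.5, 0.7])),
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(params=admissible_params())
def test_positivity_under_random_parameters(params):
    """Upwinded chemotactic flux keeps both fields nonnegative."""
    grid = SpatialGrid.for_params(params, 50)
    sol = simulate(params, grid, [0.0, 8.0, 16.0, 24.0])
    assert sol.rho.min() >= -1e-10
    assert sol.alpha.min() >= -1e-10


class TestQualitativeDynamics:
    """The control fixture reproduces the observed infiltration phases."""

    def test_total_infiltration_nondecreasing_and_saturating(
            self, control_solution):
        total = control_solution.total_cells()
        assert np.all(np.diff(total) >= -1e-9)
        late_rel = (total[-1] - total[-2]) / total[-1]
        assert 0 <= late_rel < 0.01

    def test_late_time_accumulation_adjacent_to_interface(
            self, control_solution):
        rho = control_solution.rho[-1]
        i = control_solution.grid.interface_face_index
        assert rho[i - 1] > rho[i - 2]
        assert rho[i - 1] > rho[i]


class TestSerialisation:
    def test_params_json_yaml_roundtrip(self, tmp_path, generic_params):
        p_json = tmp_path / "p.json"
        p_yaml = tmp_path / "p.yaml"
        generic_params.to_json(p_json)
        generic_params.to_yaml(p_yaml)
        assert ModelParams.from_json(p_json) == generic_params
        assert ModelParams.from_yaml(p_yaml) == generic_params

    def test_solution_csv_long_format(self, tmp_path, control_solution):
        out = tmp_path / "sol.csv"
        control_solution.to_csv(out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns) == ["time_h", "x", "rho", "alpha"]
        n = control_solution.grid.n_cells
        assert len(df) == len(control_solution.times) * n

    def test_grid_snaps_interface_to_face(self):
        grid = SpatialGrid(n_cells=200, x_t=0.351)
        assert grid.x_t == pytest.approx(0.35)
        assert grid.faces[grid.interface_face_index] == pytest.approx(grid.x_t)
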