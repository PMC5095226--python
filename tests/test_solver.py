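"""Solver tests: conservation, analytic limits, boundary handling, stability."""

import numpy as np
import pytest

from cellmotion import (InitialAttractantConfig, MODEL_NAMES, ParameterSet,
                        SolverFailure, SpatialGrid, TimePolynomial,
                        influx_from_counts, integrate, peclet_number,
                        semidiscretize, sigmoid_initial_attractant,
                        solve_model)
from cellmotion.solver import _interleave


def gaussian(x, mu, sig):
    return np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))


class TestSpatialGrid:
    def test_geometry(self):
        g = SpatialGrid(100.0, 50)
        assert g.dx == 2.0
        assert g.nodes[0] == 1.0 and g.nodes[-1] == 99.0
        assert np.all(np.diff(g.nodes) > 0)

    def test_rejects_tiny_grid(self):
        with pytest.raises(ValueError):
            SpatialGrid(100.0, 5)


class TestSemidiscretize:
    def test_discrete_conservation_of_rhs(self, grid, basic_params, rng):
        """Interior fluxes telescope: sum of dC/dt vanishes with no sources."""
        C = rng.uniform(0, 2, grid.n_boxes)
        A = rng.uniform(0, 1, grid.n_boxes)
        for name in MODEL_NAMES:
            p = basic_params.replace(nu=0.0, C_max=10 * C.max())
            rhs = semidiscretize(name, p, grid)
            dy = rhs(0.0, np.concatenate((C, A)))
            assert abs(np.sum(dy[:grid.n_boxes]) * grid.dx) < 1e-9

    def test_uniform_state_is_equilibrium(self, grid, basic_params):
        p = basic_params.replace(nu=0.0, gamma=TimePolynomial((-700.0,), True))
        y = np.concatenate((np.full(grid.n_boxes, 1.3),
                            np.full(grid.n_boxes, 0.6)))
        dy = semidiscretize("basic", p, grid)(0.0, y)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_upwind_transport_moves_peak_right(self, grid):
        """Pure advection: mass conserved, centroid moves with the flow."""
        # a constant rightward velocity arises from a linear attractant ramp
        p = ParameterSet(alpha=TimePolynomial.constant(10.0, True),
                         D_C=TimePolynomial((-700.0,), True),
                         gamma=TimePolynomial((-700.0,), True),
                         D_A=0.0)
        C0 = np.zeros(grid.n_boxes)
        C0[10] = 1.0 / grid.dx
        A0 = grid.nodes / grid.l  # dA/dx = 0.01 -> a = 0.1 um/h
        y0 = _interleave(C0, A0)
        rhs = semidiscretize("basic", p, grid, interleaved=True)
        sol = integrate(rhs, y0, [0.0, 40.0], grid, interleaved=True)
        mass = sol.total_cells()
        assert mass[1] == pytest.approx(mass[0], rel=1e-8)
        c0 = np.sum(sol.C[0] * grid.nodes) / np.sum(sol.C[0])
        c1 = np.sum(sol.C[1] * grid.nodes) / np.sum(sol.C[1])
        assert c1 > c0 + 1.0


class TestIntegrate:
    def test_heat_kernel_limit(self):
        """The diffusion model reproduces analytic Gaussian spreading."""
        grid = SpatialGrid(2000.0, 400)
        D = 500.0
        p = ParameterSet(D_C=TimePolynomial.constant(D, True))
        sig0 = 50.0
        C0 = gaussian(grid.nodes, 1000.0, sig0)
        sol = solve_model("diffusion", p, grid, [0.0, 1.0], C0)
        exact = gaussian(grid.nodes, 1000.0, np.sqrt(sig0 ** 2 + 2 * D * 1.0))
        assert np.max(np.abs(sol.C[1] - exact)) < 0.01 * exact.max()

    def test_mass_conservation_all_models(self, basic_params):
        grid = SpatialGrid(200.0, 80)
        C0 = gaussian(grid.nodes, 60.0, 20.0) * 50
        p = basic_params.replace(nu=0.0, C_max=5 * C0.max())
        for name in MODEL_NAMES:
            sol = solve_model(name, p, grid, [0.0, 2.0, 5.0], C0)
            mass = sol.total_cells()
            drift = np.max(np.abs(mass - mass[0])) / mass[0]
            assert drift < 1e-6, name

    def test_influx_mass_balance(self):
        """Empty domain filling at rate r: total cells equal r*t."""
        grid = SpatialGrid(100.0, 40)
        p = ParameterSet(D_C=TimePolynomial.constant(5.0, True))
        influx = influx_from_counts([0.0, 10.0], [0.0, 50.0])  # r = 5 /h
        sol = solve_model("diffusion", p, grid, [0.0, 4.0, 8.0],
                          np.zeros(grid.n_boxes), influx=influx)
        for t, total in zip(sol.times[1:], sol.total_cells()[1:]):
            assert total == pytest.approx(5.0 * t, rel=1e-3)

    def test_exponential_attractant_decay(self, basic_params):
        """With D_A=0 and frozen uniform cells, A decays as exp(-gamma C t)."""
        grid = SpatialGrid(100.0, 40)
        gamma = 0.5
        c = 2.0
        p = ParameterSet(D_C=TimePolynomial.constant(1.0, True),
                         gamma=TimePolynomial.constant(gamma, True),
                         alpha=TimePolynomial((-700.0,), True),
                         D_A=0.0, A0=1.0)
        C0 = np.full(grid.n_boxes, c)
        sol = solve_model("basic", p, grid, [0.0, 1.0], C0, rtol=1e-9,
                          atol=1e-12)
        assert np.allclose(sol.A[1], np.exp(-gamma * c * 1.0), rtol=1e-5)

    def test_exponential_growth_of_total_mass(self):
        """Closed domain with division: mass grows as e^(nu T)."""
        grid = SpatialGrid(100.0, 40)
        nu = 0.2
        p = ParameterSet(D_C=TimePolynomial.constant(5.0, True), nu=nu)
        C0 = gaussian(grid.nodes, 50.0, 10.0)
        sol = solve_model("diffusion", p, grid, [0.0, 3.0], C0,
                          rtol=1e-8, atol=1e-11)
        m = sol.total_cells()
        assert m[1] / m[0] == pytest.approx(np.exp(nu * 3.0), rel=1e-4)

    def test_attractant_maximum_principle(self, basic_params):
        """Depletion only: max A never increases and A stays non-negative."""
        grid = SpatialGrid(100.0, 40)
        p = basic_params.replace(attractant_init=InitialAttractantConfig(
            0.2, 1.0, 50.0, 0.2))
        C0 = gaussian(grid.nodes, 30.0, 10.0) * 20
        sol = solve_model("receptor_saturation", p, grid,
                          np.linspace(0, 4, 9), C0)
        peaks = sol.A.max(axis=1)
        assert np.all(np.diff(peaks) <= 1e-9)
        assert sol.A.min() >= -1e-12

    def test_no_negative_oscillations_at_high_peclet(self):
        """Upwinding keeps undershoots negligible even past Peclet 1."""
        grid = SpatialGrid(200.0, 40)  # coarse grid, dx=5
        p = ParameterSet(alpha=TimePolynomial.constant(500.0, True),
                         D_C=TimePolynomial.constant(2.0, True),
                         gamma=TimePolynomial.constant(0.5, True),
                         D_A=0.0, A0=1.0)
        C0 = gaussian(grid.nodes, 50.0, 15.0) * 100
        sol = solve_model("basic", p, grid, np.linspace(0, 3, 7), C0,
                          compute_peclet=True)
        assert sol.diagnostics["max_peclet"] > 1.0
        assert sol.C.min() > -1e-6 * sol.C.max()

    def test_failure_is_structured(self, grid):
        def bad_rhs(t, y):
            return np.full_like(y, np.nan)
        with pytest.raises(SolverFailure):
            integrate(bad_rhs, np.ones(2 * grid.n_boxes), [0.0, 1.0], grid)

    def test_rejects_negative_initial_state(self, grid, basic_params):
        rhs = semidiscretize("diffusion", basic_params, grid)
        y0 = -np.ones(2 * grid.n_boxes)
        with pytest.raises(ValueError):
            integrate(rhs, y0, [0.0, 1.0], grid)


class TestPecletNumber:
    def test_zero_advection(self):
        assert peclet_number(np.zeros(5), 1.0, 1.0) == 0.0

    def test_threshold_case(self):
        assert peclet_number(np.full(5, 2.0), 1.0, 1.0) == pytest.approx(2.0)

    def test_linear_in_dx(self):
        a = np.array([1.0, -3.0, 2.0])
        assert peclet_number(a, 2.0, 0.5) == pytest.approx(
            0.5 * peclet_number(a, 2.0, 1.0))

    def test_rejects_nonpositive_diffusion(self):
        with pytest.raises(ValueError):
            peclet_number(np.ones(3), 0.0, 1.0)


class TestSigmoidInitialAttractant:
    def test_degenerate_sigmoid_is_uniform(self, grid):
        cfg = InitialAttractantConfig(1.0, 1.0, 50.0, 0.1)
        assert np.allclose(sigmoid_initial_attractant(cfg, grid), 1.0)

    def test_midpoint_value(self):
        grid = SpatialGrid(100.0, 50)
        cfg = InitialAttractantConfig(0.2, 0.8, 49.0, 0.3)
        A = sigmoid_initial_attractant(cfg, grid)
        # node at exactly the midpoint (x=49 is a box centre)
        i = np.argmin(np.abs(grid.nodes - 49.0))
        assert A[i] == pytest.approx(0.5, rel=1e-9)
        assert np.all(np.diff(A) >= 0)
        assert A.min() >= 0.2 and A.max() <= 0.8

    def test_steep_limit_is_step(self, grid):
        cfg = InitialAttractantConfig(0.1, 1.0, 50.0, 50.0)
        A = sigmoid_initial_attractant(cfg, grid)
        left = grid.nodes < 50.0 - 10 * grid.dx
        assert np.all(A[left] < 0.1 + 1e-6)

    def test_rejects_bad_steepness(self, grid):
        with pytest.raises(ValueError):
            InitialAttractantConfig(0.0, 1.0, 50.0, 0.0)


class TestInfluxFromCounts:
    def test_constant_counts_zero_flux(self):
        flux = influx_from_counts([0.0, 5.0, 10.0], [100, 100, 100])
        assert flux(3.0) == 0.0

    def test_linear_growth_slope(self):
        flux = influx_from_counts([0.0, 10.0], [100, 200])
        assert flux(4.0) == pytest.approx(10.0)

    def test_division_explains_exponential_growth(self):
        """Counts growing exactly as e^(nu t) need no boundary influx."""
        nu = 1e-4
        t = np.linspace(0, 10, 101)
        flux = influx_from_counts(t, 100 * np.exp(nu * t), nu=nu)
        assert np.max(np.abs(flux(t[:-1]))) < 1e-6

    def test_rejects_unordered_times(self):
        with pytest.raises(ValueError):
            influx_from_counts([0.0, 0.0], [1, 2])


class TestGridConvergence:
    def test_diffusion_likelihood_converges_second_order(self):
        """Central-difference diffusion: grid-doubling deltas shrink ~4x."""
        from cellmotion.experiments import _model_for_scenario
        from cellmotion.simulate import recovery_scenario, simulate_assay
        base = recovery_scenario(0, n_boxes=60)
        obs, _ = simulate_assay(base, 0)
        lls = {}
        for nb in (200, 400, 800):
            sc = recovery_scenario(0, n_boxes=nb)
            m = _model_for_scenario(obs, sc, model="diffusion")
            lls[nb] = m.loglike(sc.params)
        d1 = abs(lls[400] - lls[200])
        d2 = abs(lls[800] - lls[400])
        assert d2 < 0.35 * d1     # second-order shrinkage
        assert d2 < 0.3           # sub-0.3-unit on a ~8000-unit loglik

    def test_advective_likelihood_converges_first_order(self):
        """Upwind advection is first order: the grid-doubling change shrinks
        by about half per refinement and is already sub-unit at 400 boxes."""
        from cellmotion.experiments import _model_for_scenario
        from cellmotion.simulate import recovery_scenario, simulate_assay
        base = recovery_scenario(0, n_boxes=60)
        obs, _ = simulate_assay(base, 0)
        lls = {}
        for nb in (200, 400, 800):
            sc = recovery_scenario(0, n_boxes=nb)
            m = _model_for_scenario(obs, sc)
            lls[nb] = m.loglike(sc.params)
        d1 = abs(lls[400] - lls[200])
        d2 = abs(lls[800] - lls[400])
        assert d2 < 0.75 * d1      # consistent refinement
        assert d2 < 1.0            # resolved to sub-unit at shipped scale


class TestStackedRhsContract:
    def test_stacked_and_interleaved_agree(self, grid, basic_params, rng):
        C = rng.uniform(0, 2, grid.n_boxes)
        A = rng.uniform(0, 1, grid.n_boxes)
        stacked = semidiscretize("full", basic_params.replace(
            C_max=10 * C.max()), grid)(0.5, np.concatenate((C, A)))
        il = semidiscretize("full", basic_params.replace(
            C_max=10 * C.max()), grid, interleaved=True)(
                0.5, _interleave(C, A))
        assert np.allclose(stacked[:grid.n_boxes], il[0::2])
        assert np.allclose(stacked[grid.n_boxes:], il[1::2])
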