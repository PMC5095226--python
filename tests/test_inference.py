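"""Inference tests: transforms, bootstrap, optimization harness, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellmotion.inference as inf
from cellmotion import (BoundSpec, Observations, ParameterSet, SpatialGrid,
                        TimePolynomial, bootstrap_resample, prune_modes)
from cellmotion.inference import (FitProblem, OptimizationResult,
                                  ParameterSpace, PseudoPosterior,
                                  InferenceFailure, maximize, fit_once,
                                  run_pseudo_posterior)
from cellmotion.simulate import recovery_scenario, simulate_assay
from cellmotion.experiments import _model_for_scenario


class TestBoundTransforms:
    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(-50, 50))
    def test_identity_roundtrip(self, x):
        tr = BoundSpec("p").transform
        assert tr.to_unconstrained(tr.to_natural(x)) == pytest.approx(x)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0.01, 1e6))
    def test_lower_bound_roundtrip(self, x):
        tr = BoundSpec("p", lower=0.0).transform
        z = tr.to_unconstrained(x)
        assert tr.to_natural(z) == pytest.approx(x, rel=1e-10)
        assert tr.to_natural(-1e3) > 0.0  # bound unbreakable

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(150.001, 199.999))
    def test_two_sided_roundtrip(self, x):
        tr = BoundSpec("D_A", 150.0, 200.0).transform
        z = tr.to_unconstrained(x)
        assert tr.to_natural(z) == pytest.approx(x, rel=1e-10)
        for zz in (-1e3, -50.0, 0.0, 50.0, 1e3):
            assert 150.0 < tr.to_natural(zz) < 200.0

    def test_upper_bound_roundtrip(self):
        tr = BoundSpec("p", upper=5.0).transform
        assert tr.to_natural(tr.to_unconstrained(4.2)) == pytest.approx(4.2)
        assert tr.to_natural(10.0) < 5.0

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="K_d"):
            BoundSpec("K_d", lower=2.0, upper=1.0)


class TestParameterSpace:
    def test_pack_unpack_roundtrip(self, basic_params):
        space = ParameterSpace("receptor_saturation", basic_params, degree=1)
        z = space.pack(basic_params)
        back = space.unpack(z)
        assert back.alpha(0.7) == pytest.approx(basic_params.alpha(0.7))
        assert back.K_d == pytest.approx(basic_params.K_d)

    def test_bounds_respected_by_construction(self, basic_params):
        space = ParameterSpace("overcrowding", basic_params,
                               scalar_bounds={"C_max": (3.0, np.inf)})
        for z in np.random.default_rng(0).normal(size=(20, space.n_free)):
            p = space.unpack(z)
            assert p.K_d >= 0.0
            assert p.C_max > 3.0
            assert p.alpha(1.0) > 0 and p.D_C(1.0) > 0 and p.gamma(1.0) > 0

    def test_free_parameter_count_by_model(self, basic_params):
        expect = {"diffusion": 1, "basic": 3, "receptor_saturation": 4,
                  "interaction": 6, "overcrowding": 5, "full": 7}
        for name, k in expect.items():
            space = ParameterSpace(name, basic_params, degree=0)
            assert space.n_free == k, name


class TestBootstrapResample:
    def test_counts_preserved(self, toy_obs, rng):
        b = bootstrap_resample(toy_obs, rng)
        assert np.array_equal(b.counts, toy_obs.counts)
        assert np.array_equal(b.times, toy_obs.times)

    def test_single_cell_group_unchanged(self, rng):
        obs = Observations([0.0], [[42.0]], 100.0)
        b = bootstrap_resample(obs, rng)
        assert np.array_equal(b.groups[0], [42.0])

    def test_resampling_is_uniform(self, rng):
        obs = Observations([0.0], [[0.0, 10.0]], 100.0)
        zeros = sum(np.sum(bootstrap_resample(obs, rng).groups[0] == 0.0)
                    for _ in range(5000))
        # 10^4 draws of a fair coin: 3-sigma band
        assert abs(zeros - 5000) < 3 * np.sqrt(10000 * 0.25)

    def test_draws_only_observed_positions(self, toy_obs, rng):
        b = bootstrap_resample(toy_obs, rng)
        for orig, boot in zip(toy_obs.groups, b.groups):
            assert set(boot) <= set(orig)


class TestMaximize:
    def test_quadratic_with_lower_bound(self):
        """Surrogate objective -(theta-2)^2 with theta > 0: optimum at 2."""
        tr = BoundSpec("theta", lower=0.0).transform
        fun = lambda z: -(tr.to_natural(z[0]) - 2.0) ** 2
        z, f, nfev, ok = maximize(fun, np.array([tr.to_unconstrained(0.5)]),
                                  maxfev=500, ftol=1e-12, xtol=1e-8)
        assert tr.to_natural(z[0]) == pytest.approx(2.0, abs=1e-4)
        assert ok

    def test_never_worse_than_start(self):
        fun = lambda z: -np.sum(z ** 2)
        x0 = np.zeros(2)  # already optimal
        z, f, _, _ = maximize(fun, x0, maxfev=50)
        assert f >= fun(x0)


@pytest.fixture(scope="module")
def tiny_problem():
    scenario = recovery_scenario(7, n_boxes=40,
                                 counts=(20, 25, 30, 35, 40, 50))
    obs, _ = simulate_assay(scenario, 7)
    model = _model_for_scenario(obs, scenario)
    return model.problem, scenario


class TestFitOnce:
    def test_achieved_at_least_initial(self, tiny_problem):
        problem, scenario = tiny_problem
        res = fit_once(problem, scenario.params, maxfev=60)
        assert res.fun >= problem.weighted_loglik(scenario.params) - 1e-9

    def test_fit_beats_generating_parameters(self, tiny_problem):
        """The MLE cannot be worse than the truth on the same data."""
        problem, scenario = tiny_problem
        res = fit_once(problem, None, maxfev=300)
        assert res.fun >= problem.weighted_loglik(scenario.params) - 1e-6


class TestRunPseudoPosterior:
    def test_reproducible_and_counts(self, tiny_problem):
        problem, _ = tiny_problem
        pp1 = run_pseudo_posterior(problem, 3, 11, maxfev=40, maxfev_center=80)
        pp2 = run_pseudo_posterior(problem, 3, 11, maxfev=40, maxfev_center=80)
        assert pp1.m == 3
        t1 = pp1.parameter_table(problem.space)
        t2 = pp2.parameter_table(problem.space)
        assert t1.equals(t2)  # bitwise reproducibility
        assert pp1.matrix.shape == (3, problem.obs.n)

    def test_parallel_matches_serial(self, tiny_problem):
        problem, _ = tiny_problem
        pp1 = run_pseudo_posterior(problem, 2, 17, maxfev=30, maxfev_center=60)
        pp2 = run_pseudo_posterior(problem, 2, 17, maxfev=30, maxfev_center=60,
                                   n_jobs=2)
        t1 = pp1.parameter_table(problem.space)
        t2 = pp2.parameter_table(problem.space)
        assert t1.equals(t2)

    def test_rejects_m_below_two(self, tiny_problem):
        problem, _ = tiny_problem
        with pytest.raises(ValueError):
            run_pseudo_posterior(problem, 1, 0)

    def test_failed_replicates_recycled(self, tiny_problem, monkeypatch):
        """Fits failing on odd replicate indices are discarded and replaced."""
        problem, _ = tiny_problem
        real_fit = inf.fit_once
        calls = []

        def flaky(problem_, init=None, *a, **kw):
            rep = kw.get("replicate_id")
            if rep is not None and rep % 2 == 1:
                raise InferenceFailure("stub failure on odd replicate")
            calls.append(rep)
            return real_fit(problem_, init, *a, **kw)

        monkeypatch.setattr(inf, "fit_once", flaky)
        pp = run_pseudo_posterior(problem, 3, 5, maxfev=30, maxfev_center=60)
        reps = [r.replicate_id for r in pp.results]
        assert len(reps) == 3
        assert all(r % 2 == 0 for r in reps)
        assert pp.report["failures"] >= 2

    def test_budget_exhaustion_is_structured(self, tiny_problem, monkeypatch):
        problem, _ = tiny_problem
        real_fit = inf.fit_once

        def always_fail(problem_, init=None, *a, **kw):
            if kw.get("replicate_id") is not None:
                raise InferenceFailure("stub")
            return real_fit(problem_, init, *a, **kw)

        monkeypatch.setattr(inf, "fit_once", always_fail)
        with pytest.raises(InferenceFailure, match="failure rate"):
            run_pseudo_posterior(problem, 2, 0, maxfev=30, maxfev_center=60)


class TestPosteriorSpreadShrinksWithData:
    def test_doubling_counts_tightens_estimates(self):
        """More cells per time point -> tighter pseudo-posterior (majority
        vote over replicate experiments, per component)."""
        base_counts = (25, 30, 35, 40, 45, 50)
        double_counts = tuple(2 * c for c in base_counts)
        wins = {k: 0 for k in ("alpha[0]", "D_C[0]", "gamma[0]")}
        n_rep = 6
        for rep in range(n_rep):
            iqrs = {}
            for counts in (base_counts, double_counts):
                scenario = recovery_scenario(100 + rep, n_boxes=40,
                                             counts=counts)
                obs, _ = simulate_assay(scenario, 100 + rep)
                model = _model_for_scenario(obs, scenario)
                res = model.fit_pseudo_posterior(
                    m=24, seed=100 + rep, maxfev=80, maxfev_center=250)
                tab = res.params_frame()
                iqrs[counts] = {
                    k: tab[k].quantile(0.75) - tab[k].quantile(0.25)
                    for k in wins}
            for k in wins:
                wins[k] += iqrs[double_counts][k] < iqrs[base_counts][k]
        for k, w in wins.items():
            assert w > n_rep / 2, (k, wins)


def _dummy_pp(values):
    values = np.asarray(values, dtype=float)
    results = [OptimizationResult(params=None, fun=v, optimizer="stub",
                                  converged=True, loglik_original=v)
               for v in values]
    matrix = np.tile(values[:, None], (1, 4))
    return PseudoPosterior(results, matrix, values.copy())


class TestPruneModes:
    def test_tight_cluster_untouched(self, rng):
        pp = _dummy_pp(-1000 + 0.5 * rng.uniform(size=30))
        out = prune_modes(pp)
        assert out.m == 30
        assert out.report["pruning"]["rows_removed"] == 0

    def test_bimodal_keeps_top_cluster(self, rng):
        low = -1100 + rng.normal(scale=1.0, size=25)
        high = -1000 + rng.normal(scale=1.0, size=25)
        pp = _dummy_pp(np.concatenate([low, high]))
        out = prune_modes(pp)
        assert out.m == 25
        assert out.logliks.min() > -1050
        assert out.matrix.shape[0] == 25

    def test_idempotent(self, rng):
        low = -1100 + rng.normal(scale=1.0, size=20)
        high = -1000 + rng.normal(scale=1.0, size=20)
        pp = _dummy_pp(np.concatenate([low, high]))
        once = prune_modes(pp)
        twice = prune_modes(once)
        assert twice.m == once.m
        assert np.array_equal(twice.logliks, once.logliks)
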