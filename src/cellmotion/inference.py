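"""Bounded maximum weighted-likelihood fits and the bootstrap pseudo-posterior.

Parameters are optimized on an unconstrained scale: one-sided bounds map
through a shifted log, two-sided bounds through a scaled logit, so bound
violations are impossible by construction.  The pseudo-posterior is the set
of optimized parameter sets obtained by refitting on bootstrap resamples of
the data (resampled with replacement within each time point); it stands in
for a Bayesian posterior sample under flat priors.  Because the optimizer
can be trapped on local optima, the pseudo-posterior may be multi-modal in
achieved likelihood; :func:`prune_modes` removes all but the highest
likelihood peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pde import ModelSpec, ParameterSet, TimePolynomial, get_model
from .likelihood import (Observations, pointwise_loglik, weighted_loglik)
from .solver import (BoundaryInflux, SolverFailure, SpatialGrid, solve_model)

__all__ = [
    "BoundSpec",
    "ParameterSpace",
    "FitProblem",
    "OptimizationResult",
    "PseudoPosterior",
    "InferenceFailure",
    "bootstrap_resample",
    "maximize",
    "fit_once",
    "run_pseudo_posterior",
    "prune_modes",
]

_BIG = 1e12


class InferenceFailure(RuntimeError):
    """Raised when an optimization cannot complete from a given start."""


# ---------------------------------------------------------------------------
# bound transforms
# ---------------------------------------------------------------------------

class _Identity:
    def to_natural(self, z):
        return z

    def to_unconstrained(self, x):
        return x


class _LogLower:
    def __init__(self, lower):
        self.lower = lower

    def to_natural(self, z):
        v = self.lower + math.exp(min(z, 700.0))
        # guard float underflow: stay strictly inside the open interval
        return v if v > self.lower else np.nextafter(self.lower, np.inf)

    def to_unconstrained(self, x):
        if x <= self.lower:
            raise ValueError(f"value {x} at or below lower bound {self.lower}")
        return math.log(x - self.lower)


class _LogUpper:
    def __init__(self, upper):
        self.upper = upper

    def to_natural(self, z):
        v = self.upper - math.exp(min(z, 700.0))
        return v if v < self.upper else np.nextafter(self.upper, -np.inf)

    def to_unconstrained(self, x):
        if x >= self.upper:
            raise ValueError(f"value {x} at or above upper bound {self.upper}")
        return math.log(self.upper - x)


class _Logit:
    def __init__(self, lower, upper):
        self.lower = lower
        self.upper = upper

    def to_natural(self, z):
        s = 1.0 / (1.0 + math.exp(-max(min(z, 700.0), -700.0)))
        v = self.lower + (self.upper - self.lower) * s
        if v <= self.lower:
            return np.nextafter(self.lower, np.inf)
        if v >= self.upper:
            return np.nextafter(self.upper, -np.inf)
        return v

    def to_unconstrained(self, x):
        if not (self.lower < x < self.upper):
            raise ValueError(f"value {x} outside ({self.lower}, {self.upper})")
        p = (x - self.lower) / (self.upper - self.lower)
        return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class BoundSpec:
    """Lower/upper bound for one scalar parameter; either may be infinite."""

    name: str
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"bounds for {self.name!r}: lower ({self.lower}) must be "
                f"strictly below upper ({self.upper})")

    @property
    def transform(self):
        lo, hi = self.lower, self.upper
        if np.isinf(lo) and np.isinf(hi):
            return _Identity()
        if np.isinf(hi):
            return _LogLower(lo)
        if np.isinf(lo):
            return _LogUpper(hi)
        return _Logit(lo, hi)


# ---------------------------------------------------------------------------
# parameter space: ParameterSet <-> unconstrained vector
# ---------------------------------------------------------------------------

_POLY_FIELDS = ("alpha", "D_C", "gamma", "eta")
_DEFAULT_SCALAR_BOUNDS = {
    "K_d": (0.0, np.inf),
    "lam": (0.0, np.inf),
    "C_max": (0.0, np.inf),
    "D_A": (0.0, np.inf),
    "attr_lower": (0.0, np.inf),
    "attr_delta": (0.0, np.inf),
    "attr_steepness": (0.0, np.inf),
}


def default_free_scalars(spec: ModelSpec) -> tuple:
    free = []
    if spec.occupancy:
        free.append("K_d")
    if spec.interaction:
        free.append("lam")
    if spec.crowding:
        free.append("C_max")
    return tuple(free)


class ParameterSpace:
    """Maps between a ParameterSet and the unconstrained optimizer vector.

    Free entries are: the polynomial coefficients of the time-varying
    parameters active in the model (identity transform; positivity comes
    from exponentiation inside the model), plus whichever scalars the model
    and configuration declare free, each with its bound transform.
    """

    def __init__(self, spec, base: ParameterSet, degree: int = 0,
                 free_scalars: Optional[Sequence[str]] = None,
                 scalar_bounds: Optional[dict] = None,
                 grid: Optional[SpatialGrid] = None):
        self.spec = get_model(spec)
        self.degree = int(degree)
        bounds = dict(scalar_bounds or {})
        if free_scalars is None:
            free_scalars = default_free_scalars(self.spec)
        self.free_scalars = tuple(free_scalars)
        # pad polynomials to the requested degree
        self.base = base.replace(**{
            f: getattr(base, f).with_degree(self.degree) for f in _POLY_FIELDS})

        self._poly_fields = ["D_C"]
        if self.spec.advection:
            self._poly_fields = ["alpha", "D_C", "gamma"]
        if self.spec.interaction:
            self._poly_fields.append("eta")

        self._entries = []  # (name, kind, key/index, transform)
        for f in self._poly_fields:
            for k in range(self.degree + 1):
                self._entries.append((f"{f}[{k}]", "coef", (f, k), _Identity()))
        estimate_sigmoid = (
            not isinstance(base.attractant_init, str)
            and getattr(base.attractant_init, "estimate", False)
            and self.spec.uses_attractant)
        sigmoid_names = (("attr_lower", "attr_delta", "attr_midpoint",
                          "attr_steepness") if estimate_sigmoid else ())
        for name in tuple(self.free_scalars) + sigmoid_names:
            lo, hi = bounds.get(name, _DEFAULT_SCALAR_BOUNDS.get(
                name, (-np.inf, np.inf)))
            if name == "attr_midpoint" and name not in bounds and grid is not None:
                lo, hi = 0.0, grid.l
            tr = BoundSpec(name, lo, hi).transform
            self._entries.append((name, "scalar", name, tr))

    @property
    def names(self):
        return [e[0] for e in self._entries]

    @property
    def n_free(self) -> int:
        return len(self._entries)

    def _scalar_value(self, params: ParameterSet, name: str) -> float:
        if name.startswith("attr_"):
            cfg = params.attractant_init
            if name == "attr_lower":
                return cfg.lower
            if name == "attr_delta":
                return cfg.upper - cfg.lower
            if name == "attr_midpoint":
                return cfg.midpoint
            return cfg.steepness
        return getattr(params, name)

    def pack(self, params: ParameterSet) -> np.ndarray:
        z = np.empty(self.n_free)
        for i, (name, kind, key, tr) in enumerate(self._entries):
            if kind == "coef":
                f, k = key
                poly = getattr(params, f).with_degree(self.degree)
                z[i] = poly.coefficients[k]
            else:
                z[i] = tr.to_unconstrained(self._scalar_value(params, key))
        return z

    def unpack(self, z: np.ndarray) -> ParameterSet:
        coefs = {f: list(getattr(self.base, f).coefficients)
                 for f in self._poly_fields}
        scalars = {}
        attr = {}
        for (name, kind, key, tr), zi in zip(self._entries, z):
            if kind == "coef":
                f, k = key
                coefs[f][k] = float(zi)
            elif key.startswith("attr_"):
                attr[key] = tr.to_natural(float(zi))
            else:
                scalars[key] = tr.to_natural(float(zi))
        kw = dict(scalars)
        for f, c in coefs.items():
            kw[f] = TimePolynomial(tuple(c), getattr(self.base, f).exponentiate)
        if attr:
            cfg = self.base.attractant_init
            kw["attractant_init"] = dc_replace(
                cfg,
                lower=attr["attr_lower"],
                upper=attr["attr_lower"] + attr["attr_delta"],
                midpoint=attr["attr_midpoint"],
                steepness=attr["attr_steepness"])
        return self.base.replace(**kw)

    def natural_values(self, params: ParameterSet) -> dict:
        out = {}
        for name, kind, key, _ in self._entries:
            if kind == "coef":
                f, k = key
                out[name] = getattr(params, f).with_degree(
                    self.degree).coefficients[k]
            else:
                out[name] = self._scalar_value(params, key)
        return out


# ---------------------------------------------------------------------------
# fit problem
# ---------------------------------------------------------------------------

@dataclass
class FitProblem:
    """Everything needed to evaluate the weighted log-likelihood of one model
    on one dataset: the candidate model, grid, initial conditions, boundary
    influx and the free-parameter space."""

    spec: ModelSpec
    obs: Observations
    grid: SpatialGrid
    base: ParameterSet
    degree: int = 0
    initial_cells: Optional[np.ndarray] = None
    influx: Optional[BoundaryInflux] = None
    free_scalars: Optional[Sequence[str]] = None
    scalar_bounds: dict = field(default_factory=dict)
    rtol: float = 1e-6
    atol: float = 1e-9
    ic_builder: Optional[Callable] = None  # obs -> (initial_cells, influx)

    def __post_init__(self):
        self.spec = get_model(self.spec)
        if self.initial_cells is None:
            if self.ic_builder is None:
                raise ValueError("need initial_cells or an ic_builder")
            self.initial_cells, self.influx = self.ic_builder(self.obs)
        self.space = ParameterSpace(self.spec, self.base, self.degree,
                                    self.free_scalars, self.scalar_bounds,
                                    self.grid)

    def with_observations(self, obs: Observations) -> "FitProblem":
        ic, influx = (self.ic_builder(obs) if self.ic_builder is not None
                      else (self.initial_cells, self.influx))
        new = FitProblem(self.spec, obs, self.grid, self.base, self.degree,
                         ic, influx, self.free_scalars, self.scalar_bounds,
                         self.rtol, self.atol, self.ic_builder)
        return new

    def solve(self, params: ParameterSet, **kw):
        return solve_model(self.spec, params, self.grid, self.obs.times,
                           self.initial_cells, influx=self.influx,
                           rtol=self.rtol, atol=self.atol, **kw)

    def weighted_loglik(self, params: ParameterSet) -> float:
        try:
            return weighted_loglik(self.solve(params), self.obs)
        except SolverFailure:
            return -np.inf

    def objective(self, z: np.ndarray) -> float:
        """Negative weighted log-likelihood of the unconstrained vector."""
        try:
            value = self.weighted_loglik(self.space.unpack(z))
        except (OverflowError, ValueError):
            return _BIG
        if not np.isfinite(value):
            return _BIG
        return -value


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    """One maximization of the weighted log-likelihood."""

    params: ParameterSet
    fun: float            # achieved weighted log-likelihood (its own data)
    optimizer: str
    converged: bool
    replicate_id: Optional[int] = None
    seed: Optional[int] = None
    nfev: int = 0
    loglik_original: float = np.nan  # weighted loglik on the unresampled data


def maximize(fun: Callable, x0: np.ndarray, method: str = "nelder-mead",
             maxfev: int = 2000, ftol: float = 1e-8, xtol: float = 1e-4):
    """Maximize ``fun`` over unconstrained coordinates.

    Returns (x_best, f_best, nfev, success).  ``fun`` returning -inf (or a
    failure penalty) is tolerated: the optimizer simply avoids the region.
    """
    neg = lambda z: -fun(z)
    x0 = np.asarray(x0, dtype=float)
    f0 = fun(x0)
    method = method.lower().replace("_", "-")
    if method in ("nelder-mead", "nm"):
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "fatol": ftol * max(1.0, abs(f0)),
                     "xatol": xtol, "adaptive": x0.size > 4})
    elif method == "bfgs":
        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"maxiter": maxfev, "gtol": 1e-5})
    else:
        raise ValueError(f"unknown optimizer {method!r}; use nelder-mead or bfgs")
    fbest = -res.fun
    if fbest < f0:  # never return a point worse than the start
        return x0, f0, res.nfev, False
    return res.x, fbest, int(res.nfev if hasattr(res, "nfev") else 0), bool(
        res.success or fbest >= f0)


def fit_once(problem: FitProblem, init=None, optimizer: str = "nelder-mead",
             maxfev: int = 2000, ftol: float = 1e-8,
             replicate_id: Optional[int] = None,
             seed: Optional[int] = None) -> OptimizationResult:
    """Maximize the weighted log-likelihood from one starting point.

    ``init`` may be a ParameterSet, an unconstrained vector, or None (start
    from the problem's base parameter set).
    """
    space = problem.space
    if init is None:
        z0 = space.pack(problem.base)
    elif isinstance(init, ParameterSet):
        z0 = space.pack(init)
    else:
        z0 = np.asarray(init, dtype=float)
    try:
        z, fbest, nfev, success = maximize(
            lambda zz: -problem.objective(zz), z0, optimizer, maxfev, ftol)
    except Exception as exc:  # noqa: BLE001 - optimizer-internal breakdown
        raise InferenceFailure(f"optimizer failed: {exc}") from exc
    if fbest <= -_BIG / 2:
        raise InferenceFailure(
            "no solvable parameter set found from this start")
    return OptimizationResult(params=space.unpack(z), fun=fbest,
                              optimizer=optimizer, converged=success,
                              replicate_id=replicate_id, seed=seed, nfev=nfev)


# ---------------------------------------------------------------------------
# bootstrap pseudo-posterior
# ---------------------------------------------------------------------------

def bootstrap_resample(obs: Observations, rng: np.random.Generator
                       ) -> Observations:
    """Resample positions with replacement within each time point.

    Per-time-point counts are preserved exactly.
    """
    groups = [rng.choice(g, size=g.size, replace=True) for g in obs.groups]
    return Observations(obs.times.copy(), groups, obs.domain_length)


@dataclass
class PseudoPosterior:
    """Retained bootstrap-optimization results and their pointwise matrix."""

    results: list
    matrix: np.ndarray            # [m x n] log p(y_i | theta_s), original data
    logliks: np.ndarray           # weighted loglik of each row, original data
    report: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.results)

    def parameter_table(self, space: ParameterSpace) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"replicate_id": r.replicate_id, "seed": r.seed,
                   "converged": r.converged, "loglik": r.loglik_original,
                   "loglik_bootstrap": r.fun}
            row.update(space.natural_values(r.params))
            rows.append(row)
        return pd.DataFrame(rows)


def _rep_rng(root_seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((root_seed, rep)))


def _one_replicate(problem, z_center, jitter, root_seed, rep, optimizer,
                   maxfev, ftol):
    rng = _rep_rng(root_seed, rep)
    obs_b = bootstrap_resample(problem.obs, rng)
    eps = rng.standard_normal(z_center.size)
    z0 = np.where(np.abs(z_center) > 1e-8,
                  z_center * (1.0 + jitter * eps), jitter * eps)
    try:
        prob_b = problem.with_observations(obs_b)
        res = fit_once(prob_b, z0, optimizer, maxfev, ftol,
                       replicate_id=rep, seed=root_seed)
    except (InferenceFailure, SolverFailure):
        return None
    return res if np.isfinite(res.fun) else None


def run_pseudo_posterior(problem: FitProblem, m_target: int, root_seed: int,
                         optimizer: str = "nelder-mead",
                         maxfev: int = 2000, maxfev_center: Optional[int] = None,
                         jitter: float = 0.05,
                         center: Optional[OptimizationResult] = None,
                         ftol: float = 1e-8, n_jobs: int = 1,
                         n_starts: int = 1, start_spread: float = 1.5
                         ) -> PseudoPosterior:
    """Bootstrap-optimization pseudo-posterior with failure recycling.

    The full dataset is fitted once from the base start (optionally from
    ``n_starts`` dispersed starting points, keeping the best — the
    likelihood surface is multi-modal and a single start can be trapped on
    a mode where a richer model merely mimics a poorer one); every
    bootstrap fit then starts from that maximum-weighted-likelihood point
    jittered by multiplicative noise.  Failed fits are discarded and fresh
    replicates drawn until ``m_target`` successes or a 3x retry budget is
    exhausted.  Replicates are keyed by index (seed derived from
    (root_seed, index)), so the retained set is independent of parallel
    scheduling; with ``n_jobs > 1`` the bootstrap fits run in joblib
    workers.
    """
    if m_target < 2:
        raise ValueError("m_target must be at least 2")
    if center is None:
        mc = maxfev_center or max(maxfev, 400)
        center = fit_once(problem, None, optimizer, mc, ftol)
        if n_starts > 1:
            z_base = problem.space.pack(problem.base)
            rng0 = np.random.default_rng(
                np.random.SeedSequence((root_seed, 0x57A275)))
            for _ in range(n_starts - 1):
                z_try = z_base + start_spread * rng0.standard_normal(
                    z_base.size)
                try:
                    cand = fit_once(problem, z_try, optimizer, mc, ftol)
                except (InferenceFailure, SolverFailure):
                    continue
                if cand.fun > center.fun:
                    center = cand
            # polish the winning start
            center = fit_once(problem, center.params, optimizer, mc, ftol)
    z_center = problem.space.pack(center.params)

    results = []
    attempts = 0
    rep = 0
    budget = 3 * m_target
    if n_jobs != 1:
        from joblib import Parallel, delayed
        while len(results) < m_target and attempts < budget:
            wave = min(m_target - len(results), budget - attempts)
            out = Parallel(n_jobs=n_jobs)(
                delayed(_one_replicate)(problem, z_center, jitter, root_seed,
                                        rep + i, optimizer, maxfev, ftol)
                for i in range(wave))
            attempts += wave
            rep += wave
            results.extend(r for r in out if r is not None)
        results = sorted(results, key=lambda r: r.replicate_id)[:m_target]
    else:
        while len(results) < m_target and attempts < budget:
            res = _one_replicate(problem, z_center, jitter, root_seed, rep,
                                 optimizer, maxfev, ftol)
            attempts += 1
            rep += 1
            if res is not None:
                results.append(res)
    if len(results) < m_target:
        raise InferenceFailure(
            f"bootstrap budget exhausted: {len(results)}/{m_target} fits "
            f"succeeded in {attempts} attempts "
            f"(failure rate {1 - len(results) / attempts:.2f})")

    rows, kept = [], []
    for res in results:
        try:
            sol = problem.solve(res.params)
        except SolverFailure:
            warnings.warn("dropping pseudo-posterior row whose solve failed "
                          "on the original data")
            continue
        row = pointwise_loglik(sol, problem.obs)
        if not np.all(np.isfinite(row)):
            continue
        res.loglik_original = float(
            problem.obs.n / problem.obs.T
            * sum(row[s].sum() / n for s, n in _group_slices(problem.obs)))
        rows.append(row)
        kept.append(res)
    matrix = np.vstack(rows)
    logliks = np.array([r.loglik_original for r in kept])
    report = {"m_target": m_target, "attempts": attempts,
              "failures": attempts - len(results),
              "rows_dropped_on_original": len(results) - len(kept),
              "root_seed": root_seed, "optimizer": optimizer,
              "center_loglik": center.fun,
              "substitutions": {
                  "start_rule": "jittered-MLE starts",
                  "pruning_rule": "KDE antimode split (applied separately)"}}
    return PseudoPosterior(kept, matrix, logliks, report)


def _group_slices(obs: Observations):
    start = 0
    for g in obs.groups:
        yield slice(start, start + g.size), g.size
        start += g.size


def prune_modes(pp: PseudoPosterior, min_spread: float = 1.0,
                depth: float = 0.8) -> PseudoPosterior:
    """Keep only the highest-likelihood peak of the pseudo-posterior.

    The 1-D distribution of achieved weighted log-likelihoods is kernel
    smoothed; antimodes whose density dips below ``depth`` times the smaller
    neighbouring peak split the sample into clusters, and only the cluster
    containing the global maximum is retained.  Unimodal input (or spread
    below ``min_spread`` log-likelihood units) passes through unchanged.
    """
    if pp.m < 2:
        raise ValueError("pseudo-posterior needs at least two rows")
    values = pp.logliks
    spread = float(values.max() - values.min())
    report = dict(pp.report)
    if spread < min_spread or np.allclose(values, values[0]):
        report["pruning"] = {"modes_found": 1, "rows_removed": 0}
        return PseudoPosterior(pp.results, pp.matrix, pp.logliks, report)
    try:
        kde = stats.gaussian_kde(values)
    except np.linalg.LinAlgError:
        report["pruning"] = {"modes_found": 1, "rows_removed": 0}
        return PseudoPosterior(pp.results, pp.matrix, pp.logliks, report)
    pad = 0.1 * spread
    xs = np.linspace(values.min() - pad, values.max() + pad, 512)
    d = kde(xs)
    cuts = []
    i_mins = np.where((d[1:-1] < d[:-2]) & (d[1:-1] <= d[2:]))[0] + 1
    for i in i_mins:
        left_peak = d[:i].max()
        right_peak = d[i:].max()
        if d[i] < depth * min(left_peak, right_peak):
            cuts.append(xs[i])
    if not cuts:
        report["pruning"] = {"modes_found": 1, "rows_removed": 0}
        return PseudoPosterior(pp.results, pp.matrix, pp.logliks, report)
    below_max = [c for c in cuts if c < values.max()]
    thr = max(below_max) if below_max else -np.inf
    keep = values > thr
    if keep.sum() < 2:  # never prune below the minimum usable size
        keep = np.argsort(values)[-2:]
        keep = np.isin(np.arange(values.size), keep)
    results = [r for r, k in zip(pp.results, keep) if k]
    report["pruning"] = {"modes_found": len(cuts) + 1,
                         "rows_removed": int((~keep).sum()),
                         "threshold": float(thr)}
    return PseudoPosterior(results, pp.matrix[keep], values[keep], report)
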