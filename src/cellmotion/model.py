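"""statsmodels-style front end: a Model built from data, a Results object.

`CellMigrationModel` couples one candidate movement model to one observed
coordinate dataset (initial conditions, boundary influx, grid and bounds
resolved from the data and configuration).  ``fit()`` maximizes the
weighted log-likelihood; ``fit_pseudo_posterior()`` additionally builds the
bootstrap pseudo-posterior, enabling WAIC and percentile intervals.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import selection
from .inference import (FitProblem, OptimizationResult, PseudoPosterior,
                        fit_once, prune_modes, run_pseudo_posterior)
from .likelihood import Observations
from .pde import ModelSpec, ParameterSet, TimePolynomial, get_model
from .simulate import initial_density_estimate
from .solver import (BoundaryInflux, SpatialGrid, influx_from_counts,
                     solve_model)

__all__ = ["CellMigrationModel", "CellMigrationResults",
           "max_observed_density", "default_start"]


def max_observed_density(obs: Observations, grid: SpatialGrid) -> float:
    """Maximum cell density (cells/um) over the per-time density estimates.

    Used as the lower bound for C_max during inference: the packing
    density cannot be below what was actually observed.
    """
    peak = 0.0
    for g in obs.groups:
        if g.size >= 5:
            peak = max(peak, float(initial_density_estimate(g, grid).max()))
    if peak == 0.0:
        peak = obs.counts.max() / grid.l
    return peak


def default_start(obs: Observations, spec: ModelSpec,
                  grid: SpatialGrid) -> ParameterSet:
    """Moderate data-scaled starting parameter set for optimization."""
    l, tmax = obs.l, float(obs.times.max())
    tmax = max(tmax, 1e-6)
    nbar = float(obs.counts.mean())
    cbar = max(nbar / l, 1e-12)
    kw = dict(
        D_C=TimePolynomial.constant(0.02 * l ** 2 / tmax, True),
        alpha=TimePolynomial.constant(0.25 * l ** 2 / tmax, True),
        gamma=TimePolynomial.constant(0.5 / (tmax * cbar), True),
        eta=TimePolynomial.constant(0.0, False),
        D_A=0.1 * l ** 2 / tmax,
        K_d=1.0,
        lam=1.0 / cbar,
        attractant_init="uniform", A0=1.0,
    )
    return ParameterSet(**kw)


class CellMigrationModel:
    """One candidate advection-diffusion-reaction model bound to data.

    Parameters
    ----------
    obs
        :class:`Observations` (or a DataFrame with time_h / x_um columns
        via :meth:`from_dataframe`).
    model
        Candidate name: diffusion, basic, receptor_saturation, interaction,
        overcrowding or full.
    degree
        Polynomial degree for the time-varying parameters (same degree for
        all of them).
    start
        Base :class:`ParameterSet` providing starting values and the fixed
        (non-estimated) scalars such as D_A, nu and the initial attractant
        configuration.  Defaults to a data-scaled moderate start.
    initial_cells
        ``"estimate"`` (density estimate of the earliest time point),
        ``"empty"`` (C(x,0)=0; requires an influx) or an explicit density
        array on the grid.
    influx
        ``"from_counts"`` (left-boundary flux derived from the observed
        per-time totals), ``None``, or an explicit BoundaryInflux.
    """

    def __init__(self, obs: Observations, model: Union[str, ModelSpec] = "basic",
                 degree: int = 0, n_boxes: int = 100,
                 grid: Optional[SpatialGrid] = None,
                 start: Optional[ParameterSet] = None,
                 initial_cells: Union[str, np.ndarray] = "estimate",
                 influx: Union[str, BoundaryInflux, None] = None,
                 free_scalars: Optional[Sequence[str]] = None,
                 bounds: Optional[dict] = None,
                 reestimate_initial: bool = True,
                 rtol: float = 1e-6, atol: float = 1e-9):
        self.obs = obs
        self.spec = get_model(model)
        self.degree = int(degree)
        self.grid = grid or SpatialGrid(obs.domain_length, n_boxes)
        self.start = start or default_start(obs, self.spec, self.grid)
        bounds = dict(bounds or {})
        if self.spec.crowding and "C_max" not in bounds:
            lower = max_observed_density(obs, self.grid)
            bounds["C_max"] = (lower, np.inf)
        if self.spec.crowding:
            lo = bounds["C_max"][0]
            if self.start.C_max <= lo:
                self.start = self.start.replace(C_max=2.0 * max(lo, 1e-12))
        self._bounds = bounds
        self._initial_mode = initial_cells
        self._influx_mode = influx

        ic_builder = None
        static_ic, static_influx = self._resolve_ic(obs)
        if ((isinstance(initial_cells, str) and initial_cells == "estimate"
             and reestimate_initial)):
            ic_builder = self._resolve_ic
        self.problem = FitProblem(
            self.spec, obs, self.grid, self.start, self.degree,
            static_ic, static_influx, free_scalars, bounds,
            rtol, atol, ic_builder)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, domain_length: float, **kw
                       ) -> "CellMigrationModel":
        return cls(Observations.from_dataframe(df, domain_length), **kw)

    @classmethod
    def from_csv(cls, path, domain_length: Optional[float] = None, **kw
                 ) -> "CellMigrationModel":
        from .io import read_observations
        return cls(read_observations(path, domain_length), **kw)

    def _resolve_ic(self, obs: Observations):
        mode = self._initial_mode
        if isinstance(mode, str):
            if mode == "estimate":
                C0 = initial_density_estimate(obs.groups[0], self.grid)
            elif mode == "empty":
                C0 = np.zeros(self.grid.n_boxes)
            else:
                raise ValueError(f"unknown initial_cells mode {mode!r}")
        else:
            C0 = np.asarray(mode, dtype=float)
        influx = self._influx_mode
        if isinstance(influx, str):
            if influx != "from_counts":
                raise ValueError(f"unknown influx mode {influx!r}")
            times, counts = obs.times, obs.counts.astype(float)
            if times[0] > 0:  # domain empty before the first observation
                times = np.concatenate(([0.0], times))
                counts = np.concatenate(([C0.sum() * self.grid.dx], counts))
            influx = influx_from_counts(times, counts, nu=self.start.nu)
        return C0, influx

    # -- statsmodels-style API ----------------------------------------------

    @property
    def nobs(self) -> int:
        return self.obs.n

    @property
    def k_params(self) -> int:
        return self.problem.space.n_free

    def loglike(self, params: ParameterSet) -> float:
        """Weighted log-likelihood of a parameter set."""
        return self.problem.weighted_loglik(params)

    def solve(self, params: ParameterSet, **kw):
        return self.problem.solve(params, **kw)

    def fit(self, method: str = "nelder-mead", start: Optional[ParameterSet] = None,
            maxfev: int = 2000, ftol: float = 1e-8) -> "CellMigrationResults":
        res = fit_once(self.problem, start, method, maxfev, ftol)
        res.loglik_original = res.fun
        return CellMigrationResults(self, res)

    def fit_pseudo_posterior(self, m: int = 100, seed: int = 0,
                             method: str = "nelder-mead", maxfev: int = 2000,
                             maxfev_center: Optional[int] = None,
                             prune: bool = True, jitter: float = 0.05,
                             n_starts: int = 1,
                             n_jobs: int = 1) -> "CellMigrationResults":
        pp = run_pseudo_posterior(self.problem, m, seed, method,
                                  maxfev=maxfev, maxfev_center=maxfev_center,
                                  jitter=jitter, n_starts=n_starts,
                                  n_jobs=n_jobs)
        if prune:
            pp = prune_modes(pp)
        best = int(np.argmax(pp.logliks))
        return CellMigrationResults(self, pp.results[best], pp)

    def select_degree(self, degrees: Sequence[int] = (0, 1, 2, 3),
                      method: str = "nelder-mead", maxfev: int = 2000):
        """Pick the shared polynomial degree by AICc/BIC improvement."""
        def factory(d):
            clone = CellMigrationModel(
                self.obs, self.spec, d, grid=self.grid, start=self.start,
                initial_cells=self._initial_mode, influx=self._influx_mode,
                bounds=self._bounds,
                reestimate_initial=self.problem.ic_builder is not None,
                rtol=self.problem.rtol, atol=self.problem.atol)
            return clone.problem
        return selection.select_polynomial_degree(factory, degrees,
                                                  method, maxfev)


class CellMigrationResults:
    """Fit results: estimates, uncertainty, information criteria, summary."""

    def __init__(self, model: CellMigrationModel, mle: OptimizationResult,
                 pseudo_posterior: Optional[PseudoPosterior] = None):
        self.model = model
        self.mle = mle
        self.pp = pseudo_posterior

    # -- point estimates -----------------------------------------------------

    @property
    def params(self) -> ParameterSet:
        return self.mle.params

    @property
    def llf(self) -> float:
        """Maximum weighted log-likelihood achieved."""
        v = self.mle.loglik_original
        return float(v if np.isfinite(v) else self.mle.fun)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def aicc(self) -> float:
        return selection.aicc(self.llf, self.k_params, self.nobs)

    @property
    def bic(self) -> float:
        return selection.bic(self.llf, self.k_params, self.nobs)

    @property
    def waic(self) -> float:
        self._need_pp()
        return selection.waic(self.pp.matrix)

    @property
    def waic_se(self) -> float:
        self._need_pp()
        return selection.waic_se(self.pp.matrix)

    def _need_pp(self):
        if self.pp is None:
            raise ValueError("no pseudo-posterior: use fit_pseudo_posterior()")

    # -- uncertainty ---------------------------------------------------------

    def params_frame(self) -> pd.DataFrame:
        """Pseudo-posterior draws as a table of natural-scale parameters."""
        self._need_pp()
        return self.pp.parameter_table(self.model.problem.space)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Central pseudo-posterior percentile intervals per parameter."""
        self._need_pp()
        tab = self.params_frame()
        cols = self.model.problem.space.names
        lo = tab[cols].quantile(alpha / 2)
        hi = tab[cols].quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- diagnostics ---------------------------------------------------------

    @property
    def solution(self):
        """Forward solve at the point estimate, with Peclet diagnostics."""
        if not hasattr(self, "_solution"):
            self._solution = self.model.solve(self.params, compute_peclet=True)
        return self._solution

    @property
    def max_peclet(self) -> float:
        return self.solution.diagnostics.get("max_peclet", np.nan)

    def plot_fit(self, axes=None, density_points: int = 400):
        """Diagnostic panels: observed vs modelled cell density per time point.

        Blue: boundary-corrected density estimate of the observed positions
        (scaled to the observed count); red dashed: model density scaled to
        the same count; green dotted: latent attractant (right axis scale).
        Returns the matplotlib figure.
        """
        import matplotlib
        import matplotlib.pyplot as plt
        from .simulate import initial_density_estimate

        m = self.model
        obs = m.obs
        sol = self.solution
        T = obs.T
        if axes is None:
            ncol = min(T, 3)
            nrow = int(np.ceil(T / ncol))
            fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.6 * nrow),
                                     sharex=True, squeeze=False)
            axes = axes.ravel()
        else:
            fig = axes[0].figure
        x = m.grid.nodes
        for j, (t, g) in enumerate(zip(obs.times, obs.groups)):
            ax = axes[j]
            i = sol.time_index(t)
            C = np.clip(sol.C[i], 0.0, None)
            total = np.trapezoid(C, x)
            if total > 0:
                ax.plot(x, C * (g.size / total), "r--", lw=1.2,
                        label="model")
            if g.size >= 5:
                ax.plot(x, initial_density_estimate(g, m.grid), "b-",
                        lw=1.2, label="data")
            ax2 = ax.twinx()
            ax2.plot(x, sol.A[i], "g:", lw=1.0, label="attractant")
            ax2.set_yticks([])
            ax.set_title(f"t = {t:g} h", fontsize=9)
        for ax in axes[T:]:
            ax.set_visible(False)
        axes[0].legend(fontsize=7, loc="upper right")
        fig.supxlabel("x (um)")
        fig.supylabel("cell density (cells/um)")
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        m = self.model
        space = m.problem.space
        lines = [
            "Collective cell movement model fit",
            "=" * 54,
            f"model:            {m.spec.name} (polynomial degree {m.degree})",
            f"observations:     {m.nobs} cells over {m.obs.T} time points",
            f"domain:           {m.obs.l:g} um, {m.grid.n_boxes} boxes",
            f"free parameters:  {self.k_params}",
            f"weighted loglik:  {self.llf:.3f}",
            f"AICc: {self.aicc:.2f}   BIC: {self.bic:.2f}",
        ]
        if self.pp is not None:
            lines.append(f"WAIC: {self.waic:.2f} (SE {self.waic_se:.2f})  "
                         f"[pseudo-posterior m={self.pp.m}]")
        lines.append(f"max grid Peclet:  {self.max_peclet:.3f}"
                     + ("  (instability risk)" if self.max_peclet > 1 else ""))
        lines.append("-" * 54)
        vals = space.natural_values(self.params)
        ci = self.conf_int() if self.pp is not None else None
        for name in space.names:
            row = f"{name:18s} {vals[name]:14.6g}"
            if ci is not None:
                row += f"   [{ci.loc[name, 'lower']:.6g}, " \
                       f"{ci.loc[name, 'upper']:.6g}]"
            lines.append(row)
        return "\n".join(lines)
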