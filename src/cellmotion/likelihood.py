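"""Cell-position likelihoods from a forward-solved density field.

Each observed cell coordinate y_i at time point t_j contributes the
normalized model density

    p(y_i | theta) = C(y_i, t_j) / integral_0^l C(x, t_j) dx,

so the likelihood is invariant to the absolute scale of C.  Because the
number of observed cells grows over time in movement assays, the standard
log-likelihood over-weights late time points; the weighted form

    l_w = (n / T) * sum_j l_j / n_j

gives each time point equal voice and the factor n/T returns the value to
the scale of the standard log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .solver import Solution

__all__ = [
    "Observations",
    "point_likelihood",
    "loglik_by_timepoint",
    "total_loglik",
    "weighted_loglik",
    "pointwise_loglik_matrix",
    "DENSITY_FLOOR",
]

DENSITY_FLOOR = 1e-300


@dataclass
class Observations:
    """Cell x-coordinates grouped by observation time.

    Attributes
    ----------
    times : observation times (hours), strictly increasing, one per group
    groups : list of position arrays (micrometres), one per time point
    domain_length : chamber length l (micrometres)
    """

    times: np.ndarray
    groups: list
    domain_length: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("need at least one observation time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if len(self.groups) != self.times.size:
            raise ValueError("one position group per time point required")
        self.groups = [np.sort(np.asarray(g, dtype=float)) for g in self.groups]
        for t, g in zip(self.times, self.groups):
            if g.size == 0:
                raise ValueError(f"time point t={t} has no cells")
            bad = g[(g < 0) | (g > self.domain_length)]
            if bad.size:
                raise ValueError(
                    f"position {bad[0]:.6g} at t={t} outside [0, "
                    f"{self.domain_length}]")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, domain_length: float
                       ) -> "Observations":
        if not {"time_h", "x_um"} <= set(df.columns):
            raise ValueError("dataframe needs columns time_h and x_um")
        times = np.sort(df["time_h"].unique())
        groups = [df.loc[df["time_h"] == t, "x_um"].to_numpy() for t in times]
        return cls(times, groups, domain_length)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, x) for t, g in zip(self.times, self.groups) for x in g]
        return pd.DataFrame(rows, columns=["time_h", "x_um"])

    @property
    def counts(self) -> np.ndarray:
        return np.array([g.size for g in self.groups])

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def T(self) -> int:
        return int(self.times.size)

    @property
    def l(self) -> float:
        return self.domain_length


def _normalized_density(solution: Solution, t_index: int):
    """Nodes (with boundary extension) and unit-integral density at one time.

    Box-centre values are extended to the domain edges by constant
    extrapolation and integrated with the trapezoid rule; a zero total mass
    signals a degenerate parameter set.
    """
    grid = solution.grid
    C = np.clip(solution.C[t_index], 0.0, None)
    xs = np.concatenate(([0.0], grid.nodes, [grid.l]))
    vals = np.concatenate(([C[0]], C, [C[-1]]))
    total = np.trapezoid(vals, xs)
    if total <= 0 or not np.isfinite(total):
        raise ZeroDivisionError(
            f"zero or non-finite total modelled mass at time index {t_index}")
    return xs, vals / total


def point_likelihood(solution: Solution, t_index: int, x) -> np.ndarray:
    """Normalized model density at position(s) x (1/um), floored at 1e-300."""
    xs, dens = _normalized_density(solution, t_index)
    p = np.interp(np.asarray(x, dtype=float), xs, dens)
    p = np.maximum(p, DENSITY_FLOOR)
    return p if p.ndim else float(p)


def loglik_by_timepoint(solution: Solution, obs: Observations) -> np.ndarray:
    """Per-time-point log-likelihoods l_j (sums over the cells of group j)."""
    out = np.empty(obs.T)
    for j, (t, g) in enumerate(zip(obs.times, obs.groups)):
        idx = solution.time_index(t)
        try:
            out[j] = float(np.sum(np.log(point_likelihood(solution, idx, g))))
        except ZeroDivisionError:
            out[j] = -np.inf
    return out


def total_loglik(solution: Solution, obs: Observations) -> float:
    """Standard log-likelihood: sum of log p(y_i) over all cells."""
    return float(loglik_by_timepoint(solution, obs).sum())


def weighted_loglik(solution: Solution, obs: Observations) -> float:
    """Time-point-weighted log-likelihood (n/T) sum_j l_j / n_j."""
    lj = loglik_by_timepoint(solution, obs)
    nj = obs.counts
    return float(obs.n / obs.T * np.sum(lj / nj))


def pointwise_loglik(solution: Solution, obs: Observations) -> np.ndarray:
    """log p(y_i) for every cell, concatenated in (time, position) order."""
    parts = []
    for t, g in zip(obs.times, obs.groups):
        idx = solution.time_index(t)
        try:
            parts.append(np.log(point_likelihood(solution, idx, g)))
        except ZeroDivisionError:
            parts.append(np.full(g.size, -np.inf))
    return np.concatenate(parts)


def pointwise_loglik_matrix(solutions: Sequence[Solution], obs: Observations
                            ) -> np.ndarray:
    """Stack pointwise log-likelihood rows for a set of solved parameter sets.

    Row s corresponds to pseudo-posterior draw s, column i to observation i.
    """
    rows = [pointwise_loglik(sol, obs) for sol in solutions]
    return np.vstack(rows)
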