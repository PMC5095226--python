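"""Reusable end-to-end experiment harnesses.

These drive the full pipeline on synthetic scenarios with known truth:
parameter-recovery coverage, model-selection consistency, polynomial-degree
selection and the pseudo-posterior-vs-exact-posterior WAIC check.  They are
what the command-line ``recover`` subcommand, the test suite and the
reproduction script all call, so every reported number comes through one
code path.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Sequence

import numpy as np

from .inference import FitProblem
from .model import CellMigrationModel
from .pde import TimePolynomial
from .selection import compare_models, validate_waic_on_benchmark
from .simulate import (ScenarioConfig, recovery_scenario, saturation_scenario,
                       simulate_assay)

__all__ = [
    "recovery_experiment",
    "recovery_study",
    "selection_experiment",
    "selection_study",
    "degree_experiment",
    "degree_study",
    "waic_benchmark_study",
]

# Desk-scale optimizer budgets: bootstrap fits start near the full-data
# optimum, so they need far fewer simplex steps than the centre fit.
MAXFEV_CENTER = 400
MAXFEV_BOOT = 120


def _model_for_scenario(obs, scenario: ScenarioConfig, model: Optional[str]
                        = None, degree: int = 0) -> CellMigrationModel:
    """Bind a candidate model to simulated data, fixing the assay constants
    (D_A, nu, initial attractant, initial cell layout) at their true values."""
    from .model import default_start
    spec_name = model or scenario.model
    start = default_start(obs, None, scenario.grid).replace(
        D_A=scenario.params.D_A, nu=scenario.params.nu,
        attractant_init=scenario.params.attractant_init,
        A0=scenario.params.A0)
    return CellMigrationModel(
        obs, spec_name, degree=degree, grid=scenario.grid, start=start,
        initial_cells=(scenario.initial_cells if scenario.initial_cells
                       is not None else "empty"),
        influx=("from_counts" if scenario.influx_counts is not None else None),
        rtol=1e-5, atol=1e-8)


def recovery_experiment(seed: int, m: int = 100, n_boxes: int = 50,
                        maxfev: int = 100,
                        maxfev_center: int = 300) -> dict:
    """One parameter-recovery replicate on the basic-model scenario.

    Simulates an assay with known alpha, D_C, gamma; fits the generating
    model with an m-replicate pseudo-posterior; reports whether each true
    value falls inside the central 95-percentile interval.
    """
    scenario = recovery_scenario(seed, n_boxes)
    obs, _ = simulate_assay(scenario, seed)
    model = _model_for_scenario(obs, scenario)
    res = model.fit_pseudo_posterior(m=m, seed=seed, maxfev=maxfev,
                                     maxfev_center=maxfev_center)
    ci = res.conf_int(alpha=0.05)
    truth = {"alpha[0]": math.log(scenario.params.alpha(0.0)),
             "D_C[0]": math.log(scenario.params.D_C(0.0)),
             "gamma[0]": math.log(scenario.params.gamma(0.0))}
    inside = {k: bool(ci.loc[k, "lower"] <= v <= ci.loc[k, "upper"])
              for k, v in truth.items()}
    return {"seed": seed, "inside": inside, "truth": truth,
            "conf_int": ci.loc[list(truth)].to_dict(),
            "m_retained": res.pp.m, "llf": res.llf}


def recovery_study(n_seeds: int = 20, m: int = 100, n_boxes: int = 50,
                   seed0: int = 0) -> dict:
    """Coverage of the 95-percentile intervals over replicate experiments."""
    reports = [recovery_experiment(seed0 + s, m, n_boxes)
               for s in range(n_seeds)]
    flags = [v for r in reports for v in r["inside"].values()]
    return {"n_seeds": n_seeds, "m": m,
            "coverage": float(np.mean(flags)),
            "n_components": len(flags),
            "per_seed": [r["inside"] for r in reports]}


def selection_experiment(seed: int, m: int = 50,
                         models: Sequence[str] = ("diffusion", "basic",
                                                  "receptor_saturation"),
                         n_boxes: int = 60, maxfev: int = MAXFEV_BOOT,
                         maxfev_center: int = MAXFEV_CENTER):
    """Compare candidate models on data generated with strong receptor
    saturation; returns the ComparisonTable."""
    scenario = saturation_scenario(seed, n_boxes)
    obs, _ = simulate_assay(scenario, seed)
    problems: Dict[str, FitProblem] = {}
    for name in models:
        problems[name] = _model_for_scenario(obs, scenario, name).problem
    return compare_models(problems, m, seed, maxfev=maxfev,
                          maxfev_center=maxfev_center)


def selection_study(n_seeds: int = 5, m: int = 50, seed0: int = 0) -> dict:
    """How often the generating (receptor-saturation) model wins on WAIC."""
    wins = 0
    tables = []
    for s in range(n_seeds):
        table = selection_experiment(seed0 + s, m)
        t = table.table.set_index("model")["waic"]
        ok = (t["receptor_saturation"] < t["diffusion"]
              and t["receptor_saturation"] < t["basic"])
        wins += bool(ok)
        tables.append(t.to_dict())
    return {"n_seeds": n_seeds, "m": m, "wins": wins,
            "win_fraction": wins / n_seeds, "tables": tables}


def degree_experiment(truth: str, seed: int, degrees: Sequence[int] = (0, 1, 2),
                      n_boxes: int = 60, maxfev: int = 600) -> int:
    """Select the time-polynomial degree on data with known time structure.

    ``truth="constant"``: all generating parameters constant in time (the
    right answer is degree 0).  ``truth="linear"``: the chemotactic
    responsiveness grows strongly (log-linearly) in time, so degree >= 1
    should be selected.
    """
    scenario = recovery_scenario(seed, n_boxes)
    if truth == "linear":
        a0 = scenario.params.alpha(0.0)
        scenario = scenario.replace(params=scenario.params.replace(
            alpha=TimePolynomial((math.log(a0 / 3.0), 0.5), True)))
    elif truth != "constant":
        raise ValueError("truth must be 'constant' or 'linear'")
    obs, _ = simulate_assay(scenario, seed)

    def factory(d):
        return _model_for_scenario(obs, scenario, degree=d).problem

    from .selection import select_polynomial_degree
    selected, _ = select_polynomial_degree(factory, degrees, maxfev=maxfev)
    return selected


def degree_study(n_seeds: int = 10, seed0: int = 0, **kw) -> dict:
    """Majority-vote degree selection under constant and linear truths."""
    const = [degree_experiment("constant", seed0 + s, **kw)
             for s in range(n_seeds)]
    lin = [degree_experiment("linear", seed0 + s, **kw)
           for s in range(n_seeds)]
    return {
        "constant_degrees": const, "linear_degrees": lin,
        "constant_majority_zero": sum(d == 0 for d in const) > n_seeds / 2,
        "linear_majority_ge1": sum(d >= 1 for d in lin) > n_seeds / 2,
    }


def waic_benchmark_study(n_seeds: int = 10, seed0: int = 0, **kw) -> dict:
    """Bootstrap-route vs exact-posterior WAIC agreement over seeds."""
    reports = [validate_waic_on_benchmark(seed0 + s, **kw)
               for s in range(n_seeds)]
    agree = sum(r["orders_agree"] for r in reports)
    close = sum(r["max_rel_diff"] < 0.05 for r in reports)
    return {"n_seeds": n_seeds,
            "order_agreement": agree, "within_5pct": close,
            "order_agreement_majority": agree > n_seeds / 2,
            "within_5pct_majority": close > n_seeds / 2,
            "max_rel_diff": max(r["max_rel_diff"] for r in reports),
            "reports": reports}
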