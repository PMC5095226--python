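"""Readers, writers and run configuration.

Coordinate tables are comma-separated UTF-8 text with columns ``time_h``
and ``x_um`` and a leading comment line carrying the domain length, so a
written file round-trips without extra context.  Nested results are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .likelihood import Observations
from .pde import ParameterSet, TimePolynomial
from .solver import InitialAttractantConfig, Solution

__all__ = [
    "read_observations",
    "write_observations",
    "write_solution",
    "params_to_dict",
    "params_from_dict",
    "RunConfig",
]

_HEADER_KEY = "domain_length_um"


def write_observations(obs: Observations, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_HEADER_KEY}={obs.domain_length:.10g}\n")
        obs.to_frame().to_csv(fh, index=False)


def read_observations(path, domain_length: Optional[float] = None
                      ) -> Observations:
    """Read a coordinate table (columns time_h, x_um; '#' comment header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if domain_length is None:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") and _HEADER_KEY in line:
                    domain_length = float(line.split("=", 1)[1])
                    break
                if not line.startswith("#"):
                    break
    if domain_length is None:
        raise ValueError(f"{path}: no domain length in header; pass "
                         "domain_length explicitly")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    missing = {"time_h", "x_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time_h", "x_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[~np.isfinite(df["time_h"]) | ~np.isfinite(df["x_um"])]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line "
                         f"{int(bad.index[0]) + 3} (non-numeric or missing "
                         "value)")
    df = df.sort_values(["time_h", "x_um"], kind="mergesort")
    return Observations.from_dataframe(df, domain_length)


def write_solution(sol: Solution, path) -> None:
    """Write C and A as delimited matrices with times/nodes header rows."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("times," + ",".join(f"{t:.10g}" for t in sol.times) + "\n")
        fh.write("nodes," + ",".join(f"{x:.10g}" for x in sol.grid.nodes)
                 + "\n")
        for label, mat in (("C", sol.C), ("A", sol.A)):
            for i in range(mat.shape[0]):
                fh.write(f"{label}[{i}]," + ",".join(
                    f"{v:.10g}" for v in mat[i]) + "\n")


# ---------------------------------------------------------------------------
# parameter (de)serialization
# ---------------------------------------------------------------------------

def params_to_dict(p: ParameterSet) -> dict:
    d = {}
    for f in ("alpha", "D_C", "gamma", "eta"):
        poly = getattr(p, f)
        d[f] = {"coefficients": list(poly.coefficients),
                "exponentiate": poly.exponentiate}
    for f in ("D_A", "nu", "K_d", "lam", "C_max", "A0"):
        d[f] = getattr(p, f)
    if isinstance(p.attractant_init, str):
        d["attractant_init"] = p.attractant_init
    else:
        cfg = p.attractant_init
        d["attractant_init"] = {"lower": cfg.lower, "upper": cfg.upper,
                                "midpoint": cfg.midpoint,
                                "steepness": cfg.steepness,
                                "estimate": cfg.estimate}
    return d


def params_from_dict(d: dict) -> ParameterSet:
    kw = {}
    for f in ("alpha", "D_C", "gamma", "eta"):
        poly = d[f]
        kw[f] = TimePolynomial(tuple(poly["coefficients"]),
                               poly["exponentiate"])
    for f in ("D_A", "nu", "K_d", "lam", "C_max", "A0"):
        if f in d:
            kw[f] = d[f]
    ai = d.get("attractant_init", "uniform")
    if isinstance(ai, str):
        kw["attractant_init"] = ai
    else:
        kw["attractant_init"] = InitialAttractantConfig(
            ai["lower"], ai["upper"], ai["midpoint"], ai["steepness"],
            ai.get("estimate", False))
    return ParameterSet(**kw)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    dataset: Optional[str] = None       # path to a coordinate CSV
    scenario: Optional[str] = None      # or a named synthetic scenario
    models: tuple = ("basic",)
    degree: Union[int, str] = 0         # an int or "auto"
    m_bootstrap: int = 100
    seed: int = 0
    n_boxes: int = 100
    optimizer: str = "nelder-mead"
    maxfev: int = 2000
    initial_cells: str = "estimate"
    influx: Optional[str] = None
    output_dir: str = "results"
    bounds: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = (yaml.safe_load(fh) if path.suffix in (".yml", ".yaml")
                   else json.load(fh))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if isinstance(raw.get("models"), list):
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @property
    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
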