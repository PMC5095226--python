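"""Candidate advection-diffusion-reaction models for collective cell movement.

The cell density ``C(x, t)`` obeys

    dC/dt = -d/dx [ a(x,t) C ] + d/dx [ D_C(t) dC/dx ] + nu C,

where the advection coefficient ``a(x, t)`` encodes the directional-movement
hypothesis, ``D_C`` is the cell diffusion coefficient and ``nu`` the cell
division rate.  Six nested candidates are supported:

============================ ==================================================
model                        advection coefficient a(x, t)
============================ ==================================================
``diffusion``                0
``basic``                    alpha(t) * dA/dx
``receptor_saturation``      alpha(t) * d/dx[ A / (K_d + A) ]
``interaction``              receptor_saturation + eta(t)/(1 + lambda C) dC/dx
``overcrowding``             (1 - C/C_max) * receptor_saturation
``full``                     (1 - C/C_max) * occupancy term + interaction term
============================ ==================================================

The attractant ``A(x, t)`` is depleted by the cells (a self-generated
gradient) and diffuses:

    dA/dt = D_A d2A/dx2 - gamma(t) C A.

``alpha``, ``D_C``, ``gamma`` and ``eta`` may vary in time as polynomials;
the first three are exponentiated to keep them positive, while ``eta`` is
signed (negative values mean cell-cell repulsion).

Internal units are micrometres and hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "TimePolynomial",
    "ParameterSet",
    "ModelSpec",
    "MODEL_NAMES",
    "get_model",
    "evaluate_time_polynomial",
    "advection_coefficient",
    "attractant_rhs",
    "reaction_term",
    "receptor_occupancy",
]


@dataclass(frozen=True)
class TimePolynomial:
    """Polynomial in time, optionally exponentiated to enforce positivity.

    Parameters
    ----------
    coefficients
        Ordered coefficients, constant term first (value at ``t=0`` on the
        un-exponentiated scale).
    exponentiate
        If true, the evaluated value is ``exp(polynomial)`` and hence
        strictly positive for all finite ``t``.
    """

    coefficients: tuple
    exponentiate: bool = False

    def __post_init__(self):
        coeffs = tuple(float(c) for c in np.atleast_1d(self.coefficients))
        if len(coeffs) == 0:
            raise ValueError("TimePolynomial needs at least one coefficient")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        value = np.zeros_like(t)
        for c in reversed(self.coefficients):
            value = value * t + c
        if self.exponentiate:
            value = np.exp(value)
        return value if value.ndim else float(value)

    @classmethod
    def constant(cls, value: float, exponentiate: bool = False) -> "TimePolynomial":
        """Degree-0 polynomial taking natural-scale ``value`` at all times."""
        if exponentiate:
            if value <= 0:
                raise ValueError("exponentiated polynomial needs value > 0")
            return cls((math.log(value),), True)
        return cls((float(value),), False)

    def with_degree(self, degree: int) -> "TimePolynomial":
        """Zero-pad or truncate the coefficient tuple to the given degree."""
        coeffs = list(self.coefficients[: degree + 1])
        coeffs += [0.0] * (degree + 1 - len(coeffs))
        return TimePolynomial(tuple(coeffs), self.exponentiate)


def evaluate_time_polynomial(poly: TimePolynomial, t: float) -> float:
    """Evaluate a :class:`TimePolynomial` at time ``t`` (hours)."""
    return poly(t)


# Default sentinel for a spatially uniform initial attractant profile.
UNIFORM = "uniform"


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters for one candidate model.

    alpha : chemotactic responsiveness (um^2/h per unit occupancy-gradient)
    D_C   : cell diffusion coefficient (um^2/h)
    gamma : attractant depletion rate (1/h per unit cell density)
    eta   : cell-cell interaction strength, signed (um^2/h per unit
            density-gradient); negative = repulsion
    D_A   : attractant diffusion coefficient (um^2/h)
    nu    : cell division rate (1/h)
    K_d   : receptor dissociation constant (attractant units)
    lam   : interaction saturation (inverse cell-density units)
    C_max : maximum packing density (cells/um)
    attractant_init : "uniform" or an InitialAttractantConfig (see solver)
    """

    alpha: TimePolynomial = field(
        default_factory=lambda: TimePolynomial((0.0,), True))
    D_C: TimePolynomial = field(
        default_factory=lambda: TimePolynomial((0.0,), True))
    gamma: TimePolynomial = field(
        default_factory=lambda: TimePolynomial((0.0,), True))
    eta: TimePolynomial = field(
        default_factory=lambda: TimePolynomial((0.0,), False))
    D_A: float = 0.0
    nu: float = 0.0
    K_d: float = 1.0
    lam: float = 0.0
    C_max: float = 1.0
    attractant_init: Union[str, object] = UNIFORM
    A0: float = 1.0  # uniform initial attractant level when attractant_init == "uniform"

    def __post_init__(self):
        if self.D_A < 0 or self.nu < 0 or self.K_d < 0 or self.lam < 0:
            raise ValueError("D_A, nu, K_d and lam must be non-negative")
        if self.C_max <= 0:
            raise ValueError("C_max must be positive")
        if not (self.alpha.exponentiate and self.D_C.exponentiate
                and self.gamma.exponentiate):
            raise ValueError("alpha, D_C and gamma must be exponentiated")
        if self.eta.exponentiate:
            raise ValueError("eta is signed and must not be exponentiated")

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model, defined by which advection terms are active."""

    name: str
    advection: bool      # any directional component at all
    occupancy: bool      # respond to receptor occupancy rather than raw A
    interaction: bool    # conspecific density-gradient term
    crowding: bool       # volume-filling damping towards C_max

    @property
    def uses_attractant(self) -> bool:
        return self.advection


_MODELS = {
    "diffusion": ModelSpec("diffusion", False, False, False, False),
    "basic": ModelSpec("basic", True, False, False, False),
    "receptor_saturation": ModelSpec("receptor_saturation", True, True, False, False),
    "interaction": ModelSpec("interaction", True, True, True, False),
    "overcrowding": ModelSpec("overcrowding", True, True, False, True),
    "full": ModelSpec("full", True, True, True, True),
}

MODEL_NAMES = tuple(_MODELS)


def get_model(name: Union[str, ModelSpec]) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None


def receptor_occupancy(A: np.ndarray, K_d: float) -> np.ndarray:
    """Fraction of occupied receptors A/(K_d + A) (single-site equilibrium)."""
    A = np.asarray(A, dtype=float)
    return A / (K_d + A)


def _gradient(f: np.ndarray, dx: float) -> np.ndarray:
    # central differences, one-sided at the boundaries (matches np.gradient)
    return np.gradient(f, dx)


def advection_coefficient(spec, params: ParameterSet, C, A, grid, t: float):
    """Advection velocity field a(x, t) at the box centres.

    Uses the same central-difference stencils as the diagnostic path of the
    solver.  ``C`` and ``A`` must be non-negative fields on ``grid``.
    """
    spec = get_model(spec)
    C = np.asarray(C, dtype=float)
    A = np.asarray(A, dtype=float)
    if C.shape != A.shape or C.shape[0] != grid.n_boxes:
        raise ValueError("C and A must both live on the grid")
    if not spec.advection:
        return np.zeros_like(C)

    alpha = params.alpha(t)
    if spec.occupancy:
        response = alpha * _gradient(receptor_occupancy(A, params.K_d), grid.dx)
    else:
        response = alpha * _gradient(A, grid.dx)

    if spec.crowding:
        if np.max(C) > params.C_max:
            raise ValueError(
                f"C_max={params.C_max} below max cell density {np.max(C):.6g}; "
                "overcrowding advection factor would go negative")
        response = response * (1.0 - C / params.C_max)

    if spec.interaction:
        eta = params.eta(t)
        response = response + (eta / (1.0 + params.lam * C)) * _gradient(C, grid.dx)

    return response


def attractant_rhs(params: ParameterSet, C, A, grid, t: float):
    """dA/dt = D_A d2A/dx2 - gamma(t) C A on the grid (zero-flux edges)."""
    C = np.asarray(C, dtype=float)
    A = np.asarray(A, dtype=float)
    if C.shape != A.shape or C.shape[0] != grid.n_boxes:
        raise ValueError("C and A must both live on the grid")
    Aext = np.concatenate(([A[0]], A, [A[-1]]))  # zero-flux ghost boxes
    lap = (Aext[2:] - 2.0 * A + Aext[:-2]) / grid.dx ** 2
    return params.D_A * lap - params.gamma(t) * np.clip(C, 0.0, None) * A


def reaction_term(nu: float, C) -> np.ndarray:
    """Exponential population growth through cell division: nu * C."""
    if nu < 0:
        raise ValueError("nu must be non-negative")
    return nu * np.asarray(C, dtype=float)
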