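"""Reparameterized dosing regimens and the multiobjective regimen cost.

A regimen is described by three decision variables: the per-treatment dose
``d`` (10^6 c.f.u), the gap ``g`` between treatments (days) and the number of
treatments ``N``.  ``N`` is relaxed to a real number during search; the
executed impulse count is round(N) and the integrality violation |N-round(N)|
is penalized in the cost.  The cost of a regimen is

    J(d, g, N) = w1 * sum_k Tu(k)/tu_norm * dt          (cumulative tumor burden)
               + lam * d * N                            (cumulative dose)
               + wN * |N - round(N)|                    (integer relaxation)
               + wt * Tu(kt)/tu_norm                    (relaxed terminal tumor-free
                                                         constraint)

where ``tu_norm`` is the maximal untreated Tu over the 100-day horizon from
the same initial state, and the stage sum runs over both endpoints k = 0..kt
(rectangle rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _integrate
from .model import (
    DT_DEFAULT,
    KT_DEFAULT,
    ImpulseSchedule,
    IntegrationBlowupError,
    ModelParameters,
    untreated_tumor_max,
)

__all__ = [
    "DosingScheme",
    "SearchBounds",
    "CostWeights",
    "DEFAULT_BOUNDS",
    "EXPANDED_BOUNDS",
    "build_input_signal",
    "evaluate_cost",
    "cumulative_dose",
    "cost_objective",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DosingScheme:
    """Decision vector (d, g, N); N may be fractional during search."""

    d: float          # per-treatment dose, 10^6 c.f.u
    g: float          # gap between treatments, days
    n: float          # number of treatments (real-valued during search)

    def __post_init__(self):
        if self.d < 0:
            raise ValueError(f"dose must be nonnegative, got {self.d}")
        if not self.g > 0:
            raise ValueError(f"gap must be positive, got {self.g}")
        if self.n < 1:
            raise ValueError(f"number of treatments must be >= 1, got {self.n}")

    @property
    def n_executed(self) -> int:
        return _round_half_up(self.n)

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.g, self.n], dtype=float)


@dataclass(frozen=True)
class SearchBounds:
    """Per-variable (lower, upper) box for the regimen search."""

    d: tuple = (2.2, 6.4)
    g: tuple = (5.0, 10.0)
    n: tuple = (3.0, 10.0)

    def __post_init__(self):
        for name in ("d", "g", "n"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.d[0], self.g[0], self.n[0]], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.d[1], self.g[1], self.n[1]], dtype=float)

    def contains(self, point, tol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lower - tol) and np.all(p <= self.upper + tol))


#: clinically constrained box (weekly-scheme doses, 5-10 day gaps, 3-10 treatments)
DEFAULT_BOUNDS = SearchBounds()
#: widened box used to probe whether the constrained optimum is only local
EXPANDED_BOUNDS = SearchBounds(d=(0.0, 50.0), g=(1.0, 20.0), n=(1.0, 20.0))

BOUNDS_PRESETS = {"default": DEFAULT_BOUNDS, "expanded": EXPANDED_BOUNDS}


@dataclass(frozen=True)
class CostWeights:
    """Weights of the multiobjective regimen cost.

    ``tu_norm`` is the normalization constant for Tu (the maximal untreated
    Tu over the horizon) and must be precomputed for the (params, x0) pair
    under study; see :func:`CostWeights.for_model`.
    """

    tu_norm: float
    w1: float = 200.0     # stage (cumulative tumor burden) weight
    lam: float = 1.0      # cumulative-dose penalty weight
    w_n: float = 1e4      # integer-relaxation penalty weight
    w_t: float = 1e5      # terminal tumor-burden weight

    def __post_init__(self):
        if not self.tu_norm > 0:
            raise ValueError("tu_norm must be positive")
        for name in ("w1", "lam", "w_n", "w_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def for_model(cls, params: ModelParameters, x0, kt: int = KT_DEFAULT,
                  dt: float = DT_DEFAULT, **kwargs) -> "CostWeights":
        return cls(tu_norm=untreated_tumor_max(params, x0, kt=kt, dt=dt), **kwargs)


def build_input_signal(scheme: DosingScheme, dt: float = DT_DEFAULT,
                       kt: int = KT_DEFAULT, warn: bool = True) -> ImpulseSchedule:
    """Impulse schedule induced by a regimen: dose d at steps round(n*g/dt).

    Treatments that would fall beyond the horizon are dropped (with a warning
    when ``warn``).
    """
    if scheme.g / dt < 1:
        raise ValueError(
            f"gap {scheme.g} days is below the grid resolution {dt} days"
        )
    n_exec = scheme.n_executed
    indices = np.array(
        [_round_half_up(i * scheme.g / dt) for i in range(n_exec)], dtype=np.int64
    )
    keep = indices <= kt
    if not keep.all():
        if warn:
            warnings.warn(
                f"{int((~keep).sum())} treatment(s) of scheme "
                f"(d={scheme.d}, g={scheme.g}, N={scheme.n}) fall beyond the "
                f"{kt * dt:.0f}-day horizon and were dropped",
                stacklevel=2,
            )
        indices = indices[keep]
    doses = np.full(indices.shape, float(scheme.d))
    return ImpulseSchedule(indices, doses, dt=dt, kt=kt)


def cumulative_dose(scheme: DosingScheme) -> float:
    """Total administered BCG, d*N with the raw (possibly fractional) N."""
    return float(scheme.d * scheme.n)


def evaluate_cost(
    scheme: DosingScheme,
    params: ModelParameters,
    x0,
    weights: CostWeights,
    dt: float = DT_DEFAULT,
    kt: int = KT_DEFAULT,
    breakdown: bool = False,
):
    """Multiobjective cost of a regimen (deterministic; see module docstring).

    With ``breakdown=True`` returns a dict with the stage, dose,
    integer-penalty and terminal contributions alongside the total.
    """
    schedule = build_input_signal(scheme, dt=dt, kt=kt, warn=False)
    x0 = np.asarray(x0, dtype=float)
    tu_sum, tu_final, first_bad = _integrate.tu_cost_terms(
        x0, schedule.dose_array(), params.to_array(), dt
    )
    if first_bad >= 0:
        raise IntegrationBlowupError(first_bad)
    stage = weights.w1 * tu_sum * dt / weights.tu_norm
    dose_term = weights.lam * scheme.d * scheme.n
    integer_term = weights.w_n * abs(scheme.n - scheme.n_executed)
    terminal = weights.w_t * tu_final / weights.tu_norm
    total = stage + dose_term + integer_term + terminal
    if breakdown:
        return {
            "stage": stage,
            "dose": dose_term,
            "integer_penalty": integer_term,
            "terminal": terminal,
            "total": total,
        }
    return total


def cost_objective(
    params: ModelParameters,
    x0,
    weights: Optional[CostWeights] = None,
    dt: float = DT_DEFAULT,
    kt: int = KT_DEFAULT,
) -> Callable[[np.ndarray], float]:
    """Objective f([d, g, N]) -> cost for the metaheuristic optimizers."""
    if weights is None:
        weights = CostWeights.for_model(params, x0, kt=kt, dt=dt)

    def objective(point) -> float:
        d, g, n = np.asarray(point, dtype=float)
        return evaluate_cost(DosingScheme(d, g, n), params, x0, weights, dt=dt, kt=kt)

    return objective
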