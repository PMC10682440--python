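"""Impulsive four-state tumor–immune model of intravesical BCG immunotherapy.

The model tracks BCG concentration ``B`` (10^6 c.f.u), activated effector
cells ``E``, infected tumor cells ``Ti`` and uninfected tumor cells ``Tu``
(each 10^6 cells), in dimensionless units.  Between instillations the states
evolve under

    dB/dt  = -mu1*B - p1*E*B - p2*B*Tu
    dE/dt  = -mu2*E + alpha*Ti + p4*E*B - p5*E*Ti
    dTi/dt = -p3*E*Ti + p2*B*Tu
    dTu/dt = -p2*B*Tu + r*(1 - beta*Tu)*Tu

and each instillation is an impulsive jump ``B <- B + dose``.  The continuous
dynamics are discretized with the classical fourth-order Runge–Kutta scheme on
a fixed grid (default step 0.01 day).  The convention is impulse-then-
integrate: the dose scheduled at grid step k is added to B, the post-impulse
state is stored as row k, and the integrator then advances to step k+1.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import _integrate

__all__ = [
    "ModelParameters",
    "ImpulseSchedule",
    "Trajectory",
    "ode_rhs",
    "rk4_step",
    "apply_impulse",
    "simulate",
    "untreated_tumor_max",
    "settling_time",
    "DT_DEFAULT",
    "HORIZON_DAYS",
    "KT_DEFAULT",
    "X0_DEFAULT",
]

#: global grid step in days, used by every component unless overridden
DT_DEFAULT = 0.01
#: maximal treatment period in days (max gap * max number of treatments)
HORIZON_DAYS = 100.0
#: grid index of the final day at the default step
KT_DEFAULT = 10_000

#: early-stage disease test condition: few effector cells, no infected cells
X0_DEFAULT = np.array([0.1, 0.1, 0.0, 0.8])

STATE_NAMES = ("B", "E", "Ti", "Tu")


class InvalidStateError(ValueError):
    """A state vector contained non-finite entries."""


class IntegrationBlowupError(RuntimeError):
    """The integration produced non-finite values."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration produced non-finite state at grid step {step}")


@dataclass(frozen=True)
class ModelParameters:
    """The ten positive rate constants, in dimensionless working units.

    Defaults are the dimensionless estimates for the human bladder-cancer
    parameterization (cell populations scaled by 10^6).
    """

    mu1: float = 1.0      # BCG decay rate (1/day)
    mu2: float = 0.41     # effector-cell decay rate (1/day)
    p1: float = 1.25      # BCG kill rate by antigen-presenting cells
    p2: float = 0.285     # tumor-cell infection rate by BCG
    p3: float = 1.1       # infected-cell destruction rate by effectors
    p4: float = 0.12      # immune activation rate
    p5: float = 0.003     # effector deactivation rate
    alpha: float = 0.52   # infected-tumor stimulation rate (1/day)
    beta: float = 0.011   # inverse tumor carrying capacity
    r: float = 0.032      # tumor growth rate (1/day)

    def __post_init__(self):
        for name in _integrate.PARAM_ORDER:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _integrate.PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (10,):
            raise ValueError(f"expected 10 parameters, got shape {arr.shape}")
        return cls(**dict(zip(_integrate.PARAM_ORDER, arr.tolist())))

    def as_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in _integrate.PARAM_ORDER}

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ImpulseSchedule:
    """Instillation times (grid indices) and dose magnitudes on a fixed grid."""

    indices: np.ndarray      # strictly increasing grid indices
    doses: np.ndarray        # nonnegative doses, 10^6 c.f.u
    dt: float = DT_DEFAULT   # grid step, days
    kt: int = KT_DEFAULT     # grid index of the final day

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if self.indices.shape != self.doses.shape:
            raise ValueError("indices and doses must have matching shapes")
        if self.indices.size:
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("impulse indices must be strictly increasing")
            if self.indices[0] < 0 or self.indices[-1] > self.kt:
                raise ValueError("impulse indices must lie in [0, kt]")
        if np.any(self.doses < 0):
            raise ValueError("doses must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @classmethod
    def empty(cls, dt: float = DT_DEFAULT, kt: int = KT_DEFAULT) -> "ImpulseSchedule":
        return cls(np.empty(0, dtype=np.int64), np.empty(0), dt=dt, kt=kt)

    @property
    def times(self) -> np.ndarray:
        """Instillation times in days."""
        return self.indices * self.dt

    @property
    def total_dose(self) -> float:
        return float(self.doses.sum())

    def dose_array(self) -> np.ndarray:
        """Dense per-step dose array of length kt+1."""
        dense = np.zeros(self.kt + 1)
        dense[self.indices] = self.doses
        return dense


@dataclass(frozen=True)
class Trajectory:
    """One simulated run: states on the grid plus the applied impulses."""

    dt: float
    states: np.ndarray                 # (kt+1, 4), row k = post-impulse state
    schedule: ImpulseSchedule
    params: ModelParameters
    x0: np.ndarray

    @property
    def kt(self) -> int:
        return self.states.shape[0] - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.shape[0]) * self.dt

    @property
    def tu(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_days", self.times)
        df["dose_applied"] = self.schedule.dose_array()
        return df

    def to_csv(self, path_or_buf) -> None:
        # %.17g round-trips float64 exactly through its decimal representation
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf, params: Optional[ModelParameters] = None) -> "Trajectory":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        states = df[list(STATE_NAMES)].to_numpy()
        dose = df["dose_applied"].to_numpy()
        t = df["time_days"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else DT_DEFAULT
        kt = len(t) - 1
        idx = np.flatnonzero(dose > 0)
        schedule = ImpulseSchedule(idx, dose[idx], dt=dt, kt=kt)
        x0 = states[0].copy()
        x0[0] -= dose[0]  # undo a day-0 impulse to recover the pre-impulse state
        return cls(dt=dt, states=states, schedule=schedule,
                   params=params or ModelParameters(), x0=x0)


def ode_rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivative of ``[B, E, Ti, Tu]`` under the continuous dynamics."""
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"non-finite state {x}")
    out = np.empty(4)
    _integrate.rhs(x, params.to_array(), out)
    return out


def rk4_step(state, params: ModelParameters, dt: float) -> np.ndarray:
    """One classical fourth-order Runge–Kutta step of size ``dt`` days."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    x = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"non-finite state {x}")
    return _integrate.rk4_step(x, params.to_array(), float(dt))


def apply_impulse(state, dose: float) -> np.ndarray:
    """Instillation jump: B increases by ``dose``, other states unchanged."""
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose}")
    x = np.asarray(state, dtype=float).copy()
    x[0] += dose
    return x


def simulate(
    params: ModelParameters,
    x0,
    schedule: Optional[ImpulseSchedule] = None,
    kt: Optional[int] = None,
    dt: Optional[float] = None,
) -> Trajectory:
    """Integrate the impulsive system over the grid.

    ``kt`` and ``dt`` default to the schedule's values (or the global
    defaults for a schedule-free run).  Raises
    :class:`IntegrationBlowupError` naming the first bad step if the state
    becomes non-finite.
    """
    if schedule is None:
        schedule = ImpulseSchedule.empty(dt=dt or DT_DEFAULT, kt=kt or KT_DEFAULT)
    if kt is not None and kt != schedule.kt:
        schedule = ImpulseSchedule(schedule.indices, schedule.doses, dt=schedule.dt, kt=kt)
    if dt is not None and dt != schedule.dt:
        schedule = ImpulseSchedule(schedule.indices, schedule.doses, dt=dt, kt=schedule.kt)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (4,):
        raise ValueError("x0 must have 4 components")
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    states, first_bad = _integrate.integrate_dense(
        x0, schedule.dose_array(), params.to_array(), schedule.dt
    )
    if first_bad >= 0:
        raise IntegrationBlowupError(first_bad)
    return Trajectory(dt=schedule.dt, states=states, schedule=schedule,
                      params=params, x0=x0.copy())


def untreated_tumor_max(
    params: ModelParameters,
    x0,
    kt: int = KT_DEFAULT,
    dt: float = DT_DEFAULT,
) -> float:
    """Maximum of Tu on the zero-input trajectory over the horizon.

    Used as the normalization constant for Tu in the regimen stage and
    terminal costs.
    """
    traj = simulate(params, x0, ImpulseSchedule.empty(dt=dt, kt=kt))
    return float(traj.tu.max())


def settling_time(traj: Trajectory, fraction: float = 0.01) -> Optional[float]:
    """First grid time (days) with Tu below ``fraction`` of its initial value.

    Returns None if the threshold is never crossed.  Reported on the grid
    without interpolation, so the result is quantized to one grid step.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    tu0 = float(traj.tu[0])
    if tu0 <= 0:
        raise ValueError("settling time undefined: initial Tu is zero")
    below = traj.tu < fraction * tu0
    if not below.any():
        return None
    return float(np.argmax(below) * traj.dt)


# -- parameter / initial-state config files ---------------------------------

def save_params_config(path, params: ModelParameters, x0=X0_DEFAULT) -> None:
    """Write a YAML config mirroring the canonical parameter names plus x0."""
    doc = params.as_dict()
    doc["x0"] = [float(v) for v in np.asarray(x0)]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params_config(path) -> tuple[ModelParameters, np.ndarray]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    x0 = np.asarray(doc.pop("x0", X0_DEFAULT), dtype=float)
    return ModelParameters(**doc), x0
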