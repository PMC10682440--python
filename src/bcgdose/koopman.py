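"""Data-driven lifted linear surrogate of the tumor–immune model (EDMD).

The surrogate predicts the full four-state vector from an extended state
built by time-delay embedding of the measured output (uninfected tumor cells,
``Tu``) and past inputs.  With one delay unit, one output and one input the
extended state is the 5-vector

    Z_k = [y_k, y_{k-1}, y_{k-2}, u_{k-1}, u_{k-2}].

The extended state is lifted with thin-plate-spline radial basis functions
psi(r) = r^2 log r centered at k-means centroids of the training extended
states, giving Z_lift = [Z_k, psi(|Z_k - c_1|), ..., psi(|Z_k - c_K|)].
Extended dynamic mode decomposition then solves two least-squares problems:

    Z_lift(k+1) ~ A_lift Z_lift(k) + B_lift u(k)
    X(k)        ~ C_lift Z_lift(k)

via the pseudo-inverse (minimum-norm on rank deficiency; optional ridge).
Multi-step prediction iterates the lifted recursion linearly and projects
each step through C_lift.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from . import _integrate
from .model import (
    DT_DEFAULT,
    HORIZON_DAYS,
    ImpulseSchedule,
    ModelParameters,
)

__all__ = [
    "TrajectoryData",
    "TrainingDataset",
    "KoopmanModel",
    "generate_training_data",
    "extended_states",
    "thin_plate_rbf",
    "lift",
    "fit_centers",
    "fit_koopman",
    "predict",
    "taylor_linearize",
    "simulate_affine",
    "N_DELAYS",
    "EXT_DIM",
]

#: delay units in the embedding
N_DELAYS = 1
#: extended-state dimension: n_y*(n_d+2) + (n_d+1)*n_u with n_y = n_u = 1
EXT_DIM = (N_DELAYS + 2) + (N_DELAYS + 1)


@dataclass
class TrajectoryData:
    """Output, full-state and input sequences of one training run."""

    y: np.ndarray   # (T,)   output Tu(k)
    x: np.ndarray   # (T, 4) full state
    u: np.ndarray   # (T,)   applied impulse at step k (0 between doses)


@dataclass
class TrainingDataset:
    trajectories: list
    dt: float
    seed: Optional[int] = None
    n_resampled: int = 0


def generate_training_data(
    params: ModelParameters,
    n_traj: int = 100,
    horizon_days: float = HORIZON_DAYS,
    dt: float = DT_DEFAULT,
    dose_interval_days: float = 5.0,
    dose_range: tuple = (0.0, 6.4),
    seed: Optional[int] = None,
) -> TrainingDataset:
    """Simulate ``n_traj`` randomized runs covering the operating envelope.

    Initial states draw B, E, Ti ~ U[0, 0.5] and Tu ~ U[0.1, 1]; impulses are
    placed every ``dose_interval_days`` with doses ~ U over ``dose_range``
    (the admissible per-treatment window).  Runs that blow up are resampled
    and counted in ``n_resampled``.
    """
    rng = np.random.default_rng(seed)
    kt = int(round(horizon_days / dt))
    dose_idx = np.arange(0, kt + 1, int(round(dose_interval_days / dt)))
    p_arr = params.to_array()
    trajectories = []
    n_resampled = 0
    while len(trajectories) < n_traj:
        x0 = np.array([
            rng.uniform(0.0, 0.5), rng.uniform(0.0, 0.5),
            rng.uniform(0.0, 0.5), rng.uniform(0.1, 1.0),
        ])
        doses = rng.uniform(dose_range[0], dose_range[1], size=dose_idx.size)
        dense = np.zeros(kt + 1)
        dense[dose_idx] = doses
        states, first_bad = _integrate.integrate_dense(x0, dense, p_arr, dt)
        if first_bad >= 0:
            n_resampled += 1
            continue
        trajectories.append(TrajectoryData(y=states[:, 3].copy(), x=states, u=dense))
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} diverging training run(s)")
    return TrainingDataset(trajectories, dt=dt, seed=seed, n_resampled=n_resampled)


def extended_states(y: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Delay-embedded extended states Z_k for k = n_d+1 .. T-1.

    The first ``N_DELAYS + 1`` steps of a trajectory lack full lag history
    and are dropped.
    """
    if y.shape != u.shape or y.ndim != 1:
        raise ValueError("y and u must be 1-D arrays of equal length")
    if y.size < EXT_DIM:
        raise ValueError("trajectory too short for the delay embedding")
    return np.column_stack([y[2:], y[1:-1], y[:-2], u[1:-1], u[:-2]])


def thin_plate_rbf(z, centers) -> np.ndarray:
    """Thin-plate-spline features psi(r) = r^2 log r, with psi(0) = 0.

    ``z`` may be a single extended state or a batch (m, EXT_DIM); returns
    (n_rbf,) or (m, n_rbf).
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    z2 = np.atleast_2d(z)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    r2 = cdist(z2, centers, metric="sqeuclidean")
    out = np.zeros_like(r2)
    pos = r2 > 0
    # r^2 log r = 0.5 * r^2 log r^2, avoiding the sqrt
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out[0] if single else out


def lift(z, centers: Optional[np.ndarray]) -> np.ndarray:
    """Stack [Z, psi(Z)]; with no centers the lifting is the identity."""
    z = np.asarray(z, dtype=float)
    if centers is None or np.size(centers) == 0:
        return z
    single = z.ndim == 1
    z2 = np.atleast_2d(z)
    feats = thin_plate_rbf(z2, centers)
    out = np.hstack([z2, feats])
    return out[0] if single else out


def fit_centers(dataset: TrainingDataset, k: int = 10, seed: Optional[int] = None,
                max_samples: int = 200_000) -> np.ndarray:
    """K-means centroids of the pooled extended states (seeded, subsampled)."""
    pooled = np.vstack([extended_states(t.y, t.u) for t in dataset.trajectories])
    if k > pooled.shape[0]:
        raise ValueError(f"k={k} exceeds the {pooled.shape[0]} available samples")
    if pooled.shape[0] > max_samples:
        rng = np.random.default_rng(seed)
        pooled = pooled[rng.choice(pooled.shape[0], max_samples, replace=False)]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(pooled)
    return km.cluster_centers_


@dataclass
class KoopmanModel:
    """Fitted lifted linear model (A_lift, B_lift, C_lift) plus its dictionary."""

    a: np.ndarray                    # (L, L) lifted transition
    b: np.ndarray                    # (L,)   lifted input map (single input)
    c: np.ndarray                    # (4, L) projection to the full state
    centers: Optional[np.ndarray]    # (n_rbf, EXT_DIM) RBF centers (or None)
    dt: float = DT_DEFAULT

    @property
    def n_rbf(self) -> int:
        return 0 if self.centers is None else self.centers.shape[0]

    @property
    def lifted_dim(self) -> int:
        return self.a.shape[0]

    def lift(self, z_ext) -> np.ndarray:
        return lift(z_ext, self.centers)

    def save(self, path) -> None:
        doc = {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "centers": None if self.centers is None else self.centers.tolist(),
            "dt": self.dt,
            "ext_dim": EXT_DIM,
            "n_delays": N_DELAYS,
            "layout": "[y_k, y_k-1, y_k-2, u_k-1, u_k-2]",
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "KoopmanModel":
        with open(path) as fh:
            doc = json.load(fh)
        centers = doc["centers"]
        return cls(
            a=np.asarray(doc["a"]), b=np.asarray(doc["b"]), c=np.asarray(doc["c"]),
            centers=None if centers is None else np.asarray(centers),
            dt=doc.get("dt", DT_DEFAULT),
        )


def _training_arrays(dataset: TrainingDataset, centers):
    z_now, z_next, u_now, x_now = [], [], [], []
    for t in dataset.trajectories:
        z = extended_states(t.y, t.u)        # rows k = 2 .. T-1
        z_now.append(z[:-1])                 # k = 2 .. T-2
        z_next.append(z[1:])                 # k+1
        u_now.append(t.u[2:-1])
        x_now.append(t.x[2:-1])
    z_now = np.vstack(z_now)
    z_next = np.vstack(z_next)
    u_now = np.concatenate(u_now)
    x_now = np.vstack(x_now)
    return lift(z_now, centers), lift(z_next, centers), u_now, x_now


def fit_koopman(dataset: TrainingDataset, centers=None, ridge: float = 0.0) -> KoopmanModel:
    """EDMD least-squares fit of (A_lift, B_lift) and the projection C_lift.

    Minimizes the Frobenius residuals || Z_lift(k+1) - [A B][Z_lift(k); u(k)] ||_F
    and || X(k) - C Z_lift(k) ||_F via pseudo-inverse (minimum-norm solution on
    rank deficiency, with a warning); ``ridge > 0`` switches to a Tikhonov-
    regularized solve for conditioning.
    """
    zl, zl1, u, x = _training_arrays(dataset, centers)
    regressor = np.hstack([zl, u[:, None]])          # (m, L+1)

    def solve(reg, target):
        if ridge > 0:
            gram = reg.T @ reg + ridge * np.eye(reg.shape[1])
            return np.linalg.solve(gram, reg.T @ target)
        theta, _, rank, _ = np.linalg.lstsq(reg, target, rcond=None)
        if rank < reg.shape[1]:
            warnings.warn(
                f"rank-deficient regressor (rank {rank} < {reg.shape[1]}); "
                "returning the minimum-norm solution"
            )
        return theta

    theta_ab = solve(regressor, zl1)                 # (L+1, L)
    a = theta_ab[:-1].T
    b = theta_ab[-1]
    theta_c = solve(zl, x)                           # (L, 4)
    c = theta_c.T
    return KoopmanModel(a=a, b=b, c=c,
                        centers=None if centers is None else np.asarray(centers),
                        dt=dataset.dt)


def predict(model: KoopmanModel, z0_ext, inputs, steps: Optional[int] = None) -> np.ndarray:
    """Roll the lifted recursion forward and project each step to X-hat.

    Returns (steps+1, 4): row 0 is the projection of the initial lifted state,
    row i the prediction after i steps driven by ``inputs[0..i-1]``.
    """
    inputs = np.asarray(inputs, dtype=float)
    if steps is None:
        steps = inputs.size
    if inputs.size < steps:
        raise ValueError("fewer inputs than prediction steps")
    zl = model.lift(np.asarray(z0_ext, dtype=float))
    out = np.empty((steps + 1, 4))
    out[0] = model.c @ zl
    for i in range(steps):
        zl = model.a @ zl + model.b * inputs[i]
        out[i + 1] = model.c @ zl
    return out


def taylor_linearize(params: ModelParameters, x_op) -> tuple[np.ndarray, np.ndarray]:
    """First-order Taylor model at an operating point: dx/dt ~ J x + b.

    Returns the analytic Jacobian J of the continuous dynamics at ``x_op``
    and the affine offset b = f(x_op) - J x_op.
    """
    x = np.asarray(x_op, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("operating point must be finite")
    bb, e, ti, tu = x
    p = params
    jac = np.array([
        [-p.mu1 - p.p1 * e - p.p2 * tu, -p.p1 * bb, 0.0, -p.p2 * bb],
        [p.p4 * e, -p.mu2 + p.p4 * bb - p.p5 * ti, p.alpha - p.p5 * e, 0.0],
        [p.p2 * tu, -p.p3 * ti, -p.p3 * e, p.p2 * bb],
        [-p.p2 * tu, 0.0, 0.0, -p.p2 * bb + p.r - 2.0 * p.r * p.beta * tu],
    ])
    f0 = np.empty(4)
    _integrate.rhs(x, params.to_array(), f0)
    return jac, f0 - jac @ x


def simulate_affine(jac: np.ndarray, offset: np.ndarray, x0,
                    schedule: ImpulseSchedule) -> np.ndarray:
    """Integrate the affine Taylor model with the same RK4 step and impulse
    convention as the nonlinear simulator (for a fair comparison).

    For an affine system the RK4 step is exactly the degree-4 truncation of
    the matrix exponential of the augmented system, precomputed once.
    """
    aug = np.zeros((5, 5))
    aug[:4, :4] = jac
    aug[:4, 4] = offset
    h = schedule.dt
    step = np.eye(5)
    term = np.eye(5)
    for i in range(1, 5):
        term = term @ (aug * h) / i
        step = step + term
    m, cvec = step[:4, :4], step[:4, 4]
    dose = schedule.dose_array()
    kt = dose.size - 1
    out = np.empty((kt + 1, 4))
    x = np.asarray(x0, dtype=float).copy()
    for k in range(kt + 1):
        x[0] += dose[k]
        out[k] = x
        if k < kt:
            x = m @ x + cvec
    return out
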