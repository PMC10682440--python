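"""Receding-horizon impulsive dosing on the lifted linear surrogate.

At every control interval (default 5 days) the controller lifts the measured
output/input history, predicts over the horizon with the Koopman model,
solves a box-constrained convex QP for the next impulse and applies it to the
*nonlinear* plant.  The tracking reference decays exponentially from the
initial tumor load, y_r(t) = Tu(0) * exp(-t).  The terminal weight is the
solution of a discrete-time algebraic Riccati equation posed in lifted
coordinates with Q_lift = C' Q C (the stage weight pulled back through the
projection), so that the Riccati equation is well-posed on (A_lift, B_lift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from . import _integrate
from .model import (
    DT_DEFAULT,
    HORIZON_DAYS,
    ImpulseSchedule,
    IntegrationBlowupError,
    ModelParameters,
    Trajectory,
)
from .koopman import EXT_DIM, KoopmanModel

__all__ = [
    "MPCConfig",
    "QPProblem",
    "solve_dare",
    "build_prediction",
    "build_qp",
    "solve_qp",
    "kkt_residual",
    "run_receding_horizon",
]


@dataclass
class MPCConfig:
    horizon_days: float = 5.0             # prediction horizon Hp
    control_interval_days: float = 5.0    # days between allowed impulses
    n_moves: int = 1                      # free moves per solve (control horizon)
    q_diag: tuple = (0.0, 0.0, 0.0, 1000.0)   # state-error weight diag(Q)
    r_weight: float = 0.1                 # input weight R
    u_min: float = 0.0                    # per-treatment dose bounds
    u_max: float = 6.4
    ref_decay: float = 1.0                # 1/day decay rate of the Tu reference
    x_min: Optional[tuple] = None         # optional state box (per state)
    x_max: Optional[tuple] = None

    def __post_init__(self):
        if self.u_min > self.u_max:
            raise ValueError("u_min must not exceed u_max")
        if any(q < 0 for q in self.q_diag) or self.r_weight < 0:
            raise ValueError("Q and R must be positive semidefinite")
        if self.n_moves < 1:
            raise ValueError("need at least one free move per solve")


def solve_dare(a, b, q, r, max_iter: int = 10_000, tol: float = 1e-10) -> np.ndarray:
    """Solve P = A'PA - (A'PB)(B'PB+R)^{-1}(B'PA) + Q for PSD P.

    Tries the direct scipy solver first, then falls back to fixed-point
    Riccati iteration.  Raises with the residual if neither converges to a
    Frobenius residual below 1e-8.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.asarray(b, dtype=float)
    if b.ndim == 0:
        b = b.reshape(1, 1)
    elif b.ndim == 1:
        b = b[:, None]
    q = np.atleast_2d(np.asarray(q, dtype=float))
    r = np.atleast_2d(np.asarray(r, dtype=float))

    def residual(p):
        gain = np.linalg.solve(b.T @ p @ b + r, b.T @ p @ a)
        return np.linalg.norm(a.T @ p @ a - a.T @ p @ b @ gain + q - p)

    p = None
    try:
        p = scipy.linalg.solve_discrete_are(a, b, q, r)
        if residual(p) >= 1e-8:
            p = None
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        p = None
    if p is None:
        p = q.copy()
        for _ in range(max_iter):
            gain = np.linalg.solve(b.T @ p @ b + r, b.T @ p @ a)
            p_next = a.T @ p @ a - a.T @ p @ b @ gain + q
            p_next = 0.5 * (p_next + p_next.T)
            if np.linalg.norm(p_next - p) < tol * max(1.0, np.linalg.norm(p)):
                p = p_next
                break
            p = p_next
        res = residual(p)
        if res >= 1e-8:
            raise RuntimeError(
                f"Riccati solve did not converge: residual {res:.3e} >= 1e-8"
            )
    return 0.5 * (p + p.T)


def build_prediction(model: KoopmanModel, hp_steps: int,
                     control_interval_steps: int, n_moves: int = 1):
    """Stacked prediction matrices (W, G) for the lifted linear model.

    W stacks A^i (i = 1..hp) so the free response is W z0; G is the stacked
    impulse-response matrix with one column per horizon step, where only the
    columns of the allowed move steps (0, ci, 2*ci, ...) are nonzero — doses
    are impulsive, every other input is zero.
    """
    if hp_steps < 1:
        raise ValueError("prediction horizon must cover at least one step")
    if (n_moves - 1) * control_interval_steps >= hp_steps:
        raise ValueError("horizon shorter than the span of the requested moves")
    nz = model.lifted_dim
    move_steps = [m * control_interval_steps for m in range(n_moves)]
    w = np.empty((hp_steps * nz, nz))
    g = np.zeros((hp_steps * nz, hp_steps))
    a_pow = np.eye(nz)
    # h[s] tracks A^{i-s-1} b for each move column s as i grows
    h = {s: None for s in move_steps}
    for i in range(1, hp_steps + 1):
        a_pow = model.a @ a_pow
        rows = slice((i - 1) * nz, i * nz)
        w[rows] = a_pow
        for s in move_steps:
            if i == s + 1:
                h[s] = model.b.copy()
            elif i > s + 1:
                h[s] = model.a @ h[s]
            if h[s] is not None:
                g[rows, s] = h[s]
    return w, g


@dataclass
class QPProblem:
    """min u' H u + 2 f' u  subject to  A_ineq u <= b_ineq."""

    h: np.ndarray
    f: np.ndarray
    a_ineq: np.ndarray
    b_ineq: np.ndarray
    move_steps: tuple = ()

    def __post_init__(self):
        if not np.allclose(self.h, self.h.T, atol=1e-8):
            raise ValueError("QP Hessian must be symmetric")


def build_qp(model: KoopmanModel, config: MPCConfig, z_lift, ref_tu,
             p_term: np.ndarray, dt: float = DT_DEFAULT) -> QPProblem:
    """Condense the tracking MPC over the horizon into a small dense QP.

    ``ref_tu`` gives the Tu-channel reference at horizon steps 1..Hp; other
    channels are referenced at zero (their Q weights are zero by default).
    The decision variables are the free moves only; between moves the input
    is identically zero, so zero columns are eliminated rather than carried.
    """
    hp = int(round(config.horizon_days / dt))
    ci = int(round(config.control_interval_days / dt))
    if hp < 1 or (config.n_moves - 1) * ci >= hp:
        raise ValueError("horizon shorter than the span of the requested moves")
    ref_tu = np.asarray(ref_tu, dtype=float)
    if ref_tu.size < hp:
        raise ValueError("reference must cover the prediction horizon")
    q = np.diag(config.q_diag)
    move_steps = tuple(m * ci for m in range(config.n_moves))
    m = len(move_steps)

    z = np.asarray(z_lift, dtype=float)
    h_mat = np.full((m, m), config.r_weight * 0.0)
    np.fill_diagonal(h_mat, config.r_weight)
    f_vec = np.zeros(m)
    # impulse responses per move column, advanced jointly with the free response
    resp = [np.zeros_like(model.b) for _ in range(m)]
    z_free = z.copy()
    for i in range(1, hp + 1):
        z_free = model.a @ z_free
        for j, s in enumerate(move_steps):
            if i == s + 1:
                resp[j] = model.b.copy()
            elif i > s + 1:
                resp[j] = model.a @ resp[j]
        if i < hp:
            ref = np.array([0.0, 0.0, 0.0, ref_tu[i - 1]])
            err_free = model.c @ z_free - ref
            cg = [model.c @ resp[j] for j in range(m)]
            for j in range(m):
                f_vec[j] += cg[j] @ q @ err_free
                for l in range(j, m):
                    h_mat[j, l] += cg[j] @ q @ cg[l]
        else:
            for j in range(m):
                f_vec[j] += resp[j] @ p_term @ z_free
                for l in range(j, m):
                    h_mat[j, l] += resp[j] @ p_term @ resp[l]
    h_mat = np.triu(h_mat) + np.triu(h_mat, 1).T

    a_ineq = np.vstack([np.eye(m), -np.eye(m)])
    b_ineq = np.concatenate([np.full(m, config.u_max), np.full(m, -config.u_min)])
    return QPProblem(h=h_mat, f=f_vec, a_ineq=a_ineq, b_ineq=b_ineq,
                     move_steps=move_steps)


def kkt_residual(qp: QPProblem, u: np.ndarray, lam: np.ndarray) -> float:
    """Max violation of stationarity, feasibility and complementarity."""
    u = np.atleast_1d(u)
    lam = np.atleast_1d(lam)
    stat = np.abs(2 * qp.h @ u + 2 * qp.f + qp.a_ineq.T @ lam).max() if u.size else 0.0
    slack = qp.a_ineq @ u - qp.b_ineq
    feas = max(slack.max(initial=0.0), 0.0)
    dual = max((-lam).max(initial=0.0), 0.0)
    comp = np.abs(lam * slack).max(initial=0.0)
    return float(max(stat, feas, dual, comp))


def solve_qp(qp: QPProblem, max_iter: int = 200, tol: float = 1e-10):
    """Dense primal active-set solver for min u'Hu + 2f'u, A u <= b.

    Requires a strictly convex Hessian on the feasible set (R > 0 gives H
    positive definite here).  Returns ``(u, lam)``; the multipliers allow a
    KKT residual check.  Raises on infeasible constraints.
    """
    h = 2.0 * qp.h  # internal standard form: min 1/2 u'Hu + g'u
    g = 2.0 * qp.f
    a, b = qp.a_ineq, qp.b_ineq
    m, n = a.shape

    # feasible start: try 0, then a Chebyshev-style LP
    u = np.zeros(n)
    if np.any(a @ u > b + 1e-12):
        from scipy.optimize import linprog
        lp = linprog(np.zeros(n), A_ub=a, b_ub=b, bounds=[(None, None)] * n,
                     method="highs")
        if not lp.success:
            raise RuntimeError("QP infeasible: no point satisfies the constraints")
        u = lp.x
    working = list(np.flatnonzero(np.abs(a @ u - b) <= 1e-10))

    for _ in range(max_iter):
        aw = a[working] if working else np.zeros((0, n))
        kkt = np.block([
            [h, aw.T],
            [aw, np.zeros((len(working), len(working)))],
        ])
        rhs = np.concatenate([-(h @ u + g), np.zeros(len(working))])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        p, lam_w = sol[:n], sol[n:]
        if np.linalg.norm(p) <= tol:
            if len(working) == 0 or np.all(lam_w >= -tol):
                lam = np.zeros(m)
                lam[working] = np.maximum(lam_w, 0.0)
                return u, lam
            working.pop(int(np.argmin(lam_w)))
            continue
        ap = a @ p
        mask = ap > tol
        mask[working] = False
        if mask.any():
            ratios = (b[mask] - a[mask] @ u) / ap[mask]
            alpha = min(1.0, ratios.min())
        else:
            alpha = 1.0
        u = u + alpha * p
        if alpha < 1.0:
            blocking = np.flatnonzero(mask)[int(np.argmin(ratios))]
            working.append(int(blocking))
    raise RuntimeError("active-set QP did not converge")


def run_receding_horizon(
    params: ModelParameters,
    x0,
    model: KoopmanModel,
    config: Optional[MPCConfig] = None,
    horizon_days: float = HORIZON_DAYS,
    dt: float = DT_DEFAULT,
) -> tuple[Trajectory, np.ndarray]:
    """Closed-loop impulsive MPC applied to the nonlinear plant.

    Returns the plant trajectory and the applied dose sequence (one entry per
    control interval).  The measured history before t=0 is padded with the
    initial output and zero inputs.  A DARE failure falls back to the lifted
    stage weight as terminal cost, with a warning.
    """
    cfg = config or MPCConfig()
    x0 = np.asarray(x0, dtype=float)
    kt = int(round(horizon_days / dt))
    ci = int(round(cfg.control_interval_days / dt))
    if ci < 1:
        raise ValueError("control interval below the grid resolution")
    q_lift = model.c.T @ np.diag(cfg.q_diag) @ model.c
    try:
        p_term = solve_dare(model.a, model.b, q_lift, np.atleast_2d(cfg.r_weight))
    except RuntimeError as exc:
        warnings.warn(f"terminal DARE failed ({exc}); using the lifted stage weight")
        p_term = q_lift

    p_arr = params.to_array()
    tu0 = float(x0[3])
    states = np.empty((kt + 1, 4))
    y_grid = np.empty(kt + 1)
    u_grid = np.zeros(kt + 1)
    move_indices = []
    move_doses = []

    x = x0.copy()
    k = 0
    while True:
        # measurement history for the delay embedding (pad before t=0)
        y_k = x[3]
        y_1 = y_grid[k - 1] if k >= 1 else tu0
        y_2 = y_grid[k - 2] if k >= 2 else tu0
        u_1 = u_grid[k - 1] if k >= 1 else 0.0
        u_2 = u_grid[k - 2] if k >= 2 else 0.0
        z_lift = model.lift(np.array([y_k, y_1, y_2, u_1, u_2]))
        hp = int(round(cfg.horizon_days / dt))
        t_now = k * dt
        ref = tu0 * np.exp(-cfg.ref_decay * (t_now + dt * np.arange(1, hp + 1)))
        qp = build_qp(model, cfg, z_lift, ref, p_term, dt=dt)
        try:
            u_opt, _lam = solve_qp(qp)
        except RuntimeError as exc:
            raise RuntimeError(f"QP failed at grid step {k}: {exc}") from exc
        dose = float(np.clip(u_opt[0], cfg.u_min, cfg.u_max))
        x[0] += dose
        u_grid[k] = dose
        move_indices.append(k)
        move_doses.append(dose)

        # advance the nonlinear plant to the next move (or the horizon end)
        seg_end = min(k + ci, kt)
        seg_dose = np.zeros(seg_end - k + 1)
        seg, first_bad = _integrate.integrate_dense(x, seg_dose, p_arr, dt)
        if first_bad >= 0:
            raise IntegrationBlowupError(k + first_bad)
        states[k:seg_end + 1] = seg
        y_grid[k:seg_end + 1] = seg[:, 3]
        x = seg[-1].copy()
        if seg_end >= kt:
            break
        k = seg_end

    move_indices = np.asarray(move_indices, dtype=np.int64)
    move_doses = np.asarray(move_doses)
    applied = move_doses > 0
    schedule = ImpulseSchedule(move_indices[applied], move_doses[applied],
                               dt=dt, kt=kt)
    traj = Trajectory(dt=dt, states=states, schedule=schedule, params=params,
                      x0=x0.copy())
    return traj, move_doses
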