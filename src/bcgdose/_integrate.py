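"""Compiled Runge–Kutta kernels for the impulsive tumor–immune model.

The public API lives in :mod:`bcgdose.model`; these kernels exist so that the
Monte-Carlo and variance-based analyses (tens of thousands of 10^4-step
simulations) run in seconds.  Parameters are passed as a flat float64 array in
the order ``(mu1, mu2, p1, p2, p3, p4, p5, alpha, beta, r)``; doses as a dense
per-step array aligned to the time grid (entry k = impulse applied at step k).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: index layout of the flat parameter vector
PARAM_ORDER = ("mu1", "mu2", "p1", "p2", "p3", "p4", "p5", "alpha", "beta", "r")


@njit(cache=True)
def rhs(x, p, out):
    b, e, ti, tu = x[0], x[1], x[2], x[3]
    mu1, mu2, p1, p2, p3, p4, p5, alpha, beta, r = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
    )
    out[0] = -mu1 * b - p1 * e * b - p2 * b * tu
    out[1] = -mu2 * e + alpha * ti + p4 * e * b - p5 * e * ti
    out[2] = -p3 * e * ti + p2 * b * tu
    out[3] = -p2 * b * tu + r * (1.0 - beta * tu) * tu


@njit(cache=True)
def rk4_step(x, p, dt):
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    tmp = np.empty(4)
    rhs(x, p, k1)
    for i in range(4):
        tmp[i] = x[i] + 0.5 * dt * k1[i]
    rhs(tmp, p, k2)
    for i in range(4):
        tmp[i] = x[i] + 0.5 * dt * k2[i]
    rhs(tmp, p, k3)
    for i in range(4):
        tmp[i] = x[i] + dt * k3[i]
    rhs(tmp, p, k4)
    out = np.empty(4)
    for i in range(4):
        out[i] = x[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return out


@njit(cache=True)
def integrate_dense(x0, dose, p, dt):
    """Impulse-then-integrate over the full grid, storing every state.

    Returns ``(states, first_bad)`` where ``states`` has shape (kt+1, 4) with
    row k the post-impulse state at step k, and ``first_bad`` is the index of
    the first non-finite row (-1 if the run stayed finite).
    """
    kt = dose.shape[0] - 1
    states = np.empty((kt + 1, 4))
    x = x0.copy()
    first_bad = -1
    for k in range(kt + 1):
        x[0] += dose[k]
        for i in range(4):
            states[k, i] = x[i]
        if first_bad < 0 and not (
            np.isfinite(x[0]) and np.isfinite(x[1])
            and np.isfinite(x[2]) and np.isfinite(x[3])
        ):
            first_bad = k
            break
        if k < kt:
            x = rk4_step(x, p, dt)
    return states, first_bad


@njit(cache=True)
def tu_cost_terms(x0, dose, p, dt):
    """Accumulate the uninfected-tumor terms of the regimen cost.

    Returns ``(tu_sum, tu_final, first_bad)`` with ``tu_sum`` = sum of Tu(k)
    over k = 0..kt (rectangle rule, both endpoints) and ``tu_final`` = Tu(kt).
    Avoids materialising the trajectory.
    """
    kt = dose.shape[0] - 1
    x = x0.copy()
    tu_sum = 0.0
    for k in range(kt + 1):
        x[0] += dose[k]
        if not (
            np.isfinite(x[0]) and np.isfinite(x[1])
            and np.isfinite(x[2]) and np.isfinite(x[3])
        ):
            return np.nan, np.nan, k
        tu_sum += x[3]
        if k < kt:
            x = rk4_step(x, p, dt)
    return tu_sum, x[3], -1


@njit(cache=True)
def settling_step(x0, dose, p, dt, threshold):
    """First grid step with Tu below ``threshold`` (early exit).

    Returns the step index, -1 if the threshold is never crossed within the
    horizon, or -2 if the integration produced non-finite values first.
    """
    kt = dose.shape[0] - 1
    x = x0.copy()
    for k in range(kt + 1):
        x[0] += dose[k]
        if not (
            np.isfinite(x[0]) and np.isfinite(x[1])
            and np.isfinite(x[2]) and np.isfinite(x[3])
        ):
            return -2
        if x[3] < threshold:
            return k
        if k < kt:
            x = rk4_step(x, p, dt)
    return -1
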