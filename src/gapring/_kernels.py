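"""Numba fixed-step RK4 kernel for the gap-coupled network.

External input (stimulus + frozen noise) is piecewise constant on the noise
clock; the kernel advances an integer number of RK4 steps inside each hold
interval so the solved system is exactly piecewise-smooth.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# packed cell-parameter vector layout
_P_FAST_AMP = 0
_P_TAU_M = 1
_P_G_SLOW = 2
_P_W_FLOOR = 3
_P_THETA_SLOW = 4
_P_K_SLOW = 5
_P_TAU_W_MIN = 6
_P_TAU_W_MAX = 7
_P_THETA_TW = 8
_P_K_TW = 9
_P_V_MID = 10
_P_V_SCALE = 11


def pack_params(cell) -> np.ndarray:
    return np.array([
        cell.fast_amplitude, cell.tau_m, cell.g_slow, cell.w_floor,
        cell.theta_slow, cell.k_slow, cell.tau_w_min, cell.tau_w_max,
        cell.theta_tw, cell.k_tw, cell.v_mid, cell.v_scale,
    ], dtype=np.float64)


@njit(cache=True)
def _deriv(V, W, Iin, A, deg, gnc, p, dV, dW):
    n = V.shape[0]
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if A[i, j]:
                acc += V[j]
        iel = gnc[i] * (acc - deg[i] * V[i])
        v = V[i]
        u = (v - p[_P_V_MID]) / p[_P_V_SCALE]
        ifast = p[_P_FAST_AMP] * (u * u * u / 3.0 - u)
        dV[i] = (-ifast - W[i] + iel + Iin[i]) / p[_P_TAU_M]
        winf = p[_P_W_FLOOR] + p[_P_G_SLOW] / (
            1.0 + np.exp(-(u - p[_P_THETA_SLOW]) / p[_P_K_SLOW]))
        tw = p[_P_TAU_W_MAX] + (p[_P_TAU_W_MIN] - p[_P_TAU_W_MAX]) / (
            1.0 + np.exp(-(u - p[_P_THETA_TW]) / p[_P_K_TW]))
        dW[i] = (winf - W[i]) / tw


@njit(cache=True)
def rk4_piecewise(V0, W0, A, deg, gnc, inputs, steps_per_hold, h, p):
    """Integrate over ``inputs.shape[0]`` hold intervals, recording each step.

    Returns (Vrec, Wrec) of shape (n_steps + 1, N) including the initial
    state.
    """
    n_holds = inputs.shape[0]
    n = V0.shape[0]
    n_steps = n_holds * steps_per_hold
    Vrec = np.empty((n_steps + 1, n))
    Wrec = np.empty((n_steps + 1, n))
    V = V0.copy()
    W = W0.copy()
    Vrec[0] = V
    Wrec[0] = W
    k1v = np.empty(n); k1w = np.empty(n)
    k2v = np.empty(n); k2w = np.empty(n)
    k3v = np.empty(n); k3w = np.empty(n)
    k4v = np.empty(n); k4w = np.empty(n)
    tv = np.empty(n); tw_ = np.empty(n)
    idx = 1
    for hold in range(n_holds):
        Iin = inputs[hold]
        for _ in range(steps_per_hold):
            _deriv(V, W, Iin, A, deg, gnc, p, k1v, k1w)
            for i in range(n):
                tv[i] = V[i] + 0.5 * h * k1v[i]
                tw_[i] = W[i] + 0.5 * h * k1w[i]
            _deriv(tv, tw_, Iin, A, deg, gnc, p, k2v, k2w)
            for i in range(n):
                tv[i] = V[i] + 0.5 * h * k2v[i]
                tw_[i] = W[i] + 0.5 * h * k2w[i]
            _deriv(tv, tw_, Iin, A, deg, gnc, p, k3v, k3w)
            for i in range(n):
                tv[i] = V[i] + h * k3v[i]
                tw_[i] = W[i] + h * k3w[i]
            _deriv(tv, tw_, Iin, A, deg, gnc, p, k4v, k4w)
            for i in range(n):
                V[i] += h / 6.0 * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])
                W[i] += h / 6.0 * (k1w[i] + 2.0 * k2w[i] + 2.0 * k3w[i] + k4w[i])
            Vrec[idx] = V
            Wrec[idx] = W
            idx += 1
    return Vrec, Wrec
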