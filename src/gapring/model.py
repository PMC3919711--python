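"""Cell and network right-hand sides.

The cell is a dimensionless two-variable relaxation oscillator,

    tau_m * dV/dt = -I_fast(V) - W + I_el + I_in      (voltage equation)
    dW/dt        = (W_inf(V) - W) / tau_w(V)          (slow recovery current)

with an N-shaped instantaneous current I_fast, a sigmoidal slow activation
W_inf scaled by g_slow, and a voltage-dependent slow time constant tau_w that
interpolates between tau_w_min (depolarized) and tau_w_max (hyperpolarized)
through the logistic function s(x) = 1/(1+e^x).  Gap-junction coupling passes
ohmic current proportional to the voltage difference between connected cells,
normalised so the total electrical conductance per cell is g_el regardless of
how many neighbours it is split over.
"""
from __future__ import annotations

import numpy as np

from .params import CellParams, SynParams


def sigmoid_s(x):
    """The logistic s(x) = 1/(1+e^x), decreasing in x."""
    return 1.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0)))


def fast_current(V, p: CellParams):
    """Instantaneous N-shaped fast current.

    ``I_fast(V) = g_fast * fast_shape * (u**3/3 - u)`` with
    ``u = (V - v_mid)/v_scale``.  As a function of V it has exactly two
    interior turning points (at ``V = v_mid -+ v_scale``), so the V-nullcline
    ``W = -I_fast(V) + I`` is cubic-like and shifts additively in W with the
    applied current I.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    u = (V - p.v_mid) / p.v_scale
    return p.fast_amplitude * (u**3 / 3.0 - u)


def slow_activation(V, p: CellParams):
    """Steady-state level W_inf(V) of the slow recovery current (W-nullcline).

    ``W_inf = w_floor + g_slow * s(-(u - theta_slow)/k_slow)`` with the
    normalized voltage ``u = (V - v_mid)/v_scale``: a steep sigmoid rising
    with depolarization from ``w_floor`` (placed just below the left knee of
    the free V-nullcline) to ``w_floor + g_slow``.
    """
    V = np.asarray(V, dtype=float)
    u = (V - p.v_mid) / p.v_scale
    return p.w_floor + p.g_slow * sigmoid_s(-(u - p.theta_slow) / p.k_slow)


def tau_w(V, p: CellParams):
    """Voltage-dependent time constant of the slow current.

    Sigmoidal interpolation between ``tau_w_max`` (hyperpolarized) and
    ``tau_w_min`` (depolarized) with midpoint ``theta_tw`` and rate ``k_tw``
    acting on the normalized voltage ``u = (V - v_mid)/v_scale``, oriented so
    the active phase uses the small constant and the duty cycle is short.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    u = (V - p.v_mid) / p.v_scale
    frac = sigmoid_s(-(u - p.theta_tw) / p.k_tw)  # 0 hyperpol -> 1 depol
    return p.tau_w_max + (p.tau_w_min - p.tau_w_max) * frac


def gap_current(i: int, V, adjacency, g_el: float, n_cc: int):
    """Gap-junction current into cell ``i``.

    ``I_el(i) = (g_el / N_cc) * sum_{j in nbr(i)} (V_j - V_i)`` where the
    adjacency already contains the extra antipodal connection used for
    all-to-all coupling, so the per-cell total conductance is g_el for every
    connectivity.
    """
    V = np.asarray(V, dtype=float)
    A = np.asarray(adjacency)
    n = V.shape[0]
    if not (0 <= i < n):
        raise IndexError(f"cell index {i} out of range for N={n}")
    if A.shape != (n, n):
        raise ValueError("adjacency shape does not match potential vector")
    nbr = A[i] != 0
    return g_el / n_cc * float(np.sum(V[nbr] - V[i]))


def gap_current_all(V, adjacency, g_el: float, n_cc: int, divisor=None):
    """Vector of gap currents for all cells (dense-matrix evaluation).

    ``divisor`` overrides the per-cell conductance divisor (default
    ``n_cc``); a renormalized chain passes each cell's own degree so edge
    cells keep a full g_el total.
    """
    V = np.asarray(V, dtype=float)
    A = np.asarray(adjacency, dtype=float)
    deg = A.sum(axis=1)
    div = float(n_cc) if divisor is None else np.asarray(divisor, dtype=float)
    return g_el / div * (A @ V - deg * V)


def syn_current(V_pre, V_post, sp: SynParams = SynParams()):
    """Graded synaptic current, outward-positive convention.

    ``I_syn = g_syn * s(-(V_pre - theta_syn)/k_syn) * (E_syn - V_post)``.
    The activation gate opens sigmoidally when the presynaptic cell
    depolarizes past ``theta_syn``.  The voltage equation subtracts this
    current, so with the default reversal far below the working voltage range
    a saturated synapse depolarizes the postsynaptic cell.
    """
    V_pre = np.asarray(V_pre, dtype=float)
    V_post = np.asarray(V_post, dtype=float)
    gate = sigmoid_s(-(V_pre - sp.theta_syn) / sp.k_syn)
    return sp.g_syn * gate * (sp.E_syn - V_post)


def network_rhs(t, state, net, cell: CellParams, inputs=None,
                syn: SynParams | None = None):
    """Full network right-hand side as a pure function.

    Parameters
    ----------
    t : float
        Time (used only to evaluate ``inputs``).
    state : ndarray, shape (2N,)
        Flat state ``[V_1..V_N, W_1..W_N]``.
    net : NetworkSpec
        Connectivity; ``net.adjacency`` is the symmetric 0/1 matrix.
    inputs : callable(t) -> ndarray (N,), optional
        External current per cell (stimulus + frozen noise).
    syn : SynParams, optional
        If given, neighbours couple through graded chemical synapses instead
        of gap junctions (the reciprocal-excitation comparison network).
    """
    state = np.asarray(state, dtype=float)
    n = net.N
    if state.shape[0] != 2 * n:
        raise ValueError(f"state length {state.shape[0]} != 2N = {2 * n}")
    V = state[:n]
    W = state[n:]
    I_in = np.zeros(n) if inputs is None else np.asarray(inputs(t), dtype=float)
    if syn is None:
        div = net.synapse_divisor() if getattr(net, "chain_renormalize",
                                               False) else None
        I_cpl = gap_current_all(V, net.adjacency, net.g_el, net.n_cc,
                                divisor=div)
    else:
        A = np.asarray(net.adjacency, dtype=float)
        gate = sigmoid_s(-(V - syn.theta_syn) / syn.k_syn)
        # outward-positive Eq-5 current, subtracted in the voltage equation
        I_cpl = -syn.g_syn * (A @ gate) * (syn.E_syn - V)
    dV = (-fast_current(V, cell) - W + I_cpl + I_in) / cell.tau_m
    dW = (slow_activation(V, cell) - W) / tau_w(V, cell)
    return np.concatenate([dV, dW])
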