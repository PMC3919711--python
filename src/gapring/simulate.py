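"""Network integration with frozen noise and transient switching stimuli.

The integration protocol mirrors the three-step workflow used throughout the
study: (1) start all cells from an identical point on the silent branch at
very low coupling so in-phase (IP) oscillation emerges, (2) split the network
into a target multiphase pattern with brief +1/-1 current pulses delivered to
contiguous groups at intervals of T/k, (3) test the resulting pattern for
robustness against piecewise-constant Gaussian current noise (delegated to
:mod:`gapring.stability`).

Noise is redrawn independently per cell every ``update_dt`` (0.2 time units)
and held constant between redraws; the fixed-step RK4 solver advances an
integer number of steps within each hold so the solved system is exactly
piecewise-smooth and runs are bit-reproducible for a given (seed, config).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import network_rhs
from .network import NetworkSpec, GroupPartition
from .params import CellParams, NoiseSpec, StimulusSpec

SOLVERS = ("rk4", "rk45")
DEFAULT_H = 0.1


def single_cell_net() -> NetworkSpec:
    """A trivial one-cell 'network' (no coupling), for free-cell runs."""
    return NetworkSpec(N=1, topology="ring", n_cc=1, g_el=0.0,
                       adjacency=np.zeros((1, 1), dtype=np.int8))


@dataclass
class TrajectorySet:
    """Time grid plus V, W arrays for all cells, with run provenance."""

    t: np.ndarray
    V: np.ndarray  # (samples, N)
    W: np.ndarray
    net: NetworkSpec
    cell: CellParams
    noise: NoiseSpec | None = None
    stimuli: tuple = ()
    solver: str = "rk4"
    h: float = DEFAULT_H
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.V.shape[1]

    def final_state(self) -> np.ndarray:
        return np.concatenate([self.V[-1], self.W[-1]])

    def window(self, t_from: float) -> "TrajectorySet":
        """Sub-trajectory from ``t_from`` to the end (shares arrays)."""
        k = int(np.searchsorted(self.t, t_from))
        return TrajectorySet(self.t[k:], self.V[k:], self.W[k:], self.net,
                             self.cell, self.noise, self.stimuli, self.solver,
                             self.h, dict(self.meta))

    def to_dataframe(self):
        """Tidy (time, cell, V, W) table; cell numbers are 1-based."""
        import pandas as pd

        n_t, n_c = self.V.shape
        return pd.DataFrame({
            "time": np.repeat(self.t, n_c),
            "cell": np.tile(np.arange(1, n_c + 1), n_t),
            "V": self.V.ravel(),
            "W": self.W.ravel(),
        })

    def metadata(self) -> dict:
        return {
            "N": self.net.N, "topology": self.net.topology,
            "n_cc": self.net.n_cc, "g_el": self.net.g_el,
            "cell": self.cell.as_dict(),
            "noise": None if self.noise is None else {
                "sigma": self.noise.sigma, "update_dt": self.noise.update_dt,
                "seed": self.noise.seed},
            "solver": self.solver, "h": self.h,
            "stimuli": [
                {"cells": list(s.cells), "amplitudes": list(s.amplitudes),
                 "onset": s.onset, "duration": s.duration,
                 "n_repeats": s.n_repeats} for s in self.stimuli],
            **self.meta,
        }


def _build_inputs(N: int, t0: float, n_holds: int, update_dt: float,
                  noise: NoiseSpec | None,
                  stimuli: Sequence[StimulusSpec]) -> np.ndarray:
    inputs = np.zeros((n_holds, N))
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        inputs += rng.normal(0.0, noise.sigma, size=(n_holds, N))
    for stim in stimuli:
        k0 = int(round((stim.onset - t0) / update_dt))
        n_k = max(1, int(round(stim.duration * stim.n_repeats / update_dt)))
        k0 = max(k0, 0)
        for k in range(k0, min(k0 + n_k, n_holds)):
            for c, a in zip(stim.cells, stim.amplitudes):
                inputs[k, c] += a
    return inputs


def integrate(net: NetworkSpec, cell: CellParams, init: np.ndarray,
              t_span: tuple[float, float], noise: NoiseSpec | None = None,
              stimuli: Sequence[StimulusSpec] = (), solver: str = "rk4",
              h: float = DEFAULT_H, rtol: float = 1e-6) -> TrajectorySet:
    """Integrate the network ODEs over ``t_span``.

    ``init`` is the flat state ``[V_1..V_N, W_1..W_N]``.  ``solver`` is
    ``"rk4"`` (fixed step ``h``, the default production path) or ``"rk45"``
    (adaptive Runge-Kutta(4,5) reference, relative tolerance ``rtol``).  Both
    honour the piecewise-constant input exactly by integrating between hold
    boundaries.
    """
    init = np.asarray(init, dtype=float)
    if init.shape[0] != 2 * net.N:
        raise ValueError(f"init length {init.shape[0]} != 2N = {2 * net.N}")
    if solver not in SOLVERS:
        raise ValueError(f"unknown solver {solver!r}")
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError("t_span must have positive length")
    update_dt = noise.update_dt if noise is not None else 0.2
    n_holds = int(math.ceil((t1 - t0) / update_dt - 1e-9))
    stimuli = tuple(stimuli)
    inputs = _build_inputs(net.N, t0, n_holds, update_dt, noise, stimuli)

    steps_per_hold = max(1, int(round(update_dt / h)))
    h_eff = update_dt / steps_per_hold
    n_steps = n_holds * steps_per_hold
    t_grid = t0 + h_eff * np.arange(n_steps + 1)

    if solver == "rk4":
        A = np.ascontiguousarray(net.adjacency, dtype=np.float64)
        deg = A.sum(axis=1)
        gnc = net.g_el / net.synapse_divisor() \
            if getattr(net, "chain_renormalize", False) \
            else np.full(net.N, net.g_el / net.n_cc)
        p = _kernels.pack_params(cell)
        Vrec, Wrec = _kernels.rk4_piecewise(
            init[:net.N].copy(), init[net.N:].copy(), A, deg, gnc,
            inputs, steps_per_hold, h_eff, p)
    else:
        from scipy.integrate import solve_ivp

        Vrec = np.empty((n_steps + 1, net.N))
        Wrec = np.empty((n_steps + 1, net.N))
        y = init.copy()
        Vrec[0], Wrec[0] = y[:net.N], y[net.N:]
        for hold in range(n_holds):
            Iin = inputs[hold]
            ta = t0 + hold * update_dt
            tb = ta + update_dt
            t_eval = ta + h_eff * np.arange(1, steps_per_hold + 1)
            sol = solve_ivp(
                network_rhs, (ta, tb), y, method="RK45", t_eval=t_eval,
                rtol=rtol, atol=1e-9,
                args=(net, cell, (lambda tt, I=Iin: I)))
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise RuntimeError(
                    f"adaptive solver failed near t={ta:.2f}: {sol.message}")
            blk = slice(hold * steps_per_hold + 1,
                        (hold + 1) * steps_per_hold + 1)
            Vrec[blk] = sol.y[:net.N].T
            Wrec[blk] = sol.y[net.N:].T
            y = sol.y[:, -1]

    if not np.all(np.isfinite(Vrec[-1])):
        bad = np.flatnonzero(~np.isfinite(Vrec).all(axis=1))
        raise RuntimeError(f"state became non-finite at t={t_grid[bad[0]]:.2f}")
    return TrajectorySet(t=t_grid, V=Vrec, W=Wrec, net=net, cell=cell,
                         noise=noise, stimuli=stimuli, solver=solver, h=h_eff)


# ---------------------------------------------------------------------------
# free cell: limit cycle, period, silent-branch initial point
# ---------------------------------------------------------------------------

def silent_branch_state(cell: CellParams) -> np.ndarray:
    """A point on the free cell's silent (left) branch: V-nullcline at W=0."""
    # left-branch root of W(V)=0 is at u = -sqrt(3), u=(V-v_mid)/v_scale
    v = cell.v_mid - math.sqrt(3.0) * cell.v_scale
    return np.array([v, 0.0])


def free_cycle(cell: CellParams, solver: str = "rk4", h: float = 0.05,
               v_threshold: float | None = None) -> dict:
    """Free-cell limit cycle, sampled on a phase grid.

    Integrates a single uncoupled cell to its periodic orbit and returns
    ``{"T": period, "duty": duty cycle, "phase", "V", "W", ...}`` where phase
    0 is the upward threshold crossing (active-phase onset).
    """
    if v_threshold is None:
        v_threshold = cell.v_mid  # midpoint between the two knees' V
    net = single_cell_net()
    init = silent_branch_state(cell).copy()
    # generous first run: period is a few hundred time units at defaults
    traj = integrate(net, cell, init, (0.0, 3000.0), solver=solver, h=h)
    v = traj.V[:, 0]
    ups = _up_crossings(traj.t, v, v_threshold)
    if len(ups) < 3:
        traj = integrate(net, cell, traj.final_state(), (0.0, 12000.0),
                         solver=solver, h=h)
        v = traj.V[:, 0]
        ups = _up_crossings(traj.t, v, v_threshold)
    if len(ups) < 3:
        raise RuntimeError("free cell did not oscillate (no threshold "
                           "crossings); check parameters")
    T = ups[-1] - ups[-2]
    downs = _down_crossings(traj.t, v, v_threshold)
    downs = downs[(downs > ups[-2]) & (downs < ups[-1])]
    duty = float((downs[0] - ups[-2]) / T) if len(downs) else float("nan")
    mask = (traj.t >= ups[-2]) & (traj.t <= ups[-1])
    tt = traj.t[mask]
    phase = (tt - ups[-2]) / T
    return {"T": float(T), "duty": duty, "phase": phase,
            "V": traj.V[mask, 0], "W": traj.W[mask, 0],
            "threshold": v_threshold}


def _up_crossings(t, v, th):
    idx = np.flatnonzero((v[:-1] < th) & (v[1:] >= th))
    if len(idx) == 0:
        return np.array([])
    frac = (th - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _down_crossings(t, v, th):
    idx = np.flatnonzero((v[:-1] >= th) & (v[1:] < th))
    if len(idx) == 0:
        return np.array([])
    frac = (v[idx] - th) / (v[idx] - v[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def identical_init(net: NetworkSpec, cell: CellParams) -> np.ndarray:
    """Identical-for-all-cells initial condition on the silent branch."""
    v, w = silent_branch_state(cell)
    return np.concatenate([np.full(net.N, v), np.full(net.N, w)])


def kphase_state(net: NetworkSpec, cell: CellParams, part: GroupPartition,
                 settle: float | None = None, solver: str = "rk4",
                 h: float = DEFAULT_H, cycle: dict | None = None) -> np.ndarray:
    """Construct a k-phase initial condition from the free limit cycle.

    Group ``m`` is placed on the free cycle at phase ``-m/k`` (so groups jump
    up in index order, spaced T/k apart), then the coupled network is settled
    noise-free for a few periods.
    """
    cyc = cycle if cycle is not None else free_cycle(cell)
    k = part.n_groups
    V = np.empty(net.N)
    W = np.empty(net.N)
    for m in range(k):
        ph = (1.0 - m / k) % 1.0
        j = int(np.searchsorted(cyc["phase"], ph))
        j = min(j, len(cyc["phase"]) - 1)
        V[part.labels == m] = cyc["V"][j]
        W[part.labels == m] = cyc["W"][j]
    state = np.concatenate([V, W])
    if settle is None:
        settle = 3.0 * cyc["T"]
    if settle > 0:
        traj = integrate(net, cell, state, (0.0, settle), solver=solver, h=h)
        state = traj.final_state()
    return state


# ---------------------------------------------------------------------------
# switching protocol
# ---------------------------------------------------------------------------

def switching_stimuli(part: GroupPartition, T: float, t0: float = 5.0,
                      amplitude: float = 1.0, duration: float = 0.2,
                      n_repeats: int = 3, push_pull: bool = True) -> list:
    """Stimulus library for switching IP into a k-phase pattern.

    Group ``m`` receives a +``amplitude`` pulse train at ``t0 + m*T/k``;
    with ``push_pull`` all other cells simultaneously receive the opposite
    sign, so that some cells get +1 and some -1.
    Pulses are 0.2-time-unit attempts repeated ``n_repeats`` times in
    succession.
    """
    k = part.n_groups
    N = len(part.labels)
    stims = []
    for m in range(k):
        members = tuple(int(c) for c in np.flatnonzero(part.labels == m))
        others = tuple(int(c) for c in np.flatnonzero(part.labels != m))
        cells = members + (others if push_pull else ())
        amps = (amplitude,) * len(members) + \
            ((-amplitude,) * len(others) if push_pull else ())
        stims.append(StimulusSpec(cells=cells, amplitudes=amps,
                                  onset=t0 + m * T / k, duration=duration,
                                  n_repeats=n_repeats))
    return stims


def switch_pattern(net: NetworkSpec, cell: CellParams, state: np.ndarray,
                   part: GroupPartition, amplitude: float = 1.0,
                   n_repeats: int = 3, settle: float | None = None,
                   solver: str = "rk4", h: float = DEFAULT_H,
                   cycle: dict | None = None) -> TrajectorySet:
    """Apply the +1/-1 switching protocol and settle to steady behaviour.

    Returns the post-stimulus trajectory (stimulus window included at the
    start) for classification.  Failure to switch is a valid outcome that the
    classifier reports.
    """
    cyc = cycle if cycle is not None else free_cycle(cell)
    T = cyc["T"]
    stims = switching_stimuli(part, T, amplitude=amplitude,
                              n_repeats=n_repeats)
    if settle is None:
        settle = 6.0 * T
    t_end = stims[-1].offset + settle
    traj = integrate(net, cell, state, (0.0, t_end), stimuli=stims,
                     solver=solver, h=h)
    traj.meta["switch_recipe"] = {
        "kind": "phase_staggered_push_pull", "amplitude": amplitude,
        "n_repeats": n_repeats, "T_free": T,
        "group_sizes": list(part.sizes)}
    return traj


def run_protocol(net: NetworkSpec, cell: CellParams, part: GroupPartition,
                 noise: NoiseSpec | None = None, g_establish: float = 0.02,
                 g_step: float = 0.01, solver: str = "rk4",
                 h: float = DEFAULT_H, tol_phase: float = 0.02):
    """Full three-step workflow: IP at low coupling -> switch -> noise test.

    The pattern is established by the switching protocol at ``g_establish``
    (default 0.02, where IP forms readily), then the coupling is raised to
    ``net.g_el`` in ``g_step`` increments with a short settle at each value,
    and finally the noise test is run (if ``noise`` is given).

    Returns ``(traj, label, verdict)`` where ``verdict`` is ``"stable"``,
    ``"collapsed_to_ip"``, ``"lost"`` or ``"not_established"``.
    """
    from .classify import classify_trajectory, labels_equivalent
    from .stability import test_stability

    cyc = free_cycle(cell)
    T = cyc["T"]
    low = net.with_gel(min(g_establish, net.g_el))
    state = identical_init(net, cell)
    ip = integrate(low, cell, state, (0.0, 2.2 * T), solver=solver, h=h)
    traj = switch_pattern(low, cell, ip.final_state(), part, solver=solver,
                          h=h, cycle=cyc)
    state = traj.final_state()
    g = low.g_el
    while g < net.g_el - 1e-9:
        g = min(g + g_step, net.g_el)
        step_net = net.with_gel(g)
        traj = integrate(step_net, cell, state, (0.0, 2.0 * T),
                         solver=solver, h=h)
        state = traj.final_state()
    final_net = net.with_gel(net.g_el)
    traj = integrate(final_net, cell, state, (0.0, 4.5 * T), solver=solver,
                     h=h)
    label = classify_trajectory(traj, tol_phase=tol_phase)
    target_k = part.n_groups
    if label.n_phases != target_k:
        verdict = "not_established"
    elif noise is None or noise.sigma == 0:
        verdict = "stable"
    else:
        verdict, label_after, _ = test_stability(
            final_net, cell, traj.final_state(), label, noise,
            solver=solver, h=h, tol_phase=tol_phase)
    return traj, label, verdict
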