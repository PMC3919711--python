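"""Noise-robustness testing and stability-domain mapping.

A pattern is called stable at a parameter point if, after 250 time units of
piecewise-constant Gaussian current noise followed by noise-free settling, the
classifier returns the same label (same phase count and same cell partition)
as before the noise.  Domains are mapped by continuation: the pattern is
established at the low end of the g_el grid and the coupling is raised one
grid step (0.01) at a time, carrying the settled state forward, exactly as in
the incremental-conductance protocol.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import classify_trajectory, labels_equivalent, PatternLabel
from .network import build_adjacency, partition, NetworkSpec, GroupPartition
from .params import CellParams, NoiseSpec
from .simulate import integrate, kphase_state, free_cycle, DEFAULT_H

NOISE_DURATION = 250.0
DEFAULT_G_STEP = 0.01
DEFAULT_N_SEEDS = 3

STABLE = "stable"
COLLAPSED = "collapsed_to_ip"
OTHER = "other"
ABSENT = "absent"


@dataclass
class StabilityDomain:
    """Label grid over (g_el, N_cc) or (g_el, group-size ratio)."""

    g_grid: np.ndarray
    axis_values: list            # N_cc values or size pairs
    axis_name: str               # "n_cc" | "sizes"
    labels: np.ndarray           # (len(axis_values), len(g_grid)) of str
    sigma: float
    pattern_k: int
    meta: dict = field(default_factory=dict)

    def boundary(self, row: int):
        """First failing g_el along a row, or None if never failing."""
        lab = self.labels[row]
        stable_idx = np.flatnonzero(lab == STABLE)
        if len(stable_idx) == 0:
            return ABSENT
        fail = np.flatnonzero(lab != STABLE)
        fail = fail[fail > stable_idx[0]]
        return float(self.g_grid[fail[0]]) if len(fail) else None

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.labels, columns=[f"{g:.3f}" for g in self.g_grid])
        df.insert(0, self.axis_name, [str(v) for v in self.axis_values])
        df.to_csv(path, index=False)

    def plot(self, ax=None):
        """(g_el, connectivity) domain heatmap (stable = dark)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        code = (self.labels == STABLE).astype(float)
        ax.imshow(code, aspect="auto", origin="lower", cmap="Greys",
                  extent=[self.g_grid[0], self.g_grid[-1], -0.5,
                          len(self.axis_values) - 0.5], vmin=0, vmax=1.3)
        ax.set_yticks(range(len(self.axis_values)))
        ax.set_yticklabels([str(v) for v in self.axis_values])
        ax.set_xlabel("g_el")
        ax.set_ylabel(self.axis_name)
        ax.set_title(f"{self.pattern_k}-phase, sigma={self.sigma}")
        return ax


def test_stability(net: NetworkSpec, cell: CellParams, pattern_state,
                   baseline: PatternLabel, noise: NoiseSpec,
                   duration: float = NOISE_DURATION, solver: str = "rk4",
                   h: float = DEFAULT_H, tol_phase: float = 0.02):
    """Noise test: integrate with noise, settle noise-free, re-classify.

    Returns ``(verdict, label_after, final_state)`` with verdict ``stable``,
    ``collapsed_to_ip`` or ``other``.
    """
    state = np.asarray(pattern_state, dtype=float)
    T = baseline.period if np.isfinite(baseline.period) else 300.0
    if noise.sigma > 0:
        noisy = integrate(net, cell, state, (0.0, duration), noise=noise,
                          solver=solver, h=h)
        state = noisy.final_state()
    settle = integrate(net, cell, state, (0.0, 2.0 * T), solver=solver, h=h)
    probe = integrate(net, cell, settle.final_state(), (0.0, 4.5 * T),
                      solver=solver, h=h)
    label_after = classify_trajectory(probe, tol_phase=tol_phase)
    if labels_equivalent(baseline, label_after):
        verdict = STABLE
    elif label_after.kind == "k-phase" and label_after.n_phases == 1:
        verdict = COLLAPSED
    else:
        verdict = OTHER
    return verdict, label_after, probe.final_state()


def _establish(N, topology, n_cc, g0, cell, part, solver, h, cycle,
               tol_phase, g_seed: float = 0.05):
    """Establish the k-phase pattern at ``g0``.

    The pattern is constructed from staggered free-cycle states at weak
    coupling (``min(g_seed, g0)``) and the conductance is ramped to ``g0``
    one grid step at a time (incremental protocol); patterns near their
    existence boundary are only reachable this way.
    """
    g_lo = min(g_seed, g0)
    net = build_adjacency(N, topology, n_cc, g_el=g_lo)
    state = kphase_state(net, cell, part, solver=solver, h=h, cycle=cycle)
    T = cycle["T"]
    g = g_lo
    while g < g0 - 1e-9:
        g = min(g + DEFAULT_G_STEP, g0)
        net = net.with_gel(float(g))
        settle = integrate(net, cell, state, (0.0, 2.0 * T), solver=solver,
                           h=h)
        state = settle.final_state()
    probe = integrate(net, cell, state, (0.0, 4.5 * T), solver=solver, h=h)
    label = classify_trajectory(probe, tol_phase=tol_phase)
    ok = (label.kind == "k-phase" and label.n_phases == part.n_groups)
    return net, probe.final_state(), label, ok


def sweep_gel(N: int, topology: str, n_cc: int, part: GroupPartition,
              g_grid, cell: CellParams = CellParams(),
              sigma: float = 0.0, seeds=(0,), solver: str = "rk4",
              h: float = DEFAULT_H, tol_phase: float = 0.02,
              cycle: dict | None = None):
    """Continuation sweep along a g_el grid for one (topology, n_cc) row.

    Returns ``(labels, boundary)`` where ``labels`` is the per-grid-point
    verdict list and ``boundary`` the first failing g_el (None if the pattern
    never fails on the grid, ``"absent"`` if it could not be established).
    At ``sigma > 0`` the verdict at each point is the majority over ``seeds``
    independent noise realizations started from the same settled state.
    """
    g_grid = np.asarray(g_grid, dtype=float)
    cyc = cycle if cycle is not None else free_cycle(cell)
    labels = [OTHER] * len(g_grid)
    net, state, baseline, ok = _establish(
        N, topology, n_cc, g_grid[0], cell, part, solver, h, cyc, tol_phase)
    if not ok:
        return [ABSENT] * len(g_grid), ABSENT
    T = baseline.period
    boundary = None
    for idx, g in enumerate(g_grid):
        net = net.with_gel(float(g))
        settle = integrate(net, cell, state, (0.0, 2.0 * T), solver=solver,
                           h=h)
        probe = integrate(net, cell, settle.final_state(), (0.0, 4.5 * T),
                          solver=solver, h=h)
        label_here = classify_trajectory(probe, tol_phase=tol_phase)
        pre_noise_state = probe.final_state()
        if not labels_equivalent(baseline, label_here):
            labels[idx] = (COLLAPSED if label_here.n_phases == 1
                           and label_here.kind == "k-phase" else OTHER)
            boundary = float(g)
            break
        if sigma > 0:
            verdicts = []
            for s in seeds:
                noise = NoiseSpec(sigma=sigma, seed=int(s))
                v, _, _ = test_stability(net, cell, pre_noise_state,
                                         baseline, noise, solver=solver,
                                         h=h, tol_phase=tol_phase)
                verdicts.append(v)
            n_stable = sum(v == STABLE for v in verdicts)
            if n_stable * 2 > len(verdicts):
                labels[idx] = STABLE
            else:
                vc = [v for v in verdicts if v != STABLE]
                labels[idx] = max(set(vc), key=vc.count)
                boundary = float(g)
                break
        else:
            labels[idx] = STABLE
        state = pre_noise_state
    if boundary is not None:
        # beyond the first failure only IP survives; mark remaining points
        for j in range(idx + 1, len(g_grid)):
            labels[j] = labels[idx]
    return labels, boundary


def pattern_state_at(N: int, topology: str, n_cc: int, part: GroupPartition,
                     g_target: float, cell: CellParams = CellParams(),
                     g_start: float = 0.01, g_step: float = DEFAULT_G_STEP,
                     solver: str = "rk4", h: float = DEFAULT_H,
                     tol_phase: float = 0.02, cycle: dict | None = None):
    """Establish a k-phase pattern at ``g_target`` by continuation.

    The pattern is constructed at weak coupling (where every multiphase
    pattern of interest exists) and the conductance is raised one grid step
    at a time with a short settle at each value, mirroring the
    incremental-conductance protocol.  Returns ``(net, state, label)``;
    raises if the pattern is lost on the way up.
    """
    cyc = cycle if cycle is not None else free_cycle(cell)
    net, state, label, ok = _establish(N, topology, n_cc, g_target, cell,
                                       part, solver, h, cyc, tol_phase,
                                       g_seed=g_start)
    if not ok:
        raise RuntimeError(
            f"{part.n_groups}-phase pattern not established at "
            f"g_el={g_target} (got {label.kind}/{label.n_phases})")
    return net, state, label


def find_transition_gel(N: int, topology: str, n_cc: int, pattern_k: int,
                        g_grid, cell: CellParams = CellParams(),
                        sigma: float = 0.0, seeds=(0, 1, 2),
                        sizes=None, solver: str = "rk4", h: float = DEFAULT_H,
                        tol_phase: float = 0.02, cycle: dict | None = None):
    """Smallest grid g_el at which the k-phase pattern fails.

    Returns the boundary conductance (+- one grid step), None if the pattern
    survives the whole grid, or ``"absent"`` if it is never stable.
    """
    if sizes is None:
        if N % pattern_k:
            raise ValueError("equal groups require pattern_k | N")
        sizes = [N // pattern_k] * pattern_k
    part = partition(N, sizes)
    _, boundary = sweep_gel(N, topology, n_cc, part, g_grid, cell=cell,
                            sigma=sigma, seeds=seeds, solver=solver, h=h,
                            tol_phase=tol_phase, cycle=cycle)
    return boundary


def map_domain(N: int, pattern_k: int, n_cc_list, g_grid,
               sigma: float = 0.0, seeds=(0, 1, 2),
               cell: CellParams = CellParams(), topology: str = "ring",
               solver: str = "rk4", h: float = DEFAULT_H,
               tol_phase: float = 0.02) -> StabilityDomain:
    """Stability-domain grid over (g_el, N_cc) for a k-phase pattern."""
    g_grid = np.asarray(g_grid, dtype=float)
    if len(g_grid) == 0 or len(n_cc_list) == 0:
        return StabilityDomain(g_grid=g_grid, axis_values=list(n_cc_list),
                               axis_name="n_cc",
                               labels=np.empty((len(n_cc_list), len(g_grid)),
                                               dtype=object),
                               sigma=sigma, pattern_k=pattern_k)
    cyc = free_cycle(cell)
    part = partition(N, [N // pattern_k] * pattern_k)
    rows = []
    for n_cc in n_cc_list:
        topo = "complete" if n_cc == N - 1 else topology
        labels, _ = sweep_gel(N, topo, n_cc, part, g_grid, cell=cell,
                              sigma=sigma, seeds=seeds, solver=solver, h=h,
                              tol_phase=tol_phase, cycle=cyc)
        rows.append(labels)
    return StabilityDomain(
        g_grid=g_grid, axis_values=list(n_cc_list), axis_name="n_cc",
        labels=np.array(rows, dtype=object), sigma=sigma,
        pattern_k=pattern_k,
        meta={"N": N, "seeds": list(seeds), "topology": topology})


def map_asymmetric(N: int, topology: str, size_pairs, g_grid,
                   sigma: float = 0.0, seeds=(0, 1, 2),
                   cell: CellParams = CellParams(), solver: str = "rk4",
                   h: float = DEFAULT_H,
                   tol_phase: float = 0.02) -> StabilityDomain:
    """Stability-domain grid over (g_el, group-size ratio) for 2-phase
    patterns with unequal groups (complete-graph or ring panels)."""
    g_grid = np.asarray(g_grid, dtype=float)
    cyc = free_cycle(cell)
    n_cc = N - 1 if topology == "complete" else 2
    rows = []
    for sizes in size_pairs:
        part = partition(N, sizes)
        labels, _ = sweep_gel(N, topology, n_cc, part, g_grid, cell=cell,
                              sigma=sigma, seeds=seeds, solver=solver, h=h,
                              tol_phase=tol_phase, cycle=cyc)
        rows.append(labels)
    return StabilityDomain(
        g_grid=g_grid, axis_values=[tuple(s) for s in size_pairs],
        axis_name="sizes", labels=np.array(rows, dtype=object),
        sigma=sigma, pattern_k=2,
        meta={"N": N, "seeds": list(seeds), "topology": topology})


def chain_robustness_increase(N: int = 24, sigma: float = 0.002,
                              seeds=(0, 1, 2), g_grid=None,
                              cell: CellParams = CellParams(),
                              solver: str = "rk4", h: float = DEFAULT_H):
    """Percent increase of the AP collapse boundary, nearest-neighbour chain
    relative to the fully coupled network: (chain - complete)/complete * 100.
    """
    if g_grid is None:
        g_grid = np.arange(0.05, 0.60 + 1e-9, DEFAULT_G_STEP)
    cyc = free_cycle(cell)
    b_chain = find_transition_gel(N, "chain", 2, 2, g_grid, cell=cell,
                                  sigma=sigma, seeds=seeds, solver=solver,
                                  h=h, cycle=cyc)
    b_full = find_transition_gel(N, "complete", N - 1, 2, g_grid, cell=cell,
                                 sigma=sigma, seeds=seeds, solver=solver,
                                 h=h, cycle=cyc)
    if not (isinstance(b_chain, float) and isinstance(b_full, float)):
        raise RuntimeError(
            f"AP boundary not found (chain={b_chain}, complete={b_full})")
    return (b_chain - b_full) / b_full * 100.0, b_chain, b_full
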