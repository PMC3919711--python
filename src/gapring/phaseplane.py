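"""Phase-plane geometry: nullclines, knees, critical deflections, DTK.

The V-nullcline at total applied current I is ``W = -I_fast(V) + I``; because
the current enters the voltage equation additively, a depolarizing current
shifts the whole curve (and both knees) up by exactly I.  A silent cell
coupled to active partners therefore evolves against an instantaneously
shifted nullcline; its vertical distance to the shifted left knee -- the
distance to knee, DTK, measured at the instant the active cells cross W = 0
-- predicts how close the pattern is to collapse: when the knee rises above
the cell the cell jumps up prematurely and the multiphase solution is
replaced by synchrony.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import fast_current, slow_activation, gap_current_all
from .params import CellParams


@dataclass
class NullclineCurve:
    V: np.ndarray
    W: np.ndarray
    I_total: float
    left_knee: tuple   # (V, W)
    right_knee: tuple
    w_nullcline: np.ndarray = field(default=None)  # W_inf on same V grid


@dataclass
class DeflectionRecord:
    cell: int
    group: int
    dtk: float          # W_cell - W_left_knee(shifted), vertical distance
    w_at_instant: float
    v_excursion: float  # maximal silent-phase V of the cell
    i_el: float
    g_el: float
    n_cc: int


def v_nullcline(I_total: float, cell: CellParams,
                v_range=None, n: int = 2001,
                with_w_nullcline: bool = True) -> NullclineCurve:
    """Sampled V-nullcline ``W = -I_fast(V) + I_total`` with its two knees.

    ``v_range`` defaults to 2.6 cubic half-widths either side of the centre.
    Raises if the requested range does not bracket both turning points.
    """
    if v_range is None:
        v_range = (cell.v_mid - 2.6 * cell.v_scale,
                   cell.v_mid + 2.6 * cell.v_scale)
    V = np.linspace(v_range[0], v_range[1], n)
    W = -fast_current(V, cell) + I_total
    left, right = find_knees_arrays(V, W)
    wn = slow_activation(V, cell) if with_w_nullcline else None
    return NullclineCurve(V=V, W=W, I_total=I_total, left_knee=left,
                          right_knee=right, w_nullcline=wn)


def find_knees(curve: NullclineCurve):
    """Interior extrema of W along the curve (left = lower W, right = higher)."""
    return find_knees_arrays(curve.V, curve.W)


def find_knees_arrays(V: np.ndarray, W: np.ndarray):
    """Locate the two turning points by derivative sign change with local
    quadratic refinement; deterministic for a fixed grid."""
    dW = np.diff(W)
    sign = np.sign(dW)
    sign[sign == 0] = 1
    flips = np.flatnonzero(np.diff(sign) != 0) + 1
    if len(flips) < 2:
        raise ValueError("V range does not bracket two knees")
    knees = []
    for j in flips[:2] if len(flips) == 2 else _pick_extreme(flips, W):
        j0 = max(1, min(j, len(V) - 2))
        v_fit = V[j0 - 1:j0 + 2]
        w_fit = W[j0 - 1:j0 + 2]
        a, b, c = np.polyfit(v_fit, w_fit, 2)
        v_k = -b / (2 * a) if a != 0 else V[j0]
        w_k = np.polyval([a, b, c], v_k)
        knees.append((float(v_k), float(w_k)))
    knees.sort(key=lambda p: p[1])
    left, right = knees[0], knees[1]
    return left, right


def _pick_extreme(flips, W):
    """With numerical wiggles, keep the two most extreme turning points."""
    vals = W[flips]
    return [int(flips[np.argmin(vals)]), int(flips[np.argmax(vals)])]


def knee_w_shift(cell: CellParams, I_total: float) -> float:
    """Left-knee W at applied current I (additive shift of the free knee)."""
    return -cell.knee_w + I_total


def compute_dtk(traj, label, net, cell: CellParams,
                min_cycles: int = 3, metric: str = "vertical"):
    """DTK of every silent cell at the instants active cells cross W = 0.

    For each cycle and each active group: at the time the active group's mean
    W crosses zero (rising), every silent cell's instantaneous gap current
    defines a shifted nullcline whose left knee sits at
    ``W = -knee_w + I_el``; DTK is the cell's W minus that knee W (vertical
    distance; ``metric="euclidean"`` instead measures the planar distance to
    the knee point).  Records are averaged over at least ``min_cycles``
    cycles.  Returns a list of per-cell DeflectionRecords (empty for IP).
    """
    if label.n_phases < 2:
        return []
    if metric not in ("vertical", "euclidean"):
        raise ValueError("metric must be 'vertical' or 'euclidean'")
    groups = label.group_of_cell
    th = cell.v_mid  # active/silent split at the inter-knee midpoint
    acc: dict[int, list] = {}
    wacc: dict[int, list] = {}
    iacc: dict[int, list] = {}
    grp_of: dict[int, int] = {}
    n_instants = 0
    for g in range(label.n_phases):
        members = np.flatnonzero(groups == g)
        wg = traj.W[:, members].mean(axis=1)
        vg = traj.V[:, members].mean(axis=1)
        active = vg > th
        rising = np.flatnonzero((wg[:-1] < 0) & (wg[1:] >= 0)
                                & active[:-1] & active[1:])
        for idx in rising:
            n_instants += 1
            Vnow = traj.V[idx]
            Wnow = traj.W[idx]
            div = net.synapse_divisor() if getattr(net, "chain_renormalize",
                                                   False) else None
            iel = gap_current_all(Vnow, net.adjacency, net.g_el, net.n_cc,
                                  divisor=div)
            silent = np.flatnonzero(Vnow <= th)
            for c in silent:
                knee_w = -cell.knee_w + iel[c]
                if metric == "vertical":
                    d = Wnow[c] - knee_w
                else:
                    v_knee = cell.v_mid - cell.v_scale
                    d = float(np.hypot(Vnow[c] - v_knee, Wnow[c] - knee_w))
                acc.setdefault(c, []).append(d)
                wacc.setdefault(c, []).append(Wnow[c])
                iacc.setdefault(c, []).append(iel[c])
                grp_of[c] = int(groups[c])
    if n_instants < min_cycles:
        raise ValueError(
            f"only {n_instants} W=0 crossings found; need >= {min_cycles}")
    # silent-phase V excursion per cell (maximal V while below threshold)
    records = []
    for c, ds in sorted(acc.items()):
        v = traj.V[:, c]
        sil = v <= th
        vex = float(v[sil].max()) if sil.any() else float("nan")
        records.append(DeflectionRecord(
            cell=int(c), group=grp_of[c], dtk=float(np.mean(ds)),
            w_at_instant=float(np.mean(wacc[c])),
            v_excursion=vex, i_el=float(np.mean(iacc[c])),
            g_el=net.g_el, n_cc=net.n_cc))
    return records


def min_dtk(records) -> float:
    """Smallest per-cell mean DTK -- the critical deflection's distance."""
    if not records:
        raise ValueError("no deflection records")
    return min(r.dtk for r in records)


def dtk_vs_delta_gel(pattern_k: int, points, boundaries: dict,
                     N: int = 24, cell: CellParams = CellParams(),
                     solver: str = "rk4", h: float = 0.1):
    """Paired (DTK, delta g_el) table over requested (g_el, N_cc) points.

    ``boundaries`` maps N_cc -> collapse boundary g_el for this pattern.
    Returns ``(DataFrame, spearman_rho)``; the positive rank correlation of
    DTK with the remaining distance to the collapse boundary is the
    stability-indicator check.
    """
    import pandas as pd
    from scipy.stats import spearmanr

    from .network import partition
    from .simulate import free_cycle, integrate
    from .stability import pattern_state_at

    cyc = free_cycle(cell)
    part = partition(N, [N // pattern_k] * pattern_k)
    rows = []
    for g_el, n_cc in points:
        topo = "complete" if n_cc == N - 1 else "ring"
        net, state, label = pattern_state_at(
            N, topo, n_cc, part, g_el, cell=cell, solver=solver, h=h,
            cycle=cyc)
        probe = integrate(net, cell, state, (0.0, 4.5 * cyc["T"]),
                          solver=solver, h=h)
        recs = compute_dtk(probe, label, net, cell)
        b = boundaries[n_cc]
        rows.append({"g_el": g_el, "n_cc": n_cc,
                     "dtk": min_dtk(recs),
                     "delta_gel": (b - g_el) if isinstance(b, float)
                     else float("nan")})
    df = pd.DataFrame(rows)
    rho = float(spearmanr(df["dtk"], df["delta_gel"]).statistic)
    return df, rho


def max_phases(T: float, dt: float) -> int:
    """Largest k with T/k - dt > dt (strictly), i.e. k < T/(2 dt).

    The silent-phase interval between consecutive active phases must exceed
    the active duration for one more group to fit; ``dt >= T/2`` leaves room
    for synchrony only (returns 1).
    """
    if not (0 < dt < T):
        raise ValueError("require 0 < dt < T")
    x = T / (2.0 * dt)
    k = int(np.ceil(x)) - 1
    return max(k, 1)


def plot_phase_plane(traj, cell: CellParams, cells=None, currents=(0.0,),
                     ax=None):
    """Trajectory + nullclines + knees, for quick inspection or export."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for I in currents:
        c = v_nullcline(I, cell)
        ax.plot(c.V, c.W, "--", lw=1, label=f"V-nullcline I={I:g}")
        ax.plot(*c.left_knee, "kv", ms=4)
        ax.plot(*c.right_knee, "k^", ms=4)
    c0 = v_nullcline(0.0, cell)
    ax.plot(c0.V, c0.w_nullcline, "k-", lw=1, label="W-nullcline")
    cells = range(traj.V.shape[1]) if cells is None else cells
    for c in cells:
        ax.plot(traj.V[:, c], traj.W[:, c], lw=0.8)
    ax.set_xlabel("V")
    ax.set_ylabel("W")
    return ax
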