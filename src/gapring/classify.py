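"""Pattern classification: event detection, phase clustering, order analysis.

A k-phase pattern is k groups of cells whose active-phase onsets sit at k
distinct phases of the common cycle.  The classifier detects active-phase
onset/offset events by threshold crossing with hysteresis, computes per-cell
circular mean onset phases relative to a reference cell, clusters them by
single linkage on the circle with a gap tolerance, and requires stationarity
(cycle-to-cycle drift below tolerance); non-stationary runs are labelled
transitional rather than raising.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_TOL_PHASE = 0.02


@dataclass
class EventTrain:
    """Per-cell jump-up and jump-down times (active-phase onsets/offsets)."""

    ups: list          # list of ndarray, one per cell
    downs: list
    threshold: float
    quiescent: np.ndarray = field(default=None)  # bool per cell

    @property
    def N(self) -> int:
        return len(self.ups)


@dataclass
class PatternLabel:
    n_phases: int
    group_of_cell: np.ndarray
    phi: np.ndarray          # sorted inter-group phase shifts, cycle units
    period: float
    active_duration: float
    duty_cycle: float
    intra_group_lags: np.ndarray  # per-cell onset offset within group (cycles)
    symmetric: bool
    kind: str = "k-phase"    # "k-phase" | "transitional" | "quiescent"

    @property
    def stationary(self) -> bool:
        return self.kind == "k-phase"

    def group_sizes(self) -> tuple:
        return tuple(int(np.sum(self.group_of_cell == g))
                     for g in range(self.n_phases))

    def to_json_dict(self) -> dict:
        return {
            "n_phases": int(self.n_phases),
            "group_of_cell": [int(g) for g in self.group_of_cell],
            "phi": [float(p) for p in self.phi],
            "period": float(self.period),
            "active_duration": float(self.active_duration),
            "duty_cycle": float(self.duty_cycle),
            "intra_group_lags": [float(x) for x in self.intra_group_lags],
            "symmetric": bool(self.symmetric),
            "kind": self.kind,
        }


def detect_events(traj, v_threshold: float | None = None,
                  min_gap: float = 0.5) -> EventTrain:
    """Threshold-crossing event detection with a debounce interval.

    ``v_threshold`` defaults to the midpoint between the two knees of the
    free V-nullcline (``cell.v_mid``).  Crossings closer than
    ``min_gap`` to the previous accepted event of the opposite type are
    discarded, and events are forced to alternate up/down starting with up.
    """
    if v_threshold is None:
        v_threshold = getattr(traj.cell, "v_mid", 0.0)
    t = traj.t
    ups, downs, quiet = [], [], []
    for c in range(traj.V.shape[1]):
        v = traj.V[:, c]
        u = _crossings(t, v, v_threshold, up=True)
        d = _crossings(t, v, v_threshold, up=False)
        u, d = _alternate(u, d, min_gap)
        ups.append(u)
        downs.append(d)
        quiet.append(len(u) == 0)
    return EventTrain(ups=ups, downs=downs, threshold=v_threshold,
                      quiescent=np.array(quiet))


def _crossings(t, v, th, up: bool):
    if up:
        idx = np.flatnonzero((v[:-1] < th) & (v[1:] >= th))
    else:
        idx = np.flatnonzero((v[:-1] >= th) & (v[1:] < th))
    if len(idx) == 0:
        return np.array([])
    denom = v[idx + 1] - v[idx]
    frac = np.where(denom != 0, (th - v[idx]) / denom, 0.0)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _alternate(ups, downs, min_gap):
    """Merge crossings into a debounced alternating up/down train."""
    ev = [(tt, +1) for tt in ups] + [(tt, -1) for tt in downs]
    ev.sort()
    out_u, out_d = [], []
    want = +1
    last = -np.inf
    for tt, kind in ev:
        if kind != want:
            continue
        if tt - last < min_gap:
            continue
        (out_u if kind > 0 else out_d).append(tt)
        last = tt
        want = -want
    return np.asarray(out_u), np.asarray(out_d)


def duty_cycle(events: EventTrain) -> float:
    """mean(active duration) / mean(period), pooled over cells.

    Requires at least 3 detected periods on some cell.
    """
    durs, periods = [], []
    for u, d in zip(events.ups, events.downs):
        if len(u) < 2:
            continue
        periods.extend(np.diff(u))
        for uu in u:
            later = d[d > uu]
            nxt_u = u[u > uu]
            if len(later) and (len(nxt_u) == 0 or later[0] < nxt_u[0]):
                durs.append(later[0] - uu)
    if len(periods) < 3 or not durs:
        raise ValueError("need at least 3 periods of events")
    return float(np.mean(durs) / np.mean(periods))


def _circular_mean(phases: np.ndarray) -> float:
    ang = 2 * np.pi * phases
    m = np.angle(np.mean(np.exp(1j * ang))) / (2 * np.pi)
    return m % 1.0


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def classify_pattern(events: EventTrain, tol_phase: float = DEFAULT_TOL_PHASE,
                     N: int | None = None) -> PatternLabel:
    """Cluster per-cell onset phases into phase groups.

    The reference cell is the one with the most onsets.  Per cycle of the
    reference, each cell's onset phase is measured in cycle units; cells are
    clustered by single linkage on the circle, merging neighbours whose phase
    gap is at most ``tol_phase``.  Cycle-to-cycle drift above ``tol_phase``
    per cycle yields a transitional label.
    """
    N = events.N if N is None else N
    if all(len(u) < 3 for u in events.ups):
        return _degenerate_label(N, "quiescent")
    ref = int(np.argmax([len(u) for u in events.ups]))
    ref_ups = events.ups[ref]
    if len(ref_ups) < 4:
        return _degenerate_label(N, "transitional")
    T = float(np.median(np.diff(ref_ups)))
    # per-cell phases per reference cycle
    cyc_t = ref_ups[:-1]
    n_cyc = len(cyc_t)
    ph = np.full((N, n_cyc), np.nan)
    for c in range(N):
        u = events.ups[c]
        if len(u) == 0:
            continue
        for k, t0 in enumerate(cyc_t):
            sel = u[(u >= t0 - 0.5 * T) & (u < t0 + 0.5 * T + T)]
            if len(sel):
                # onset nearest to the cycle window start
                ph[c, k] = ((sel[0] - t0) / T) % 1.0
    valid = ~np.isnan(ph)
    if not np.all(valid.sum(axis=1) >= 3):
        return _degenerate_label(N, "transitional")
    mean_ph = np.array([_circular_mean(ph[c][valid[c]]) for c in range(N)])
    # stationarity: drift of unwrapped phase across cycles
    for c in range(N):
        p = ph[c][valid[c]]
        unw = np.unwrap(2 * np.pi * p) / (2 * np.pi)
        drift = np.polyfit(np.arange(len(unw)), unw, 1)[0] if len(unw) > 1 else 0.0
        if abs(drift) > tol_phase:
            return _degenerate_label(N, "transitional")
    groups = _circular_single_linkage(mean_ph, tol_phase)
    k = int(groups.max()) + 1
    centroids = np.array([_circular_mean(mean_ph[groups == g])
                          for g in range(k)])
    order = np.argsort(centroids)
    # relabel groups by increasing centroid phase; leader group is 0
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    groups = remap[groups]
    centroids = centroids[order]
    phi = np.sort(np.diff(np.concatenate([centroids, [centroids[0] + 1.0]]))) \
        if k > 1 else np.array([])
    # active duration / duty
    try:
        duty = duty_cycle(events)
    except ValueError:
        duty = float("nan")
    lags = np.empty(N)
    for g in range(k):
        members = np.flatnonzero(groups == g)
        med = _circular_mean(mean_ph[members])
        for c in members:
            d = (mean_ph[c] - med + 0.5) % 1.0 - 0.5
            lags[c] = d
    sizes = [int(np.sum(groups == g)) for g in range(k)]
    return PatternLabel(
        n_phases=k, group_of_cell=groups, phi=phi, period=T,
        active_duration=duty * T if np.isfinite(duty) else float("nan"),
        duty_cycle=duty, intra_group_lags=lags,
        symmetric=len(set(sizes)) == 1, kind="k-phase")


def _degenerate_label(N, kind) -> PatternLabel:
    return PatternLabel(
        n_phases=0, group_of_cell=np.full(N, -1), phi=np.array([]),
        period=float("nan"), active_duration=float("nan"),
        duty_cycle=float("nan"), intra_group_lags=np.full(N, np.nan),
        symmetric=False, kind=kind)


def _circular_single_linkage(phases: np.ndarray, tol: float) -> np.ndarray:
    """Cluster circular phases: neighbours within ``tol`` chain together."""
    n = len(phases)
    order = np.argsort(phases)
    sorted_ph = phases[order]
    gaps = np.diff(np.concatenate([sorted_ph, [sorted_ph[0] + 1.0]]))
    labels = np.zeros(n, dtype=int)
    # runs between breaking gaps, in sorted order
    cluster_id = np.concatenate([[0], np.cumsum(gaps[:-1] > tol)])
    if gaps[-1] <= tol and cluster_id[-1] > 0:
        # wrap gap joins the last run with the first
        cluster_id[cluster_id == cluster_id[-1]] = 0
        uniq = {c: i for i, c in enumerate(np.unique(cluster_id))}
        cluster_id = np.array([uniq[c] for c in cluster_id])
    labels[order] = cluster_id
    return labels


def intra_group_order(events: EventTrain, part, net=None,
                      tol: float = 1e-3):
    """Per-cell onset lag relative to its group median, averaged over cycles.

    Returns a dict with per-cell mean lags (time units), the leader-to-
    follower order per group, and whether the order is consistent across
    cycles.  Empty for a single group.
    """
    import pandas as pd

    k = part.n_groups
    if k < 2:
        return {"table": pd.DataFrame(columns=["cell", "group", "lag"]),
                "order": {}, "consistent": True}
    rows = []
    consistent = True
    order = {}
    for g in range(k):
        members = part.members(g)
        trains = [events.ups[c] for c in members]
        n_cyc = min(len(tr) for tr in trains)
        if n_cyc < 2:
            continue
        mat = np.stack([tr[:n_cyc] for tr in trains])  # cells x cycles
        med = np.median(mat, axis=0)
        lag = mat - med[None, :]
        mean_lag = lag.mean(axis=1)
        first = np.argsort(mean_lag, kind="stable")
        same = all(np.array_equal(np.argsort(lag[:, j], kind="stable"), first)
                   for j in range(lag.shape[1]))
        synchronous = bool(np.all(np.abs(lag) < tol))
        consistent &= same or synchronous
        order[g] = [int(members[i]) for i in first]
        for i, c in enumerate(members):
            rows.append({"cell": int(c) + 1, "group": g,
                         "lag": float(mean_lag[i])})
    return {"table": pd.DataFrame(rows), "order": order,
            "consistent": bool(consistent)}


def classify_trajectory(traj, tol_phase: float = DEFAULT_TOL_PHASE,
                        v_threshold: float | None = None,
                        min_gap: float = 0.5) -> PatternLabel:
    """Convenience wrapper: detect events on ``traj`` and classify."""
    ev = detect_events(traj, v_threshold=v_threshold, min_gap=min_gap)
    return classify_pattern(ev, tol_phase=tol_phase)


def plot_raster(events: EventTrain, ax=None, color="k"):
    """Cell-by-onset-time raster of the detected jump-up events."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c, u in enumerate(events.ups):
        ax.plot(u, np.full(len(u), c + 1), "|", ms=6, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("cell")
    ax.set_ylim(0.5, events.N + 0.5)
    return ax


def labels_equivalent(a: PatternLabel, b: PatternLabel) -> bool:
    """Same phase count and same cell partition (group numbering ignored)."""
    if a.kind != "k-phase" or b.kind != "k-phase":
        return False
    if a.n_phases != b.n_phases:
        return False
    pa = _partition_set(a.group_of_cell)
    pb = _partition_set(b.group_of_cell)
    return pa == pb


def _partition_set(labels: np.ndarray) -> frozenset:
    return frozenset(
        frozenset(np.flatnonzero(labels == g).tolist())
        for g in np.unique(labels))
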