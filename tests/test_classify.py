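"""Event detection, phase clustering and pattern labelling."""
import numpy as np
import pytest

from gapring import (EventTrain, build_adjacency, classify_pattern,
                     classify_trajectory, detect_events, duty_cycle,
                     free_cycle, integrate, intra_group_order, kphase_state,
                     labels_equivalent, partition)
from gapring.simulate import TrajectorySet, single_cell_net


def synthetic_square_traj(edges_up, edges_down, t_end, dt=0.05, lo=-0.5,
                          hi=0.5, cell=None):
    """Square-wave voltage trace with known edge times (single cell)."""
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, lo)
    for u, d in zip(edges_up, edges_down):
        v[(t >= u) & (t < d)] = hi
    return TrajectorySet(t=t, V=v[:, None], W=np.zeros_like(v)[:, None],
                         net=single_cell_net(), cell=cell)


def synthetic_train(N, k, T=100.0, dt_active=1.0, n_cyc=6, jitter=None,
                    rng=None):
    """Event train of N cells in k equal groups phase-shifted by T/k."""
    ups, downs = [], []
    for c in range(N):
        g = c * k // N
        off = g * T / k
        u = off + T * np.arange(n_cyc)
        if jitter is not None:
            u = u + rng.normal(0, jitter, size=n_cyc)
        ups.append(u)
        downs.append(u + dt_active)
    return EventTrain(ups=ups, downs=downs, threshold=0.0,
                      quiescent=np.zeros(N, bool))


class TestDetectEvents:
    def test_square_wave_edges_recovered(self, cell):
        ups = [10.0, 110.0, 210.0, 310.0]
        downs = [12.0, 112.0, 212.0, 312.0]
        traj = synthetic_square_traj(ups, downs, 400.0, cell=cell)
        ev = detect_events(traj, v_threshold=0.0, min_gap=0.5)
        assert np.allclose(ev.ups[0], ups, atol=0.06)
        assert np.allclose(ev.downs[0], downs, atol=0.06)

    def test_free_cell_one_event_pair_per_period(self, cell, cycle, period):
        net = single_cell_net()
        from gapring.simulate import silent_branch_state

        traj = integrate(net, cell, silent_branch_state(cell),
                         (0.0, 5.2 * period))
        ev = detect_events(traj)
        assert 4 <= len(ev.ups[0]) <= 6
        assert abs(len(ev.ups[0]) - len(ev.downs[0])) <= 1

    def test_quiescent_trace_flagged(self, cell):
        traj = synthetic_square_traj([], [], 100.0, cell=cell)
        ev = detect_events(traj)
        assert ev.quiescent[0]


class TestClassifyPattern:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 6])
    def test_symmetric_k_phase_ground_truth(self, k):
        ev = synthetic_train(24, k)
        label = classify_pattern(ev, tol_phase=0.02)
        assert label.n_phases == k
        assert label.kind == "k-phase"
        if k > 1:
            assert label.phi == pytest.approx([1.0 / k] * k, abs=0.02)
            assert np.isclose(label.phi.sum(), 1.0)
        assert label.period == pytest.approx(100.0, rel=1e-6)

    def test_rotation_and_time_shift_invariance(self):
        ev = synthetic_train(24, 3)
        lab = classify_pattern(ev)
        rolled = EventTrain(ups=ev.ups[8:] + ev.ups[:8],
                            downs=ev.downs[8:] + ev.downs[:8],
                            threshold=0.0, quiescent=ev.quiescent)
        lab_rot = classify_pattern(rolled)
        shifted = EventTrain(ups=[u + 37.0 for u in ev.ups],
                            downs=[d + 37.0 for d in ev.downs],
                            threshold=0.0, quiescent=ev.quiescent)
        lab_shift = classify_pattern(shifted)
        assert lab.n_phases == lab_rot.n_phases == lab_shift.n_phases == 3
        assert labels_equivalent(lab, lab_shift)

    def test_drifting_phases_labelled_transitional(self, rng):
        ups, downs = [], []
        for c in range(8):
            base = np.cumsum(np.full(8, 100.0))
            drift = (c % 2) * np.linspace(0, 40, 8)  # 5 %/cycle drift
            u = base + drift
            ups.append(u)
            downs.append(u + 1.0)
        ev = EventTrain(ups=ups, downs=downs, threshold=0.0,
                        quiescent=np.zeros(8, bool))
        label = classify_pattern(ev, tol_phase=0.02)
        assert label.kind == "transitional"

    def test_too_few_periods_degenerate(self):
        ev = synthetic_train(6, 2, n_cyc=2)
        assert classify_pattern(ev).kind in ("transitional", "quiescent")


class TestDutyCycle:
    def test_constructed_trains(self):
        assert duty_cycle(synthetic_train(4, 1, T=100.0, dt_active=1.0)) \
            == pytest.approx(0.01, rel=1e-9)
        assert duty_cycle(synthetic_train(4, 1, T=100.0, dt_active=50.0)) \
            == pytest.approx(0.5, rel=1e-9)

    def test_free_cell_short_duty(self, cycle):
        """Active phase is a negligible fraction of the period (<= 2 %)."""
        assert 0.0 < cycle["duty"] <= 0.02

    def test_empty_train_raises(self):
        ev = EventTrain(ups=[np.array([])], downs=[np.array([])],
                        threshold=0.0, quiescent=np.ones(1, bool))
        with pytest.raises(ValueError):
            duty_cycle(ev)


class TestIntraGroupOrder:
    def test_single_group_empty_table(self):
        ev = synthetic_train(12, 1)
        res = intra_group_order(ev, partition(12, [12]))
        assert res["table"].empty

    def test_all_to_all_groups_fire_synchronously(self, cell, cycle, period):
        """Fully coupled multiphase pattern: zero intra-group lags."""
        net = build_adjacency(24, "complete", 23, g_el=0.12)
        part = partition(24, [12, 12])
        st = kphase_state(net, cell, part, cycle=cycle)
        traj = integrate(net, cell, st, (0.0, 4.5 * period))
        ev = detect_events(traj)
        res = intra_group_order(ev, part)
        assert np.abs(res["table"]["lag"]).max() < 1e-3 * period

    def test_ring_groups_fire_in_consistent_order(self, cell, cycle, period):
        """N_cc=6 anti-phase: middle cells lead, edge cells lag, same order
        every cycle."""
        net = build_adjacency(24, "ring", 6, g_el=0.22)
        part = partition(24, [12, 12])
        st = kphase_state(net, cell, part, cycle=cycle)
        traj = integrate(net, cell, st, (0.0, 4.5 * period))
        label = classify_trajectory(traj)
        assert label.n_phases == 2
        res = intra_group_order(detect_events(traj), part)
        tab = res["table"]
        g0 = tab[tab.group == 0].set_index("cell")["lag"]
        # middle cells (6, 7) jump ahead of edge cells (1, 12)
        assert g0.loc[6] < g0.loc[1]
        assert g0.loc[7] < g0.loc[12]
        assert g0.loc[1] > 0 and g0.loc[6] < 0
        assert res["consistent"]
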