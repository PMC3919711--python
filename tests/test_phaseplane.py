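"""Nullclines, knees, DTK and the maximal-phase-count inequality."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapring import (build_adjacency, classify_trajectory, compute_dtk,
                     find_knees, integrate, kphase_state, max_phases,
                     min_dtk, partition, v_nullcline)
from gapring.phaseplane import NullclineCurve, find_knees_arrays, knee_w_shift


class TestNullcline:
    def test_free_nullcline_two_knees_left_below_right(self, cell):
        c = v_nullcline(0.0, cell)
        assert c.left_knee[1] < c.right_knee[1]
        assert c.left_knee[1] == pytest.approx(-cell.knee_w, abs=1e-6)
        assert c.right_knee[1] == pytest.approx(cell.knee_w, abs=1e-6)
        assert c.left_knee[0] == pytest.approx(cell.v_mid - cell.v_scale,
                                               abs=1e-5)

    def test_depolarizing_current_shifts_curve_up(self, cell):
        c0 = v_nullcline(0.0, cell)
        c1 = v_nullcline(0.07, cell)
        assert np.all(c1.W > c0.W)
        # knee W shifts by exactly the current offset (additive in W)
        assert c1.left_knee[1] - c0.left_knee[1] == pytest.approx(0.07,
                                                                  abs=1e-9)
        assert knee_w_shift(cell, 0.07) == pytest.approx(c1.left_knee[1],
                                                         abs=1e-6)

    def test_monotone_shift_in_current(self, cell):
        knees = [v_nullcline(i, cell).left_knee[1]
                 for i in (-0.1, -0.03, 0.0, 0.05, 0.2)]
        assert np.all(np.diff(knees) > 0)

    def test_narrow_range_raises(self, cell):
        with pytest.raises(ValueError):
            v_nullcline(0.0, cell, v_range=(cell.v_mid + 1.5 * cell.v_scale,
                                            cell.v_mid + 2.0 * cell.v_scale))


class TestFindKnees:
    def test_analytic_cubic_fixture(self):
        """W = V^3 - 3V has knees at V = -+1, W = +-2."""
        V = np.linspace(-3, 3, 4001)
        W = V**3 - 3 * V
        left, right = find_knees_arrays(V, W)
        assert left[0] == pytest.approx(1.0, abs=1e-4)
        assert left[1] == pytest.approx(-2.0, abs=1e-6)
        assert right[0] == pytest.approx(-1.0, abs=1e-4)
        assert right[1] == pytest.approx(2.0, abs=1e-6)

    def test_matches_brute_force_grid_extrema(self, cell):
        c = v_nullcline(0.0, cell, n=40001)
        # brute-force oracle: argmin/argmax of W restricted to the
        # interior fold region
        inner = (c.V > cell.v_mid - 2 * cell.v_scale) & \
                (c.V < cell.v_mid + 2 * cell.v_scale)
        w_min = c.W[inner].min()
        w_max = c.W[inner].max()
        assert c.left_knee[1] == pytest.approx(w_min, abs=1e-4)
        assert c.right_knee[1] == pytest.approx(w_max, abs=1e-4)

    def test_monotone_curve_rejected(self):
        V = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            find_knees_arrays(V, V**2)


@pytest.fixture(scope="module")
def ap_run(cell, cycle, period):
    net = build_adjacency(24, "complete", 23, g_el=0.12)
    st_ = kphase_state(net, cell, partition(24, [12, 12]), cycle=cycle)
    traj = integrate(net, cell, st_, (0.0, 4.6 * period))
    return net, traj, classify_trajectory(traj)


class TestDTK:
    def test_ip_gives_empty_records(self, cell, cycle, period, ap_run):
        net, traj, label = ap_run
        from gapring.classify import PatternLabel

        ip_label = PatternLabel(
            n_phases=1, group_of_cell=np.zeros(24, int), phi=np.array([]),
            period=label.period, active_duration=1.0, duty_cycle=0.01,
            intra_group_lags=np.zeros(24), symmetric=True)
        assert compute_dtk(traj, ip_label, net, cell) == []

    def test_ap_dtk_positive_inside_domain(self, cell, ap_run):
        """Well inside the stability domain every silent cell stays a
        positive distance above its instantaneous left knee."""
        net, traj, label = ap_run
        recs = compute_dtk(traj, label, net, cell)
        assert len(recs) > 0
        assert min_dtk(recs) > 0

    def test_dtk_shrinks_with_coupling(self, cell, cycle, period):
        vals = {}
        for g in (0.01, 0.12):
            net = build_adjacency(24, "complete", 23, g_el=g)
            st_ = kphase_state(net, cell, partition(24, [12, 12]),
                               cycle=cycle)
            traj = integrate(net, cell, st_, (0.0, 4.6 * period))
            label = classify_trajectory(traj)
            assert label.n_phases == 2
            vals[g] = min_dtk(compute_dtk(traj, label, net, cell))
        assert vals[0.12] < vals[0.01]


class TestMaxPhases:
    def test_boundary_inequality_example(self):
        """T=100, dt=12.6: T/4 - dt < dt, so only 3 phases fit."""
        assert max_phases(100.0, 12.6) == 3

    def test_short_duty_example(self):
        assert max_phases(100.0, 1.0) == 49

    def test_six_phases_feasible_at_one_percent_duty(self):
        assert max_phases(100.0, 1.0) >= 6

    def test_long_active_phase_gives_synchrony_only(self):
        assert max_phases(100.0, 60.0) == 1

    @given(T=st.floats(10.0, 1000.0), dt=st.floats(0.01, 5.0),
           dt2=st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, T, dt, dt2):
        """Non-increasing in dt, non-decreasing in T."""
        lo, hi = sorted((dt, dt2))
        assert max_phases(T, lo) >= max_phases(T, hi)
        assert max_phases(2 * T, dt) >= max_phases(T, dt)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            max_phases(10.0, 0.0)
        with pytest.raises(ValueError):
            max_phases(10.0, 10.0)
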