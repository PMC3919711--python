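"""Single-cell currents, time constants and the network right-hand side."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapring import (CellParams, SynParams, build_adjacency, fast_current,
                     gap_current, gap_current_all, network_rhs,
                     slow_activation, syn_current, tau_w)
from gapring.simulate import silent_branch_state


class TestFastCurrent:
    def test_zero_scale_gives_zero_current(self, cell):
        p = cell.replace(g_fast=1e-12)
        v = np.linspace(-1, 1, 7)
        assert np.allclose(fast_current(v, p), 0.0, atol=1e-10)

    def test_cubic_root_structure(self, cell):
        """-fast_current(V) - W = 0 has 3 roots inside the knee interval of
        W and 1 root outside it (dense-grid root count)."""
        v = np.linspace(cell.v_mid - 3 * cell.v_scale,
                        cell.v_mid + 3 * cell.v_scale, 20001)
        f = -fast_current(v, cell)

        def n_roots(w):
            sgn = np.sign(f - w)
            sgn[sgn == 0] = 1  # grid point exactly on a root
            return int(np.sum(np.abs(np.diff(sgn)) > 0))

        k = cell.knee_w
        assert n_roots(0.0) == 3            # inside (-k, k)
        assert n_roots(0.5 * k) == 3
        assert n_roots(2.0 * k) == 1        # outside
        assert n_roots(-2.0 * k) == 1

    def test_exactly_two_turning_points(self, cell):
        v = np.linspace(cell.v_mid - 2.5 * cell.v_scale,
                        cell.v_mid + 2.5 * cell.v_scale, 10001)
        d = np.diff(fast_current(v, cell))
        flips = np.sum(np.diff(np.sign(d)) != 0)
        assert flips == 2

    def test_nonfinite_voltage_rejected(self, cell):
        with pytest.raises(ValueError):
            fast_current(np.nan, cell)


class TestTauW:
    def test_limits_and_midpoint(self, cell):
        """Depolarized -> 5, hyperpolarized -> 50, midpoint -> 27.5."""
        hi = cell.v_mid + 50 * cell.v_scale
        lo = cell.v_mid - 50 * cell.v_scale
        mid = cell.v_mid + cell.theta_tw * cell.v_scale
        assert tau_w(hi, cell) == pytest.approx(5.0, abs=1e-6)
        assert tau_w(lo, cell) == pytest.approx(50.0, abs=1e-6)
        assert tau_w(mid, cell) == pytest.approx(27.5, abs=1e-9)

    def test_monotone_decreasing_in_v(self, cell):
        v = np.linspace(cell.v_mid - 2 * cell.v_scale,
                        cell.v_mid + 2 * cell.v_scale, 101)
        tw = tau_w(v, cell)
        assert np.all(np.diff(tw) < 0)


class TestGapCurrent:
    def test_equal_potentials_zero(self, cell):
        net = build_adjacency(6, "ring", 2, g_el=0.1)
        V = np.full(6, 0.3)
        for i in range(6):
            assert gap_current(i, V, net.adjacency, 0.1, 2) == pytest.approx(0.0)

    def test_two_cell_example(self):
        """Mutually coupled pair, V=(1,0), g_el=0.1: currents are +-0.1."""
        net = build_adjacency(2, "complete", 1, g_el=0.1)
        V = np.array([1.0, 0.0])
        assert gap_current(1, V, net.adjacency, 0.1, 1) == pytest.approx(0.1)
        assert gap_current(0, V, net.adjacency, 0.1, 1) == pytest.approx(-0.1)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_charge_conservation_any_state(self, seed):
        """Sum over cells of the gap current vanishes for any V, topology."""
        rg = np.random.default_rng(seed)
        N = int(rg.integers(4, 13)) * 2
        n_cc = int(rg.choice([2, 4, N - 1]))
        topo = "complete" if n_cc == N - 1 else "ring"
        net = build_adjacency(N, topo, n_cc, g_el=float(rg.uniform(0, 0.5)))
        V = rg.normal(0, 1, N)
        I = gap_current_all(V, net.adjacency, net.g_el, net.n_cc)
        assert abs(I.sum()) < 1e-12 * max(1.0, np.abs(I).max() * N)

    def test_index_out_of_range(self, cell):
        net = build_adjacency(4, "ring", 2, g_el=0.1)
        with pytest.raises(IndexError):
            gap_current(7, np.zeros(4), net.adjacency, 0.1, 2)


class TestSynCurrent:
    def test_zero_driving_force(self):
        sp = SynParams()
        assert syn_current(10.0, sp.E_syn, sp) == pytest.approx(0.0)

    def test_closed_gate_far_below_threshold(self):
        sp = SynParams()
        i = syn_current(sp.theta_syn - 50 * sp.k_syn, 0.0, sp)
        assert abs(i) < 1e-6 * sp.g_syn

    def test_saturated_gate_value(self):
        """V_pre >> theta, V_post = 0: current = g_syn * E_syn = -0.2."""
        sp = SynParams()
        i = syn_current(sp.theta_syn + 50 * sp.k_syn, 0.0, sp)
        assert i == pytest.approx(sp.g_syn * sp.E_syn, rel=1e-6)


class TestNetworkRhs:
    def test_identical_states_identical_derivatives(self, cell):
        net = build_adjacency(8, "ring", 4, g_el=0.2)
        state = np.concatenate([np.full(8, -0.4), np.full(8, 0.1)])
        d = network_rhs(0.0, state, net, cell)
        assert np.allclose(d[:8], d[0])
        assert np.allclose(d[8:], d[8])

    def test_single_cell_matches_uncoupled_equations(self, cell):
        from gapring import single_cell_net

        net = single_cell_net()
        v, w = -0.45, 0.05
        d = network_rhs(0.0, np.array([v, w]), net, cell)
        dv_expect = (-fast_current(v, cell) - w) / cell.tau_m
        dw_expect = (slow_activation(v, cell) - w) / tau_w(v, cell)
        assert d[0] == pytest.approx(float(dv_expect), rel=1e-12)
        assert d[1] == pytest.approx(float(dw_expect), rel=1e-12)

    def test_ring_rotation_equivariance(self, cell, rng):
        """Rotating cell labels commutes with the right-hand side."""
        N = 12
        net = build_adjacency(N, "ring", 4, g_el=0.15)
        V = rng.normal(0, 0.4, N)
        W = rng.normal(0, 0.2, N)
        state = np.concatenate([V, W])
        d = network_rhs(0.0, state, net, cell)
        shift = 5
        rot = np.concatenate([np.roll(V, shift), np.roll(W, shift)])
        d_rot = network_rhs(0.0, rot, net, cell)
        assert np.allclose(d_rot[:N], np.roll(d[:N], shift), atol=1e-12)
        assert np.allclose(d_rot[N:], np.roll(d[N:], shift), atol=1e-12)

    def test_finite_difference_consistency(self, cell):
        """rhs matches (state(t+h)-state(t))/h of a high-accuracy solve."""
        from scipy.integrate import solve_ivp

        net = build_adjacency(4, "ring", 2, g_el=0.1)
        y0 = np.concatenate([silent_branch_state(cell)[:1].repeat(4) +
                             np.linspace(0, 0.05, 4),
                             np.full(4, 0.0)])
        d0 = network_rhs(0.0, y0, net, cell)
        h = 1e-4
        sol = solve_ivp(network_rhs, (0, h), y0, args=(net, cell),
                        rtol=1e-12, atol=1e-12)
        fd = (sol.y[:, -1] - y0) / h
        assert np.allclose(fd, d0, rtol=5e-3, atol=1e-8)

    def test_dimension_mismatch(self, cell):
        net = build_adjacency(4, "ring", 2, g_el=0.1)
        with pytest.raises(ValueError):
            network_rhs(0.0, np.zeros(6), net, cell)


def test_cell_params_invariants():
    with pytest.raises(ValueError):
        CellParams(tau_w_min=-1.0)
    with pytest.raises(ValueError):
        CellParams(tau_w_max=4.0)  # below tau_w_min
    with pytest.raises(ValueError):
        CellParams(g_fast=0.0)
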