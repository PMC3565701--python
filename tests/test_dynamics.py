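"""Integration, attractor detection, scans, hysteresis and graded roots."""

import math
from dataclasses import replace

import numpy as np
import pytest

import acdcmotif as ac
from acdcmotif.circuit import _sigma_of
from acdcmotif.dynamics import _refined_peak_times


class TestIntegrate:
    def test_constant_at_zero_signal(self, fig2a):
        traj = ac.integrate(fig2a, 0.0, t_end=30.0)
        assert np.allclose(traj.y, traj.y[0], atol=1e-9)
        assert traj.events == []

    def test_sequential_activation_into_b2(self, fig2a):
        # just above the switch: P active first, then O, finally N
        traj = ac.integrate(fig2a, 1.6, t_end=60.0)
        t_half = {}
        for i, name in enumerate(traj.names):
            above = np.flatnonzero(traj.y[:, i] > 0.4 * traj.y[:, i].max())
            t_half[name] = traj.t[above[0]]
        assert t_half["P"] < t_half["O"] < t_half["N"]
        expected = ac.branch_value("B2", 1.6, fig2a).to_array()
        assert np.allclose(traj.final_state, expected, atol=1e-6)

    def test_cycle_visits_genes_in_repressilator_order(self, fig2b_cycle):
        # inside the gap: activation of O is followed by N, then P, then O...
        traj = fig2b_cycle
        window = traj.t >= 400.0
        tw, yw = traj.t[window], traj.y[window]
        peaks = {name: _refined_peak_times(tw, yw[:, i], prominence=0.1)
                 for i, name in enumerate(traj.names)}
        o_peaks = peaks["O"]
        mid = (o_peaks[2], o_peaks[3])
        n_peak = peaks["N"][(peaks["N"] > mid[0]) & (peaks["N"] < mid[1])]
        p_peak = peaks["P"][(peaks["P"] > mid[0]) & (peaks["P"] < mid[1])]
        assert len(n_peak) == 1 and len(p_peak) == 1
        assert mid[0] < n_peak[0] < p_peak[0] < mid[1]

    def test_event_times_recorded(self, fig2b_cycle):
        assert len(fig2b_cycle.events) > 50
        times = [e["time"] for e in fig2b_cycle.events]
        assert times == sorted(times)

    def test_linear_subdynamics_between_events(self, fig2b):
        """Between switching events O and N relax exponentially."""
        traj = ac.integrate(fig2b, 1.7, t_end=40.0, rtol=1e-10, atol=1e-13)
        d = fig2b.drive(1.7)
        event_times = [0.0] + [e["time"] for e in traj.events] + [40.0]
        checked = 0
        for lo, hi in zip(event_times[:-1], event_times[1:]):
            inside = np.flatnonzero((traj.t > lo + 1e-9) & (traj.t < hi - 1e-9))
            if len(inside) < 3:
                continue
            i0 = inside[0]
            t0, x0 = traj.t[i0], traj.y[i0]
            sigma = _sigma_of(x0, fig2b)     # frozen configuration
            bP, bO, bN = sigma
            prod_O = fig2b.beta * d * bN
            prod_N = fig2b.gamma * d * bP * bO
            for i in inside[1:]:
                dt = traj.t[i] - t0
                o_exact = prod_O / fig2b.k2 + (x0[1] - prod_O / fig2b.k2) \
                    * math.exp(-fig2b.k2 * dt)
                n_exact = prod_N / fig2b.k3 + (x0[2] - prod_N / fig2b.k3) \
                    * math.exp(-fig2b.k3 * dt)
                assert traj.y[i, 1] == pytest.approx(o_exact, abs=1e-8)
                assert traj.y[i, 2] == pytest.approx(n_exact, abs=1e-8)
                checked += 1
        assert checked > 50

    def test_steep_hill_approaches_threshold_trajectories(self, fig2a):
        """h = 200 graded trajectories track the threshold model except in
        short windows around switching events."""
        sharp = fig2a.with_mode("graded", h3=200.0, h4=200.0, h5=200.0)
        thr = ac.integrate(fig2a, 2.0, t_end=15.0, rtol=1e-10, atol=1e-13)
        smooth = ac.integrate(sharp, 2.0, t_end=15.0, rtol=1e-10, atol=1e-13)
        event_times = np.array([e["time"] for e in thr.events])
        scale = np.array([fig2a.P_max, fig2a.O_max, fig2a.N_max])
        y_smooth = np.column_stack([
            np.interp(thr.t, smooth.t, smooth.y[:, i]) for i in range(3)])
        away = np.ones(len(thr.t), dtype=bool)
        for te in event_times:
            away &= np.abs(thr.t - te) > 0.3
        rel_err = np.max(np.abs(thr.y[away] - y_smooth[away]) / scale)
        assert rel_err < 0.01

    def test_nonnegativity_and_boundedness(self, sampled_params):
        rng = np.random.default_rng(5)
        for params in sampled_params[:8]:
            caps = np.array([params.P_max, params.O_max, params.N_max])
            init = rng.uniform(0.0, 1.5, 3) * caps
            S = float(rng.uniform(0.0, 10.0))
            traj = ac.integrate(params, S, init=init, t_end=30.0)
            assert np.min(traj.y) > -1e-9
            bound = np.maximum(init, caps) * (1.0 + 1e-6)
            assert np.all(traj.y <= bound + 1e-9)

    def test_input_validation(self, fig2a):
        with pytest.raises(ValueError):
            ac.integrate(fig2a, 1.0, t_end=0.0)
        with pytest.raises(ValueError):
            ac.integrate(fig2a, -1.0)
        with pytest.raises(ValueError):
            ac.integrate(fig2a, 1.0, init=[1.0, -2.0, 0.0])
        with pytest.raises(TypeError):
            ac.integrate(object(), 1.0)


class TestDetectAttractor:
    def test_fixed_point_matches_branch_b2(self, fig2a):
        traj = ac.integrate(fig2a, 5.0, t_end=120.0)
        summ = ac.detect_attractor(traj)
        assert summ.type == "fixed_point"
        assert np.allclose(summ.state,
                           ac.branch_value("B2", 5.0, fig2a).to_array(),
                           atol=1e-7)
        assert summ.residual < 1e-8

    def test_zero_signal_zero_amplitude(self, fig3a):
        traj = ac.integrate(fig3a, 0.0, t_end=60.0)
        summ = ac.detect_attractor(traj)
        assert summ.type == "fixed_point"
        assert summ.amplitude < 1e-12

    def test_limit_cycle_in_the_gap(self, fig2b_cycle):
        summ = ac.detect_attractor(fig2b_cycle)
        assert summ.type == "limit_cycle"
        assert summ.period is not None and summ.period > 0.0
        o_min, o_max = summ.extrema["O"]
        assert o_max > o_min

    def test_cycle_periods_converged(self, fig2b_cycle):
        """Oscillations, when they exist, are simple and periodic."""
        summary = ac.detect_attractor(fig2b_cycle)
        assert summary.type == "limit_cycle"
        assert summary.period_spread < 5e-3
        # one peak per variable per cycle: P, O and N peak counts agree
        traj = fig2b_cycle
        window = traj.t >= 250.0
        counts = {name: len(_refined_peak_times(traj.t[window],
                                                traj.y[window, i],
                                                prominence=0.05))
                  for i, name in enumerate(traj.names)}
        assert len(set(counts.values())) == 1


class TestScans:
    def test_fig2a_scan_has_no_cycles_and_one_transition(self, fig2a):
        table = ac.scan_bifurcation(fig2a, np.linspace(0.0, 4.0, 41),
                                    t_end=120.0)
        assert table.oscillatory_interval is None
        frame = table.frame
        # O dominance appears then disappears once: O_ss rises then drops to 0
        o_on = (frame.O_ss > 1e-6).astype(int).to_numpy()
        assert np.sum(np.abs(np.diff(o_on))) == 2

    def test_fig2b_scan_block_covers_analytic_gap(self, fig2b):
        grid = np.linspace(1.0, 2.6, 33)
        table = ac.scan_bifurcation(fig2b, grid, t_end=300.0)
        lo, hi = table.oscillatory_interval
        gap = ac.oscillation_gap(fig2b)
        step = grid[1] - grid[0]
        # the cycle is born exactly where B1 is lost ...
        assert abs(lo - gap[0]) <= step + 1e-9
        # ... spans the whole no-steady-state gap, and (from the pre-signal
        # initial state) persists a little beyond it while B2 already
        # exists, before the B2 basin captures the cells
        assert hi >= gap[1] - step
        assert hi < grid[-1]
        # contiguity of the cycle block
        osc = (table.frame.attractor_type == "limit_cycle").to_numpy()
        assert np.sum(np.abs(np.diff(osc.astype(int)))) == 2

    def test_grid_refinement_stable(self, fig2b):
        coarse = np.linspace(1.2, 2.2, 21)
        fine = np.linspace(1.2, 2.2, 41)
        lo_c, hi_c = ac.scan_bifurcation(fig2b, coarse,
                                         t_end=300.0).oscillatory_interval
        lo_f, hi_f = ac.scan_bifurcation(fig2b, fine,
                                         t_end=300.0).oscillatory_interval
        step = coarse[1] - coarse[0]
        assert abs(lo_c - lo_f) <= step + 1e-9
        assert abs(hi_c - hi_f) <= step + 1e-9

    def test_rejects_unsorted_grid(self, fig2a):
        with pytest.raises(ValueError):
            ac.scan_bifurcation(fig2a, [1.0, 0.5, 2.0])


class TestHysteresis:
    def test_fig2a_up_down_asymmetry(self, fig2a):
        res = ac.sweep_hysteresis(fig2a, 3.0, n_steps=151)
        step = 3.0 / 150
        up = [s for s, frm, _ in res.up_transitions if frm == "B1"]
        down = [s for s, _, to in res.down_transitions if to == "B1"]
        assert up and down
        assert abs(up[0] - 1.5) <= step + 1e-9
        assert abs(down[0] - 27.0 / 23.0) <= step + 1e-9
        assert up[0] > down[0]

    def test_fig3a_passes_through_coexpression(self, fig3a):
        res = ac.sweep_hysteresis(fig3a, 2.0, n_steps=151)
        step = 2.0 / 150
        b1_to_b3 = [s for s, frm, to in res.up_transitions
                    if frm == "B1" and to == "B3"]
        into_b2 = [s for s, frm, to in res.up_transitions if to == "B2"]
        assert b1_to_b3 and abs(b1_to_b3[0] - 0.39439) <= step + 1e-4
        assert into_b2 and abs(into_b2[0] - 1.0) <= 2 * step + 1e-9


class TestGradedFixedPoints:
    def test_unique_presignal_root(self):
        graded = ac.load_preset("fig4a")
        roots = ac.find_fixed_points_graded(graded, 0.0)
        assert len(roots) == 1
        assert roots[0].stable
        assert np.allclose(roots[0].state, [5.0, 0.0, 0.0], atol=1e-8)

    def test_unstable_focus_inside_oscillatory_range(self):
        fig5b = ac.load_preset("fig5b")
        roots = ac.find_fixed_points_graded(fig5b, 5.0)
        focus = [r for r in roots
                 if np.any((r.eigenvalues.real > 0.0)
                           & (np.abs(r.eigenvalues.imag) > 0.0))]
        assert focus, "expected an unstable focus accompanying the limit cycle"

    def test_steep_hill_roots_approach_threshold_branches(self, fig2a):
        sharp = fig2a.with_mode("graded", h3=200.0, h4=200.0, h5=200.0)
        roots = ac.find_fixed_points_graded(sharp, 1.0)
        stable = [r for r in roots if r.stable]
        assert len(stable) == 1
        expected = ac.branch_value("B1", 1.0, fig2a).to_array()
        assert np.allclose(stable[0].state, expected, atol=1e-3)

    def test_threshold_mode_rejected(self, fig2a):
        with pytest.raises(ValueError):
            ac.find_fixed_points_graded(fig2a, 1.0)


class TestSimulationClassifier:
    def test_matches_analytic_on_presets(self, fig2a, fig2b, fig3a, fig3b):
        for params, expected in [(fig2a, 1), (fig2b, 3), (fig3a, 2),
                                 (fig3b, 4)]:
            sim = ac.classify_regime_by_simulation(params)
            assert sim["possibility"] == expected
            assert not sim["undecided"]
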