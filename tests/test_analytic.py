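"""Closed-form branches, existence criteria and regime classification."""

import math
from dataclasses import replace

import numpy as np
import pytest

import acdcmotif as ac
from acdcmotif.circuit import _rhs, _rhs_sigma, _sigma_of


class TestBranchValues:
    def test_b1_saturated_signal(self, fig2a):
        state = ac.branch_value("B1", 1e12, fig2a)
        assert state.O == pytest.approx(5.0, rel=1e-10)
        assert state.P == pytest.approx(5.0 / 26.0, rel=1e-9)
        assert state.N == 0.0

    def test_b2_at_S_five(self, fig2a):
        state = ac.branch_value("B2", 5.0, fig2a)
        assert state.N == pytest.approx(25.0 / 6.0)
        assert state.P == pytest.approx(5.0 / (1.0 + (25.0 / 6.0 / 0.9) ** 2))
        assert state.O == 0.0

    def test_b1_zero_signal_is_presignal_state(self, sampled_params):
        for params in sampled_params[:10]:
            state = ac.branch_value("B1", 0.0, params)
            assert (state.P, state.O, state.N) == (params.P_max, 0.0, 0.0)

    def test_unknown_label_rejected(self, fig2a):
        with pytest.raises(ValueError):
            ac.branch_value("B4", 1.0, fig2a)

    def test_graded_mode_rejected(self, fig2a):
        with pytest.raises(ValueError):
            ac.branch_value("B1", 1.0, fig2a.with_mode("graded"))


class TestExistence:
    def test_b1_lost_once_O_passes_crossover(self, fig2a):
        # O reaches O_crit (P_max/P_crit1 - 1)^(1/h2) = 3 at S = 1.5
        assert ac.branch_exists("B1", 1.0, fig2a)
        assert not ac.branch_exists("B1", 2.0, fig2a)

    def test_zero_residual_wherever_branch_exists(self, sampled_params):
        rng = np.random.default_rng(42)
        checked = 0
        for params in sampled_params:
            for S in rng.uniform(0.0, 20.0, 25):
                for label in ac.existing_branches(S, params):
                    state = ac.branch_value(label, S, params)
                    res = np.max(np.abs(_rhs(state.to_array(), S, params)))
                    assert res < 1e-10
                    checked += 1
        assert checked > 200

    def test_b2_b3_exclusive(self, sampled_params):
        rng = np.random.default_rng(1)
        for params in sampled_params:
            for S in rng.uniform(0.0, 30.0, 25):
                assert not (ac.branch_exists("B2", S, params)
                            and ac.branch_exists("B3", S, params))

    def test_b2_persists_once_attained(self, sampled_params):
        for params in sampled_params[:15]:
            d_grid = np.linspace(0.01, 0.999, 300)
            exists = [ac.branch_exists("B2", ac.signal_at_drive(d), params)
                      for d in d_grid]
            first = exists.index(True) if True in exists else len(exists)
            assert all(exists[first:])

    def test_stable_node_eigenvalues(self, fig2a):
        # inside a fixed Heaviside configuration the Jacobian is triangular
        # with the decay rates on the diagonal
        for label, S in [("B1", 1.0), ("B2", 5.0)]:
            state = ac.branch_value(label, S, fig2a).to_array()
            sigma = _sigma_of(state, fig2a)
            jac = np.empty((3, 3))
            for j in range(3):
                h = 1e-7
                xp, xm = state.copy(), state.copy()
                xp[j] += h
                xm[j] -= h
                jac[:, j] = (_rhs_sigma(xp, S, fig2a, sigma)
                             - _rhs_sigma(xm, S, fig2a, sigma)) / (2 * h)
            eig = np.sort(np.linalg.eigvals(jac).real)
            assert np.allclose(eig, sorted(ac.SteadyStateBranch(label, fig2a)
                                           .eigenvalues), atol=1e-6)


class TestValidity:
    def test_fig2a_passes_all(self, fig2a):
        assert ac.validity_conditions(fig2a).all_pass

    def test_fig3b_passes_all(self, fig3b):
        assert ac.validity_conditions(fig3b).all_pass

    def test_low_alpha_fails_first_condition(self, fig2a):
        bad = replace(fig2a, alpha=0.4)    # alpha < k1 P_crit1 = 0.5
        report = ac.validity_conditions(bad)
        assert not report.all_pass
        assert "i_N_silent_at_zero_signal" in report.failures()

    def test_report_serializes(self, fig2a):
        frame = ac.validity_conditions(fig2a).to_frame()
        assert set(frame.condition) == {
            "i_N_silent_at_zero_signal", "ii_B1_eventually_lost",
            "iii_B2_attained", "iv_O_never_represses_N"}
        assert frame.passed.all()


class TestRoutesAndGaps:
    def test_routes_of_presets(self, fig2a, fig3a):
        assert ac.classify_route(fig2a) == "route1"
        assert ac.classify_route(fig3a) == "route2"

    def test_invalid_parameters_flagged(self, fig2a):
        assert ac.classify_route(replace(fig2a, alpha=0.4)) == "invalid"

    def test_fig3b_transition_signals(self, fig3b):
        crit = ac.critical_signals(fig3b)
        # B1 is lost when O reaches sqrt(2): d = sqrt(2)/5, S ~ 0.394
        d = math.sqrt(2.0) / 5.0
        assert crit["S_B1_loss"] == pytest.approx(d / (1 - d), rel=1e-12)
        assert ac.classify_route(fig3b) == "route2"

    def test_fig2_gap_and_overlap(self, fig2a, fig2b):
        # N_crit = 0.9: N_max/N_crit > O_max/O_crit, bistable overlap
        assert ac.oscillation_gap(fig2a) is None
        label = ac.classify_regime(fig2a)
        assert label.bistable_overlap == pytest.approx((27.0 / 23.0, 1.5))
        # N_crit = 1.1 flips the inequality and opens a gap
        gap = ac.oscillation_gap(fig2b)
        assert gap == pytest.approx((1.5, 33.0 / 17.0))

    def test_fig3_gap(self, fig3a, fig3b):
        assert ac.oscillation_gap(fig3a) is None
        gap = ac.oscillation_gap(fig3b)
        # opens where N = N_crit1 (S = 1), closes where N reaches 2 sqrt(2)
        assert gap[0] == pytest.approx(1.0)
        d_end = 2.0 * math.sqrt(2.0) / 4.0
        assert gap[1] == pytest.approx(d_end / (1 - d_end))

    def test_printed_condition_forms_as_special_cases(self, sampled_params):
        """The implemented predicates reduce to the printed inequalities."""
        for params in sampled_params:
            label = ac.classify_regime(params)
            has_gap = label.oscillation_interval is not None
            if label.route == 1 and params.h1 == params.h2:
                ratio_condition = (params.N_max / params.N_crit
                                   < params.O_max / params.O_crit)
                # the N_crit1 part of B2 existence can postpone B2 further;
                # the printed form is the pure repression-strength case
                n_dagger = params.N_crit * (params.P_max / params.P_crit1
                                            - 1.0) ** (1.0 / params.h1)
                if n_dagger >= params.N_crit1:
                    assert has_gap == ratio_condition
            if label.route == 2:
                printed = (params.P_max / params.P_crit1
                           > 1.0 + (params.N_crit1 / params.N_crit) ** params.h1)
                assert has_gap == printed

    def test_four_possibilities_of_the_presets(self, fig2a, fig2b, fig3a,
                                               fig3b):
        assert ac.classify_regime(fig2a).possibility == 1
        assert ac.classify_regime(fig2b).possibility == 3
        assert ac.classify_regime(fig3a).possibility == 2
        assert ac.classify_regime(fig3b).possibility == 4

    def test_route_possibility_consistency(self, sampled_params):
        for params in sampled_params:
            label = ac.classify_regime(params)
            if label.possibility in (1, 3):
                assert label.route == 1
            else:
                assert label.route == 2
            has_gap = label.oscillation_interval is not None
            assert has_gap == (label.possibility in (3, 4))

    def test_acdc_reduction_invariance(self, sampled_params):
        """Removing the O-on-N repression never changes the regime."""
        for params in sampled_params:
            reduced = replace(params, O_crit1=1e9)
            assert (ac.classify_regime(params).possibility
                    == ac.classify_regime(reduced).possibility)

    def test_invalid_regime_reports_failures(self, fig2a):
        label = ac.classify_regime(replace(fig2a, alpha=0.4))
        assert label.route == "invalid"
        assert label.possibility is None
        assert label.failures

    def test_regime_serializes(self, fig2b):
        payload = ac.classify_regime(fig2b).to_dict()
        assert payload["possibility"] == 3
        assert payload["oscillation_interval"] is not None
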