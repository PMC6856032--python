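"""State space, strategy construction, and matrix decorations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stratcea as sc
from stratcea.pathways import (
    HealthState,
    STATES,
    deterministic_matrix,
    apply_clz_intolerance,
)

HS = HealthState


def assert_row_stochastic(tm):
    assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(tm.matrix >= -1e-12)


class TestStateSpace:
    def test_eleven_states_with_consistent_flags(self):
        assert len(STATES) == 11
        assert HS.DEAD.alive is False
        assert HS.STABLE_CLZ.on_clozapine and HS.RELAPSE_CLZ.on_clozapine
        assert not HS.STABLE_AP.on_clozapine
        on_clz = [s for s in STATES if s.on_clozapine]
        assert set(on_clz) == {HS.STABLE_CLZ, HS.RELAPSE_CLZ}
        assert HS.RELAPSE_AP.in_relapse and not HS.STABLE_AP.in_relapse

    def test_dead_row_must_be_absorbing(self):
        m = np.eye(11)
        i = STATES.index(HS.DEAD)
        j = STATES.index(HS.STABLE_AP)
        m[i, i], m[i, j] = 0.0, 1.0
        with pytest.raises(sc.ValidationError, match="absorbing"):
            sc.TransitionMatrix(states=STATES, matrix=m)

    def test_non_stochastic_rows_rejected(self):
        m = np.eye(11)
        m[0, 0] = 0.9
        with pytest.raises(sc.ValidationError, match="sums to"):
            sc.TransitionMatrix(states=STATES, matrix=m)


class TestStrategyWeights:
    def test_tau_strata_are_the_subgroup_prevalences(self, base_case):
        strata = sc.build_strategy(sc.TAU, base_case)
        weights = {s.label: s.weight for s in strata}
        assert weights["ap2_responder"] == pytest.approx(0.1667)
        assert weights["clz_responder"] == pytest.approx(0.6250)
        assert weights["nonresponder"] == pytest.approx(0.2083)

    def test_sma_test_class_margins_match_worked_example(self, base_case):
        strata = sc.build_strategy(sc.SMA, base_case)
        by_class = {}
        for s in strata:
            by_class[s.test_class] = by_class.get(s.test_class, 0.0) + s.weight
        assert by_class["tp"] == pytest.approx(0.1000, abs=5e-5)
        assert by_class["tn"] == pytest.approx(0.5000, abs=5e-5)
        assert by_class["fp"] == pytest.approx(0.3333, abs=5e-5)
        assert by_class["fn"] == pytest.approx(0.0667, abs=5e-5)

    @pytest.mark.parametrize("strategy", [sc.TAU, sc.SMA])
    def test_weights_sum_to_one(self, base_case, strategy):
        strata = sc.build_strategy(strategy, base_case)
        assert sum(s.weight for s in strata) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_strategy_rejected(self, base_case):
        with pytest.raises(sc.ValidationError, match="strategy"):
            sc.build_strategy("USUAL_CARE", base_case)

    def test_test_cost_charged_only_under_sma(self, base_case):
        assert all(s.cycle0_cost == 0.0 for s in sc.build_strategy(sc.TAU, base_case))
        assert all(
            s.cycle0_cost == base_case.cost_test
            for s in sc.build_strategy(sc.SMA, base_case)
        )

    def test_perfect_test_routes_ap2_exactly_like_tau(self, perfect_test):
        tau = {s.label: s for s in sc.build_strategy(sc.TAU, perfect_test)}
        sma = {s.label: s for s in sc.build_strategy(sc.SMA, perfect_test)}
        assert set(sma) == {"tp_ap2_responder", "tn_clz_responder", "tn_nonresponder"}
        np.testing.assert_allclose(
            sma["tp_ap2_responder"].matrix.matrix, tau["ap2_responder"].matrix.matrix
        )
        # everyone else starts clozapine at cycle 0
        assert sma["tn_clz_responder"].initial_state is HS.STABLE_CLZ
        assert sma["tn_nonresponder"].initial_state is HS.RELAPSE_CLZ


class TestDecorations:
    def test_zero_nonadherence_leaves_matrix_unchanged(self, base_case):
        p = base_case.replace(nonadherence_probs={"ap": 0.0, "clz": 0.0})
        tm = deterministic_matrix({}, label="t")
        out = sc.apply_nonadherence(tm, p, HS.STABLE_AP)
        np.testing.assert_array_equal(out.matrix, tm.matrix)

    def test_nonadherence_entries_direct_construction(self, base_case):
        p = base_case.replace(
            nonadherence_probs={"ap": 0.2, "clz": 0.2}, p_relapse_if_nonadherent=0.5
        )
        out = sc.apply_nonadherence(deterministic_matrix({}, label="t"), p, HS.STABLE_AP)
        i = out.index(HS.STABLE_AP)
        j = out.index(HS.STABLE_NONADHERENT)
        k = out.index(HS.RELAPSE_NONADHERENT)
        assert out.matrix[i, j] == pytest.approx(0.2)
        assert out.matrix[j, k] == pytest.approx(0.5)
        assert out.matrix[k, i] == pytest.approx(1.0)
        assert_row_stochastic(out)

    def test_clozapine_default_nonadherence_below_conventional(self, base_case):
        assert (
            base_case.nonadherence_probs["clz"] < base_case.nonadherence_probs["ap"]
        )

    def test_zero_mortality_leaves_matrix_unchanged(self, base_case):
        p = base_case.replace(**{"mortality.p_death": 0.0})
        tm = deterministic_matrix({}, label="t")
        np.testing.assert_array_equal(sc.apply_mortality(tm, p).matrix, tm.matrix)

    def test_clozapine_mortality_multiplier_applied(self, base_case):
        p = base_case.replace(
            **{"mortality.p_death": 0.01, "mortality.clz_multiplier": 0.6}
        )
        out = sc.apply_mortality(deterministic_matrix({}, label="t"), p)
        i_dead = out.index(HS.DEAD)
        assert out.matrix[out.index(HS.STABLE_CLZ), i_dead] == pytest.approx(0.006)
        assert out.matrix[out.index(HS.STABLE_AP), i_dead] == pytest.approx(0.01)
        # dead row stays identity
        assert out.matrix[i_dead, i_dead] == 1.0
        assert_row_stochastic(out)

    def test_intolerance_branch_reaches_destination(self, base_case):
        p = base_case.replace(p_clz_intolerance=0.1)
        out = apply_clz_intolerance(
            deterministic_matrix({}, label="t"), p, HS.STABLE_POSTCLZ_AP
        )
        assert out.matrix[out.index(HS.STABLE_CLZ), out.index(HS.CLZ_SWITCHING)] == pytest.approx(0.1)
        assert out.matrix[out.index(HS.CLZ_SWITCHING), out.index(HS.STABLE_POSTCLZ_AP)] == 1.0

    @given(seed=st.integers(0, 10_000))
    def test_matrices_stay_row_stochastic_under_fuzzed_parameters(self, base_case, seed):
        p = sc.perturb(base_case, seed=seed, scale=0.5)
        for strategy in (sc.TAU, sc.SMA):
            for stratum in sc.build_strategy(strategy, p):
                assert_row_stochastic(stratum.matrix)


class TestRewards:
    def test_zero_ae_probabilities_leave_reward_unchanged(self, base_case):
        p = base_case.replace(
            adverse_event_probs={"ap": {}, "clz": {}}, clz_monitoring_cost=0.0
        )
        r = sc.StateReward(1000.0, 0.8)
        assert sc.apply_adverse_events(r, HS.STABLE_AP, p) == r

    def test_expected_value_arithmetic(self, base_case):
        p = base_case.replace(
            adverse_event_probs={"ap": {"weight_gain": 0.1}, "clz": {}},
            ae_utility_decrements={"weight_gain": 0.05},
            ae_costs={"weight_gain": 0.0},
        )
        r = sc.apply_adverse_events(sc.StateReward(0.0, 0.8), HS.STABLE_AP, p)
        assert r.annual_utility == pytest.approx(0.8 - 0.005)

    def test_neutropenia_burden_is_clozapine_only(self, base_case):
        rewards = sc.build_rewards(base_case)
        # monitoring + neutropenia load the clozapine stable state only
        extra_clz = rewards[HS.STABLE_CLZ].annual_cost - base_case.cost_remission_year
        extra_ap = rewards[HS.STABLE_AP].annual_cost - base_case.cost_remission_year
        neutropenia_cost = (
            base_case.adverse_event_probs["clz"]["neutropenia"]
            * base_case.ae_costs["neutropenia"]
        )
        assert extra_clz >= base_case.clz_monitoring_cost + neutropenia_cost
        assert "neutropenia" not in base_case.adverse_event_probs["ap"]
        assert extra_ap < base_case.clz_monitoring_cost

    def test_utility_clamped_at_zero_with_warning(self, base_case, caplog):
        p = base_case.replace(
            adverse_event_probs={"ap": {"weight_gain": 1.0}, "clz": {}},
            ae_utility_decrements={"weight_gain": 1.0},
            ae_costs={"weight_gain": 0.0},
        )
        with caplog.at_level("WARNING"):
            r = sc.apply_adverse_events(sc.StateReward(0.0, 0.3), HS.STABLE_AP, p)
        assert r.annual_utility == 0.0
        assert any("clamping" in rec.message for rec in caplog.records)


class TestCoreMechanism:
    def test_true_negatives_reach_clozapine_one_cycle_earlier(self, perfect_test):
        """With no competing flows, the clozapine-responder stratum under the
        test-guided strategy occupies stable-on-clozapine from cycle 0; under
        usual care only from cycle 1 — the strategy's entire benefit."""
        p = perfect_test.replace(
            **{
                "mortality.p_death": 0.0,
                "nonadherence_probs": {"ap": 0.0, "clz": 0.0},
                "p_clz_intolerance": 0.0,
            }
        )
        rewards = sc.build_rewards(p)
        tau = {s.label: s for s in sc.build_strategy(sc.TAU, p)}
        sma = {s.label: s for s in sc.build_strategy(sc.SMA, p)}

        def occupancy(stratum):
            solo = dataclasses.replace(stratum, weight=1.0)
            trace = sc.run_cohort([solo], rewards, p.n_cycles, p.discount_rate)
            i = list(trace.states).index(HS.STABLE_CLZ)
            return trace.occupancy[:, i]

        occ_tau = occupancy(tau["clz_responder"])
        occ_sma = occupancy(sma["tn_clz_responder"])
        assert occ_tau[0] == 0.0 and occ_tau[1] == 1.0
        assert occ_sma[0] == 1.0
        np.testing.assert_allclose(occ_sma[:-1], occ_tau[1:])
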