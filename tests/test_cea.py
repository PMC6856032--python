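"""Comparison verdicts, deterministic SA, PSA, and acceptability curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stratcea as sc
from stratcea.cea import (
    VERDICT_ICER,
    VERDICT_SMA_DOMINANT,
    VERDICT_TAU_DOMINANT,
    VERDICT_TIE,
    set_parameter,
)


class TestNetMonetaryBenefit:
    @pytest.mark.parametrize(
        "cost, qaly, wtp, expected",
        [
            (0.0, 0.0, 20000.0, 0.0),
            (502876.0, 16.25, 20000.0, -177876.0),
            (100.0, 2.0, 0.0, -100.0),
        ],
    )
    def test_values(self, cost, qaly, wtp, expected):
        assert sc.net_monetary_benefit(cost, qaly, wtp) == pytest.approx(expected)

    def test_zero_wtp_ranks_by_cost_alone(self):
        assert sc.net_monetary_benefit(100.0, 50.0, 0.0) < sc.net_monetary_benefit(
            99.0, 0.0, 0.0
        )


class TestCompareStrategies:
    def test_reported_basecase_quadrant(self):
        """Cheaper and more effective -> the stratified arm dominates."""
        res = sc.compare_strategies(tau=(510239.0, 16.15), sma=(502876.0, 16.25))
        assert res.verdict == VERDICT_SMA_DOMINANT
        assert res.incremental_cost == pytest.approx(-7363.0)
        assert res.incremental_qaly == pytest.approx(0.10)
        assert res.icer is None

    def test_identical_pairs_tie(self):
        assert sc.compare_strategies((5.0, 1.0), (5.0, 1.0)).verdict == VERDICT_TIE

    def test_icer_quadrant(self):
        res = sc.compare_strategies(tau=(0.0, 0.0), sma=(1000.0, 0.10))
        assert res.verdict == VERDICT_ICER
        assert res.icer == pytest.approx(10000.0)

    def test_tau_dominates_when_sma_costs_more_for_less(self):
        res = sc.compare_strategies(tau=(100.0, 2.0), sma=(200.0, 1.0))
        assert res.verdict == VERDICT_TAU_DOMINANT

    @given(
        shift=st.integers(-10**6, 10**6),
        tau=st.tuples(st.integers(0, 10**6), st.floats(0, 50)),
        sma=st.tuples(st.integers(0, 10**6), st.floats(0, 50)),
    )
    def test_verdict_invariant_to_constant_cost_shift(self, shift, tau, sma):
        # integer costs keep the shifted difference exact in floating point
        base = sc.compare_strategies(tau, sma)
        shifted = sc.compare_strategies(
            (tau[0] + shift, tau[1]), (sma[0] + shift, sma[1])
        )
        assert shifted.verdict == base.verdict


class TestOneWaySA:
    def test_test_cost_slope_is_exactly_one(self, base_case):
        """The test is administered once per SMA patient at cycle 0, so the
        incremental cost rises £1 per £1 of test cost."""
        table = sc.one_way_sa(base_case, "cost_test", (100.0, 1000.0), n_points=4)
        slopes = np.diff(table.incremental_cost) / np.diff(table.value)
        np.testing.assert_allclose(slopes, 1.0, atol=1e-9)

    def test_zero_width_range_gives_single_base_row(self, base_case, base_result):
        table = sc.one_way_sa(base_case, "cost_test", (500.0, 500.0))
        assert len(table) == 1
        assert table.incremental_cost[0] == pytest.approx(base_result.incremental_cost)

    def test_out_of_bounds_range_rejected_upfront(self, base_case):
        with pytest.raises(sc.ValidationError):
            sc.one_way_sa(base_case, "utility_stable", (0.5, 1.5))

    def test_mix_component_sweep_rebalances_proportionally(self, base_case):
        p = set_parameter(base_case, "mix.p_clz", 0.40)
        assert p.mix.p_clz == pytest.approx(0.40)
        total = p.mix.p_ap2 + p.mix.p_clz + p.mix.p_nonresp
        assert total == pytest.approx(1.0, abs=1e-12)
        # remaining components keep their relative proportions
        assert p.mix.p_ap2 / p.mix.p_nonresp == pytest.approx(0.1667 / 0.2083)


class TestTwoWayThreshold:
    def test_threshold_matches_grid_scan(self, base_case):
        thr = sc.two_way_threshold(base_case, sensitivity=0.6, wtp=20000.0)
        from stratcea.cea import _incremental_nmb

        grid = np.linspace(0.0, 1.0, 101)
        f = np.array(
            [
                _incremental_nmb(
                    base_case.replace(
                        **{
                            "stratifier.sensitivity": 0.6,
                            "stratifier.specificity": float(s),
                        }
                    ),
                    20000.0,
                )
                for s in grid
            ]
        )
        first = grid[f >= 0][0]
        assert abs(thr - first) <= 0.01 + 1e-9

    def test_monotone_nmb_in_specificity(self, base_case):
        from stratcea.cea import _incremental_nmb

        values = [
            _incremental_nmb(
                base_case.replace(**{"stratifier.specificity": s}), 20000.0
            )
            for s in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(values) > 0)

    def test_null_benefit_returns_sentinel(self):
        p = sc.make_null_benefit()
        assert sc.two_way_threshold(p, 0.6) == sc.NEVER_PREFERRED

    def test_perfect_model_returns_zero_floor(self, base_case):
        # free, perfectly beneficial test: preferred at any specificity
        p = sc.make_perfect_test().replace(cost_test=0.0)
        assert sc.two_way_threshold(p, 1.0) == 0.0


class TestPSA:
    def test_all_fixed_psa_collapses_to_deterministic(self, base_case, base_result):
        fixed = {k: {"kind": "fixed"} for k in base_case.distributions}
        p = base_case.replace(distributions=fixed)
        psa = sc.run_psa(p, n_iterations=5, seed=11)
        np.testing.assert_allclose(psa.tau_cost, base_result.tau_cost, rtol=1e-12)
        np.testing.assert_allclose(psa.sma_qaly, base_result.sma_qaly, rtol=1e-12)

    def test_same_seed_bitwise_identical_serialization(self, base_case, tmp_path):
        a = sc.run_psa(base_case, n_iterations=20, seed=99)
        b = sc.run_psa(base_case, n_iterations=20, seed=99)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_psa_mean_incremental_near_base_case(self, base_case, base_result):
        """Law of large numbers: the mean PSA incremental QALY approaches the
        deterministic base case (nonlinearity keeps them from being equal,
        so compare within Monte-Carlo error)."""
        psa = sc.run_psa(base_case, n_iterations=400, seed=5)
        dq = psa.sma_qaly - psa.tau_qaly
        se = dq.std(ddof=1) / np.sqrt(psa.iterations)
        assert abs(dq.mean() - base_result.incremental_qaly) < 4 * se

    def test_csv_round_trip(self, base_case, tmp_path):
        psa = sc.run_psa(base_case, n_iterations=10, seed=1)
        path = tmp_path / "psa.csv"
        psa.to_csv(path)
        again = sc.PSAResult.from_csv(path)
        np.testing.assert_allclose(again.tau_cost, psa.tau_cost)
        np.testing.assert_allclose(again.sma_qaly, psa.sma_qaly)


class TestCEAC:
    def test_single_dominant_iteration_gives_probability_one(self):
        psa = sc.PSAResult(
            iterations=1, seed=0,
            tau_cost=np.array([100.0]), tau_qaly=np.array([1.0]),
            sma_cost=np.array([50.0]), sma_qaly=np.array([2.0]),
        )
        ceac = sc.build_ceac(psa, np.array([0.0, 20000.0]))
        np.testing.assert_array_equal(ceac.p_sma, [1.0, 1.0])

    def test_probabilities_partition_at_every_wtp(self, base_case):
        psa = sc.run_psa(base_case, n_iterations=50, seed=2)
        ceac = sc.build_ceac(psa)
        np.testing.assert_allclose(ceac.p_sma + ceac.p_tau, 1.0, atol=1e-12)
        assert np.all((ceac.p_sma >= 0) & (ceac.p_sma <= 1))

    def test_wtp_zero_is_fraction_of_cheaper_draws(self, base_case):
        psa = sc.run_psa(base_case, n_iterations=50, seed=2)
        ceac = sc.build_ceac(psa, np.array([0.0]))
        assert ceac.p_sma[0] == pytest.approx((psa.sma_cost < psa.tau_cost).mean())

    def test_exact_ties_split_equally(self):
        psa = sc.PSAResult(
            iterations=2, seed=0,
            tau_cost=np.array([100.0, 100.0]), tau_qaly=np.array([1.0, 1.0]),
            sma_cost=np.array([100.0, 50.0]), sma_qaly=np.array([1.0, 1.0]),
        )
        ceac = sc.build_ceac(psa, np.array([0.0]))
        assert ceac.p_sma[0] == pytest.approx(0.75)

    def test_empty_grid_rejected(self, base_case):
        psa = sc.run_psa(base_case, n_iterations=2, seed=0)
        with pytest.raises(sc.ValidationError):
            sc.build_ceac(psa, np.array([]))


class TestTornado:
    def test_table_shape_and_swing_ordering(self, base_case):
        ranges = {
            "cost_test": (100.0, 1000.0),
            "utility_relapse": (0.19, 0.604),
        }
        table = sc.tornado(base_case, ranges)
        assert set(table.parameter) == set(ranges)
        assert list(table.swing) == sorted(table.swing, reverse=True)
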