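"""Markov CEA: method-of-moments fits, QALY trapezoid, dominance, PSA, CEAC."""

import numpy as np
import pandas as pd
import pytest

from prpecon.cea import (
    MarkovConfig,
    MarkovEngine,
    StrategySpec,
    ceac,
    classify_icer,
    fit_distribution,
    qaly_trapezoid,
    reference_case,
    run_base_case,
    run_psa,
)


class TestFitDistribution:
    def test_gamma_moment_identities(self):
        d = fit_distribution(100.0, 20.0, "gamma")
        assert d.shape["k"] == pytest.approx(25.0)
        assert d.shape["theta"] == pytest.approx(4.0)
        # analytic mean k*theta and variance k*theta^2
        assert d.shape["k"] * d.shape["theta"] == pytest.approx(100.0)
        assert d.shape["k"] * d.shape["theta"] ** 2 == pytest.approx(400.0)

    def test_beta_moment_identities(self):
        d = fit_distribution(0.5, 0.1, "beta")
        assert d.shape["alpha"] == pytest.approx(12.0)
        assert d.shape["beta"] == pytest.approx(12.0)

    def test_zero_se_is_point_mass(self):
        d = fit_distribution(42.0, 0.0, "gamma")
        rng = np.random.default_rng(0)
        assert np.all(d.rvs(rng, size=100) == 42.0)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError, match="positive mean"):
            fit_distribution(-5.0, 1.0, "gamma")
        with pytest.raises(ValueError, match="se\\^2"):
            fit_distribution(0.5, 0.6, "beta")
        with pytest.raises(ValueError, match="strictly in"):
            fit_distribution(1.5, 0.1, "beta")

    @pytest.mark.parametrize(
        "family,mean,se",
        [("gamma", 327.0, 30.0), ("gamma", 10.0, 2.0), ("beta", 0.85, 0.02), ("beta", 0.3, 0.1)],
    )
    def test_moments_recovered_from_a_million_draws(self, family, mean, se):
        d = fit_distribution(mean, se, family)
        rng = np.random.default_rng(123)
        draws = d.rvs(rng, size=1_000_000)
        n = draws.size
        mc_se_mean = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * mc_se_mean
        # SE of the sample SD ~ sd / sqrt(2(n-1)) for near-normal shapes
        mc_se_sd = draws.std() / np.sqrt(2 * (n - 1))
        assert abs(draws.std() - se) < 5 * mc_se_sd


class TestQALY:
    def test_constant_utility_closed_form(self):
        assert qaly_trapezoid([0, 12], [1.0, 1.0], 12) == pytest.approx(1.0)
        assert qaly_trapezoid([0, 3, 6, 12], [0.7] * 4, 12) == pytest.approx(0.7)

    def test_linear_utility_closed_form(self):
        assert qaly_trapezoid([0, 12], [0.8, 0.9], 12) == pytest.approx(0.85)

    def test_curve_must_cover_horizon(self):
        with pytest.raises(ValueError, match="cover"):
            qaly_trapezoid([0, 6], [0.8, 0.9], 12)


class TestBaseCase:
    def test_reference_case_reproduces_published_totals(self):
        lc, cortico, config = reference_case()
        res = run_base_case(lc, cortico, config)
        assert res.costs[0] == pytest.approx(654.0)
        assert res.costs[1] == pytest.approx(1308.0)
        assert res.qalys[0] == pytest.approx(0.846, abs=1e-9)
        assert res.qalys[1] == pytest.approx(0.708, abs=1e-9)
        assert res.verdict == "dominant"
        assert res.nmb == pytest.approx(100_000 * 0.138 + 654, abs=1e-6)

    def test_zero_cost_perfect_health_year(self):
        strat = StrategySpec(
            "a", (), (0.0, 0.0), utility_by_timepoint=((0, 1.0, 0.0), (12, 1.0, 0.0))
        )
        res = run_base_case(strat, strat, MarkovConfig(seed=0))
        assert res.qalys[0] == pytest.approx(1.0)
        assert res.costs[0] == 0.0
        assert res.verdict == "equivalent"

    def test_base_case_invariant_to_cycle_subdivision(self):
        lc, cortico, _ = reference_case()
        coarse = run_base_case(lc, cortico, MarkovConfig(cycle_months=3.0, seed=0))
        # halve the cycle length; schedules re-indexed to the same calendar months
        lc2 = StrategySpec(
            lc.name, tuple((c * 2, n) for c, n in lc.injection_schedule),
            lc.per_injection_payer_cost, lc.medication_cost, lc.utility_by_timepoint,
        )
        cortico2 = StrategySpec(
            cortico.name, tuple((c * 2, n) for c, n in cortico.injection_schedule),
            cortico.per_injection_payer_cost, cortico.medication_cost,
            cortico.utility_by_timepoint,
        )
        fine = run_base_case(lc2, cortico2, MarkovConfig(cycle_months=1.5, seed=0))
        assert fine.costs == pytest.approx(coarse.costs, abs=1e-9)
        assert fine.qalys == pytest.approx(coarse.qalys, abs=1e-9)

    def test_markov_engine_validates_and_tracks_occupancy(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovEngine(np.array([[0.5, 0.4], [0.0, 1.0]]))
        engine = MarkovEngine(np.array([[0.9, 0.1], [0.0, 1.0]]))
        occ = engine.occupancy(2)
        assert occ[2] == pytest.approx([0.81, 0.19])
        assert engine.alive_fraction(2, alive_states=[0])[2] == pytest.approx(0.81)


class TestClassifyICER:
    def test_published_base_case_is_dominant(self):
        out = classify_icer(-654.0, 0.138, 100_000.0)
        assert out["verdict"] == "dominant"
        assert out["icer"] is None
        assert out["nmb"] == pytest.approx(14454.0)

    def test_textbook_northeast_tradeoff(self):
        out = classify_icer(5000.0, 0.1, 100_000.0)
        assert out["verdict"] == "tradeoff_NE"
        assert out["icer"] == pytest.approx(50_000.0)
        assert out["nmb"] > 0  # cost-effective at this threshold

    def test_equivalence_and_dominated(self):
        assert classify_icer(0.0, 0.0, 1e5)["verdict"] == "equivalent"
        assert classify_icer(100.0, -0.01, 1e5)["verdict"] == "dominated"
        assert classify_icer(-100.0, -0.01, 1e5)["verdict"] == "tradeoff_SW"


class TestPSA:
    def test_degenerate_psa_reproduces_base_case(self):
        lc, cortico, config = reference_case(n_psa=50)
        lc0 = StrategySpec(
            lc.name, lc.injection_schedule, (327.0, 0.0), (0.0, 0.0),
            tuple((m, u, 0.0) for m, u, _ in lc.utility_by_timepoint),
        )
        cortico0 = StrategySpec(
            cortico.name, cortico.injection_schedule, (644.0, 0.0), (10.0, 0.0),
            tuple((m, u, 0.0) for m, u, _ in cortico.utility_by_timepoint),
        )
        res = run_psa(lc0, cortico0, config)
        assert np.allclose(res.psa_delta_cost, res.delta_cost)
        assert np.allclose(res.psa_delta_qaly, res.delta_qaly)
        assert res.prob_dominant in (0.0, 1.0)

    def test_reference_case_dominant_in_every_iteration(self):
        lc, cortico, config = reference_case(seed=1, n_psa=10_000)
        res = run_psa(lc, cortico, config)
        assert res.prob_dominant == 1.0
        assert res.prob_cost_effective == 1.0

    def test_symmetric_strategies_split_quadrants_evenly(self):
        # identical inputs under different names: each CE-plane quadrant ~1/4
        def strat(name):
            return StrategySpec(
                name, ((0, 2),), (300.0, 40.0), (0.0, 0.0),
                ((0.0, 0.7, 0.05), (6.0, 0.8, 0.05), (12.0, 0.8, 0.05)),
            )

        res = run_psa(strat("a"), strat("b"), MarkovConfig(n_psa=10_000, seed=2))
        assert res.prob_dominant == pytest.approx(0.25, abs=0.02)

    def test_prob_dominant_matches_brute_force_quadrant_count(self):
        lc, cortico, config = reference_case(seed=3, n_psa=2_000)
        # widen SEs so the CE plane spans several quadrants
        lc = StrategySpec(
            lc.name, lc.injection_schedule, (327.0, 150.0), (0.0, 0.0),
            lc.utility_by_timepoint,
        )
        res = run_psa(lc, cortico, config)
        brute = np.mean((res.psa_delta_cost < 0) & (res.psa_delta_qaly > 0))
        assert res.prob_dominant == pytest.approx(float(brute), abs=1e-12)
        assert 0.0 < res.prob_dominant < 1.0

    def test_fixed_seed_reproduces_draws(self):
        lc, cortico, config = reference_case(seed=9, n_psa=500)
        a = run_psa(lc, cortico, config)
        b = run_psa(lc, cortico, config)
        assert np.array_equal(a.psa_delta_cost, b.psa_delta_cost)
        assert np.array_equal(a.psa_delta_qaly, b.psa_delta_qaly)


class TestCEAC:
    def test_all_dominant_draws_give_probability_one(self):
        table = ceac(np.array([-100.0, -50.0]), np.array([0.1, 0.2]), [0, 50_000, 100_000])
        assert (table["prob_cost_effective"] == 1.0).all()

    def test_single_draw_steps_at_its_icer(self):
        table = ceac(np.array([5000.0]), np.array([0.1]), [40_000, 60_000])
        assert list(table["prob_cost_effective"]) == [0.0, 1.0]

    def test_matches_brute_force_nmb_counting(self):
        rng = np.random.default_rng(4)
        dc = rng.normal(0, 1000, 500)
        dq = rng.normal(0.05, 0.1, 500)
        grid = [0, 20_000, 100_000]
        table = ceac(dc, dq, grid)
        for w, p in zip(grid, table["prob_cost_effective"]):
            assert p == pytest.approx(np.mean(w * dq - dc > 0), abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ceac(np.array([1.0]), np.array([0.1]), [])

    def test_nondecreasing_when_all_gains_positive(self):
        rng = np.random.default_rng(8)
        dc = rng.normal(0, 500, 400)
        dq = np.abs(rng.normal(0.1, 0.05, 400))
        probs = ceac(dc, dq, list(range(0, 100_001, 5_000)))["prob_cost_effective"]
        assert (np.diff(probs) >= 0).all()
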