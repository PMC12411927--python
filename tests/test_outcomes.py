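"""Paired signed-rank tests, visit summaries, MCID responders, exact power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prpecon.outcomes import (
    PowerSpec,
    exact_binomial_power,
    fisher_exact_power,
    mcid_responders,
    required_sample_size,
    sample_size_both_designs,
    summarize_visit,
    wilcoxon_signed_rank,
)
from prpecon.outcomes import test_all_visits as run_visit_tests


def enumeration_signed_rank_p(diffs):
    """Independent oracle: two-sided exact p by brute-force 2^n sign assignments."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[np.array(diffs) > 0].sum()
    center = ranks.sum() / 2.0
    dev = abs(w_obs - center)
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= dev - 1e-9:
            hits += 1
    return hits / 2**n


class TestWilcoxonSignedRank:
    def test_three_positive_diffs_exact_p(self):
        res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert res.method == "exact"
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([5, 5, 5], [5, 5, 5])
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.n_zero_diffs == 3 and res.n_pairs == 0

    def test_zero_diffs_dropped_before_ranking(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4], [1, 4, 6, 8])
        assert res.n_zero_diffs == 1 and res.n_pairs == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.integers(-50, 50).filter(lambda d: d != 0), min_size=1, max_size=12
        )
    )
    def test_exact_p_matches_full_enumeration(self, diffs):
        base = np.zeros(len(diffs))
        res = wilcoxon_signed_rank(base, np.array(diffs, dtype=float), method="auto")
        expected = enumeration_signed_rank_p(diffs)
        if res.method == "exact":
            assert res.p_value == pytest.approx(expected, abs=1e-12)
        else:  # ties -> seeded permutation; Monte Carlo agreement
            res = wilcoxon_signed_rank(base, np.array(diffs, float), seed=0)
            assert res.p_value == pytest.approx(expected, abs=0.02)

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            diffs = rng.choice(np.arange(1, 40), size=12, replace=False) * rng.choice(
                [-1, 1], size=12
            )
            ours = wilcoxon_signed_rank(np.zeros(12), diffs).p_value
            ref = stats.wilcoxon(diffs, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_converges_to_exact(self):
        rng = np.random.default_rng(11)
        # tie-free n=18: compare exact vs forced normal approximation
        diffs = rng.permutation(np.arange(1, 19)) * np.where(rng.random(18) < 0.35, -1, 1)
        exact = wilcoxon_signed_rank(np.zeros(18), diffs, method="exact").p_value
        approx = wilcoxon_signed_rank(np.zeros(18), diffs, method="normal_approx").p_value
        assert abs(exact - approx) < 0.01

    def test_permutation_used_for_small_tied_samples(self):
        diffs = np.array([1, 1, 2, 2, 3, -1, 4, 4], dtype=float)
        res = wilcoxon_signed_rank(np.zeros(8), diffs, seed=3)
        assert res.method == "permutation"
        assert 0 < res.p_value <= 1

    def test_synthetic_improvement_detected(self, study_cohort):
        tests = run_visit_tests(study_cohort.outcomes, seed=0)
        womac_1m = tests.query("measure=='womac_total' and visit=='1m'").iloc[0]
        assert womac_1m["p"] < 0.05
        assert womac_1m["n"] == 30

    def test_patient_clustering_collapses_bilateral_knees(self, study_cohort):
        tests = run_visit_tests(study_cohort.outcomes, cluster="patient", seed=0)
        # every test pairs the 20 patients; zero differences are dropped from
        # n_pairs but accounted for separately
        assert ((tests["n"] + tests["n_zero_diffs"]) == 20).all()


class TestSummaries:
    def _frame(self, values, visit="baseline"):
        n = len(values)
        return pd.DataFrame(
            {
                "knee_id": [f"k{i}" for i in range(n)],
                "patient_id": [f"p{i}" for i in range(n)],
                "visit": visit,
                "womac_total": values,
                "womac_pain": np.zeros(n),
                "womac_function": np.zeros(n),
                "global_assessment": np.full(n, 50.0),
                "satisfied_with_knee": [True] * n,
                "satisfied_with_procedure": [None] * n,
                "eq5d_utility": np.full(n, 0.8),
            }
        )

    def test_median_and_iqr_closed_form(self):
        s = summarize_visit(self._frame([1, 2, 3, 4, 5]), "baseline")
        assert s["womac_total"]["median"] == 3
        assert s["womac_total"]["iqr"] == 2

    def test_single_record_summary(self):
        s = summarize_visit(self._frame([7]), "baseline")
        assert s["womac_total"] == {"median": 7.0, "iqr": 0.0}

    def test_empty_visit_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            summarize_visit(self._frame([1, 2]), "6m")

    def test_generator_calibration_recovered_at_scale(self, large_cohort):
        s = summarize_visit(large_cohort.outcomes, "baseline")
        assert s["womac_total"]["median"] == pytest.approx(19.5, abs=2.0)
        assert s["womac_total"]["iqr"] == pytest.approx(12.5, abs=3.0)


class TestMCIDResponders:
    def _paired_frame(self, baselines, followups, visit="6m"):
        rows = []
        for i, (b, f) in enumerate(zip(baselines, followups)):
            for v, val in (("baseline", b), (visit, f)):
                rows.append(
                    {
                        "knee_id": f"k{i}", "patient_id": f"p{i}", "visit": v,
                        "womac_total": val, "womac_pain": 0, "womac_function": 0,
                        "global_assessment": 50.0, "satisfied_with_knee": True,
                        "satisfied_with_procedure": None, "eq5d_utility": 0.8,
                    }
                )
        return pd.DataFrame(rows)

    def test_boundary_improvement_counts_as_responder(self):
        df = self._paired_frame([20.0], [13.4])  # improvement exactly 6.6
        out = mcid_responders(df, "6m", mcid=6.6)
        assert out["n_responders"] == 1

    def test_no_change_is_non_responder(self):
        out = mcid_responders(self._paired_frame([20.0], [20.0]), "6m")
        assert out["n_responders"] == 0

    def test_mcid_multiples_from_published_medians(self):
        # median improvement 19.5 - 5.5 = 14.0 -> 2.12 MCID multiples
        df = self._paired_frame([19.5] * 3, [5.5] * 3)
        out = mcid_responders(df, "6m", mcid=6.6)
        assert out["median_mcid_multiples"] == pytest.approx(14.0 / 6.6, abs=5e-3)
        assert round(out["median_mcid_multiples"], 2) == 2.12


class TestExactPower:
    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError, match="p0 == p1"):
            PowerSpec(0.5, 0.5)

    def test_extreme_effect_needs_tiny_sample(self):
        n = required_sample_size(PowerSpec(0.05, 0.95, design="one_sample_exact"))
        assert n <= 5

    def test_power_nondecreasing_in_effect_size(self):
        powers = [exact_binomial_power(25, 0.45, p1, 0.05) for p1 in (0.6, 0.75, 0.9)]
        assert powers == sorted(powers)

    def test_power_grows_with_n_on_coarse_grid(self):
        # discrete exact tests oscillate locally; compare over a coarse grid
        powers = [exact_binomial_power(n, 0.45, 0.9, 0.05) for n in (5, 15, 40)]
        assert powers[0] < powers[1] < powers[2]

    def test_fisher_power_monotone_in_effect(self):
        p_small = fisher_exact_power(15, 0.45, 0.7, 0.05)
        p_big = fisher_exact_power(15, 0.45, 0.9, 0.05)
        assert p_big > p_small

    def test_one_sample_power_is_exact_summation(self):
        # cross-check against direct scipy binomtest rejection counting
        n, p0, p1, alpha = 17, 0.45, 0.9, 0.05
        reject = [
            x for x in range(n + 1) if stats.binomtest(x, n, p0).pvalue <= alpha + 1e-12
        ]
        expected = sum(stats.binom.pmf(x, n, p1) for x in reject)
        assert exact_binomial_power(n, p0, p1, alpha) == pytest.approx(expected, abs=1e-12)

    def test_both_designs_reported_for_study_parameters(self):
        out = sample_size_both_designs(0.45, 0.90, 0.05, 0.80)
        assert out["one_sample_exact_n"] >= 1
        assert out["two_sample_fisher_n_per_group"] >= 2
        # both designs resolve well below the planned 30 knees
        assert out["one_sample_exact_n"] <= 30
        assert out["two_sample_fisher_n_total"] <= 40

    def test_unattainable_power_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            required_sample_size(PowerSpec(0.50, 0.501), n_max=50)
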