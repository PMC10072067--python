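"""Kaplan–Meier, log-rank, t-test, eclosion and count comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from flychrono.survival_stats import (
    count_compare,
    eclosion_stats,
    haemocyte_concentration,
    km_estimate,
    logrank_test,
    median_survival,
    two_sample_t,
)


def brute_force_logrank(da, ea, db, eb):
    """Independent risk-table computation of the two-group log-rank statistic."""
    da, db = np.asarray(da, float), np.asarray(db, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = sorted(set(da[ea]) | set(db[eb]))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        n_a = (da >= t).sum()
        n_b = (db >= t).sum()
        d_a = ((da == t) & ea).sum()
        d_b = ((db == t) & eb).sum()
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - n_a * d / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_product_limit_hand_example(self):
        curve = km_estimate((np.array([1, 2, 3, 4]), np.ones(4, bool)))
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert median_survival(curve) == 2

    def test_all_censored_survival_stays_one(self):
        with pytest.raises(ValueError):
            # no group at all is an error ...
            km_estimate((np.array([]), np.array([], bool)))
        curve = km_estimate((np.array([5.0, 8.0]), np.zeros(2, bool)))
        assert curve.times.size == 0
        assert np.isnan(median_survival(curve))

    def test_censored_fly_leaves_risk_set(self):
        # deaths at 1 and 3, censored at 2: S = 3/4 then 3/8
        curve = km_estimate((np.array([1, 2, 3, 4.0]), np.array([1, 0, 1, 0], bool)))
        np.testing.assert_allclose(curve.survival, [0.75, 0.375])

    @given(
        st.lists(st.integers(1, 40), min_size=2, max_size=40),
    )
    def test_equals_empirical_survival_without_censoring(self, lifespans):
        d = np.array(lifespans, float)
        curve = km_estimate((d, np.ones(d.size, bool)))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((d > t).mean())

    def test_matches_lifelines_with_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        d = rng.exponential(20, 60)
        e = d <= 30
        d = np.minimum(d, 30)
        curve = km_estimate((d, e))
        kmf = lifelines.KaplanMeierFitter().fit(d, e)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref)


class TestMedianSurvival:
    def test_exact_half_plateau_boundary_inclusive(self):
        curve = km_estimate((np.array([1, 21, 21, 30.0]), np.array([1, 1, 1, 0], bool)))
        assert median_survival(curve) == 21

    def test_three_deaths_median_two(self):
        curve = km_estimate((np.array([1, 2, 3.0]), np.ones(3, bool)))
        assert median_survival(curve) == 2

    def test_midpoint_interpolation_on_even_cohort(self):
        # n=4, deaths at 20,20,25,25: S hits exactly 0.5 at 20 -> midpoint 22.5
        curve = km_estimate((np.array([20, 20, 25, 25.0]), np.ones(4, bool)))
        assert median_survival(curve) == 20
        assert median_survival(curve, interpolation="midpoint") == 22.5

    def test_km_median_consistent_on_large_cohort(self):
        rng = np.random.default_rng(17)
        scale = 17 / np.log(2) ** (1 / 4)
        d = scale * rng.weibull(4, 300)
        e = d <= 30
        d = np.minimum(d, 30)
        m = median_survival(km_estimate((d, e)))
        assert m == pytest.approx(17, abs=2)


class TestLogRank:
    def test_identical_groups_null(self):
        g = (np.array([3, 5, 8.0]), np.ones(3, bool))
        res = logrank_test(g, g)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_risk_table(self):
        da, ea = np.array([1, 2.0]), np.ones(2, bool)
        db, eb = np.array([3, 4.0]), np.ones(2, bool)
        res = logrank_test((da, ea), (db, eb))
        assert res.chi_square == pytest.approx(brute_force_logrank(da, ea, db, eb))

    def test_matches_brute_force_with_ties_and_censoring(self):
        rng = np.random.default_rng(2)
        da = rng.integers(1, 15, 25).astype(float)
        db = rng.integers(1, 20, 30).astype(float)
        ea = rng.random(25) < 0.8
        eb = rng.random(30) < 0.8
        res = logrank_test((da, ea), (db, eb))
        assert res.chi_square == pytest.approx(brute_force_logrank(da, ea, db, eb))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        da, db = rng.exponential(17, 28), rng.exponential(24.5, 24)
        ea, eb = da <= 30, db <= 30
        da, db = np.minimum(da, 30), np.minimum(db, 30)
        res = logrank_test((da, ea), (db, eb))
        ref = lifelines.statistics.logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        assert res.chi_square == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        a = (rng.exponential(10, 20), rng.random(20) < 0.8)
        b = (rng.exponential(15, 25), rng.random(25) < 0.8)
        assert logrank_test(a, b).chi_square == pytest.approx(logrank_test(b, a).chi_square)

    def test_invariant_under_monotone_time_rescaling(self):
        rng = np.random.default_rng(4)
        da, db = rng.exponential(10, 20), rng.exponential(20, 20)
        ea = np.ones(20, bool)
        r1 = logrank_test((da, ea), (db, ea))
        r2 = logrank_test((np.sqrt(da), ea), (np.sqrt(db), ea))
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_single_event_time_equals_2x2_score_chi2(self):
        # one death in A at t=1, everyone else censored later
        da, ea = np.array([1.0, 5, 5]), np.array([1, 0, 0], bool)
        db, eb = np.array([5.0, 5, 5]), np.zeros(3, bool)
        res = logrank_test((da, ea), (db, eb))
        # 2x2 score statistic: O=1, E=3/6, V=1*(3/6)(3/6)(5/5)... per formula
        n, n_a, d = 6, 3, 1
        e = n_a * d / n
        v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        assert res.chi_square == pytest.approx((1 - e) ** 2 / v)


class TestTTests:
    def test_student_matches_closed_form(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.0214, abs=1e-3)
        assert res.df == 4

    def test_identical_groups_p_one(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_groups_use_permutation(self):
        res = two_sample_t([50, 50, 50], [80, 80, 80], n_perm=999)
        assert res.method == "permutation"
        assert 0 < res.p_value <= 0.2
        assert res.p_value >= 1 / 1000

    def test_welch_flag(self):
        a = [1.0, 2, 3, 4]
        b = [10.0, 30, 50, 70, 90]
        res = two_sample_t(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestEclosion:
    def test_perfect_survival(self):
        table = pd.DataFrame(
            {"genotype": ["wt"] * 3, "n_input_larvae": [20] * 3, "n_eclosed": [20] * 3}
        )
        summary, _ = eclosion_stats(table)
        assert summary["mean_percent"].iloc[0] == 100.0
        assert summary["sem_percent"].iloc[0] == 0.0

    def test_fifty_vs_eighty_percent_degenerate_groups(self):
        table = pd.DataFrame(
            {
                "genotype": ["mut"] * 3 + ["wt"] * 3,
                "n_input_larvae": [20] * 6,
                "n_eclosed": [10, 10, 10, 16, 16, 16],
            }
        )
        summary, pairwise = eclosion_stats(table)
        means = summary.set_index("genotype")["mean_percent"]
        assert means["mut"] == 50.0 and means["wt"] == 80.0
        row = pairwise.iloc[0]
        assert row["method"] == "permutation"
        assert row["p_value"] < 0.2

    def test_similar_rates_mostly_nonsignificant(self):
        # binomial replicates at 0.88 vs 0.80, 3 vials of 20 larvae
        rng = np.random.default_rng(0)
        nonsig = 0
        n_rep = 50
        for _ in range(n_rep):
            table = pd.DataFrame(
                {
                    "genotype": ["a"] * 3 + ["b"] * 3,
                    "n_input_larvae": [20] * 6,
                    "n_eclosed": np.r_[rng.binomial(20, 0.88, 3), rng.binomial(20, 0.80, 3)],
                }
            )
            _, pairwise = eclosion_stats(table)
            p = pairwise["p_value"].iloc[0]
            nonsig += (not np.isfinite(p)) or p > 0.05
        assert nonsig > n_rep / 2

    def test_eclosed_exceeding_input_rejected(self):
        table = pd.DataFrame(
            {"genotype": ["a"], "n_input_larvae": [20], "n_eclosed": [21]}
        )
        with pytest.raises(ValueError):
            eclosion_stats(table)


class TestCountCompare:
    def test_identical_groups(self):
        table = pd.DataFrame(
            {"genotype": ["a"] * 3 + ["b"] * 3, "value": [1.0, 2, 3, 1, 2, 3]}
        )
        assert count_compare(table, "a", "b").p_value == pytest.approx(1.0)

    def test_haemocytometer_back_calculation(self):
        # 6.45 cells in the chamber, 10 µL + 10 µL trypan-blue dilution
        assert haemocyte_concentration(6.45) == pytest.approx(1.29e5)

    def test_haemocyte_separation_power(self):
        from flychrono.synthetic_data import simulate_counts

        hits = 0
        n_rep = 25
        for i in range(n_rep):
            table = simulate_counts(
                "larva",
                {"R1261C": 3.97e5, "wt": 1.94e5},
                cv=0.3,
                n_per_group={"R1261C": 34, "wt": 30},
                seed=500 + i,
            )
            hits += count_compare(table, "R1261C", "wt").p_value < 1e-4
        assert hits >= 0.95 * n_rep
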