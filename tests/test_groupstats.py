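"""Rank tests, contingency tests, correlations and logistic IRLS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from agr_screen.groupstats import (
    chi_squared_or_fisher,
    compare_groups,
    false_positive_analysis,
    irls_logistic,
    logistic_fit,
    mann_whitney_u,
    spearman,
)
from agr_screen.synthetic import CohortSpec, default_table1_spec, generate_cohort

from conftest import build_cohort


def fisher_oracle(table):
    """Two-sided Fisher p by enumeration over all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # tables no more probable than the observed (relative fp-tolerance)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        # exact two-sided p for complete separation at 3 vs 3
        assert p == pytest.approx(0.1, abs=1e-9)

    def test_identical_multisets_u_half_product(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_tie_correction_reduces_variance(self):
        # with ties the tie-corrected p must not exceed the naive one for
        # the same U distance from the mean; check via monotone example
        _, p_ties = mann_whitney_u([1.0, 2.0] * 10, [1.0, 2.0] * 10)
        assert p_ties > 0.9  # identical distributions stay insignificant

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=20),
    )
    def test_complement_identity(self, x, y):
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_small_sample_matches_enumeration(self):
        """At 4 vs 4 without ties the p-value equals the permutation tail."""
        x = [1.0, 2.0, 4.0, 7.0]
        y = [3.0, 5.0, 6.0, 8.0]
        u_obs, p = mann_whitney_u(x, y)
        # enumerate all C(8,4) assignments of pooled ranks
        pooled = sorted(x + y)
        us = []
        for combo in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(8) if i not in combo]
            u = sum(1 for a in xs for b in ys if a > b)
            us.append(u)
        mean_u = 8.0
        tail = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u)) / len(us)
        assert p == pytest.approx(tail, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_null_type_i_error_near_nominal(self):
        """~5% rejections at alpha=0.05 under the null, n=40 per group."""
        rng = np.random.default_rng(11)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.012)


class TestChiSquaredOrFisher:
    def test_independence_gives_zero_statistic(self):
        test, statistic, p = chi_squared_or_fisher([[10, 10], [10, 10]])
        assert test == "chi_squared"
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_sparse_table_uses_fisher_with_exact_p(self):
        test, _, p = chi_squared_or_fisher([[5, 0], [0, 5]])
        assert test == "fisher_exact"
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_published_sex_counts_reproduce_closed_form(self):
        # male/female split 52/77 vs 46/62: N(ad-bc)^2 / product of margins
        test, statistic, _ = chi_squared_or_fisher([[52, 77], [46, 62]])
        assert test == "chi_squared"
        assert statistic == pytest.approx(0.1263, abs=2e-4)

    def test_zero_marginal_degenerates_to_fisher_p1(self):
        test, _, p = chi_squared_or_fisher([[0, 0], [3, 5]])
        assert test == "fisher_exact"
        assert p == 1.0

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    def test_fisher_matches_brute_force_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        test, _, p = chi_squared_or_fisher(table)
        if test == "fisher_exact":
            assert p == pytest.approx(fisher_oracle(table), abs=1e-9)


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # ranks differ by d^2 sum of 4 -> rho = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.rho == pytest.approx(0.8)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        res = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert res.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_incomplete_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan, 5], [1, 2, 3, 4, np.nan])
        assert res.n_used == 3

    def test_constant_variable_undefined(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.rho is None


class TestLogisticIRLS:
    def test_saturated_2x2_reproduces_closed_form_log_odds(self):
        # exposure table a=10,b=5 / c=5,d=10 -> log OR = ln 4
        y = np.array([1] * 10 + [1] * 5 + [0] * 5 + [0] * 10)
        x = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10)
        rows = logistic_fit(y, pd.DataFrame({"exposure": x}))
        assert rows[0].b == pytest.approx(math.log(4.0), abs=1e-8)
        assert rows[0].or_ == pytest.approx(4.0, abs=1e-6)
        assert rows[0].wald == pytest.approx((rows[0].b / rows[0].se) ** 2)

    def test_loglikelihood_monotone_across_iterations(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1])))).astype(float)
        _, _, converged, history = irls_logistic(X, y)
        assert converged
        assert all(b >= a - 1e-12 for a, b in zip(history, history[1:]))

    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(3)
        n = 10_000
        x = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        rows = logistic_fit(y, pd.DataFrame({"x": x}))
        assert abs(rows[0].b) <= 0.07

    def test_parameter_recovery_b_half(self):
        rng = np.random.default_rng(4)
        n = 50_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 0.5 * x)))
        y = (rng.random(n) < p).astype(int)
        rows = logistic_fit(y, pd.DataFrame({"x": x}))
        assert rows[0].b == pytest.approx(0.5, abs=0.05)

    def test_matches_statsmodels_on_adjusted_model(self):
        """Independent cross-check of coefficient, SE and Wald p."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 500
        age = rng.normal(70, 8, n)
        x = rng.normal(size=n) + 0.01 * age
        p = 1 / (1 + np.exp(-(-2.0 + 0.4 * x + 0.02 * age)))
        y = (rng.random(n) < p).astype(int)
        rows = logistic_fit(y, pd.DataFrame({"x": x, "age": age}), adjust_for="age")
        X = sm.add_constant(np.column_stack([x, age]))
        fit = sm.Logit(y, X).fit(disp=0)
        assert rows[0].b == pytest.approx(fit.params[1], abs=1e-6)
        assert rows[0].se == pytest.approx(fit.bse[1], rel=1e-4)
        assert rows[0].p_value == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_separation_flagged_not_silent(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 5.3])
        rows = logistic_fit(y, pd.DataFrame({"x": x}))
        assert rows[0].flagged is not None

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.array([0, 1, 2]), pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestCompareGroups:
    def test_table_shape_and_separated_marker(self, table1_cohort):
        rows = compare_groups(table1_cohort, ["agr", "sex", "age"])
        by_var = {r.variable: r for r in rows}
        assert by_var["agr"].test == "mann_whitney"
        assert by_var["agr"].p_value < 0.001
        assert by_var["sex"].test in ("chi_squared", "fisher_exact")
        assert by_var["age"].p_value > 0.001  # same distribution by design

    def test_generator_round_trip_medians(self):
        base = default_table1_spec(seed=13)
        spec = CohortSpec(
            n_infected=20_000, n_aseptic=20_000, variables=base.variables, seed=13
        )
        rows = compare_groups(generate_cohort(spec), ["agr"])
        assert "1.1" in rows[0].group_a_summary
        assert "1.5" in rows[0].group_b_summary

    def test_unknown_variable_rejected(self, table1_cohort):
        from agr_screen.cohort import ConfigurationError

        with pytest.raises(ConfigurationError):
            compare_groups(table1_cohort, ["nope"])

    def test_identical_groups_rarely_significant(self):
        rng = np.random.default_rng(6)
        pvals = []
        for seed in range(40):
            vals = np.exp(rng.normal(0.2, 0.2, 60))
            cohort = build_cohort(vals[:30], vals[30:])
            pvals.append(compare_groups(cohort, ["agr"])[0].p_value)
        assert np.mean(np.array(pvals) < 0.05) < 0.2


class TestFalsePositiveAnalysis:
    def test_planted_confounder_detected(self):
        """A confounder shifted in the false-positive stratum shows a small
        Mann-Whitney p; an independent one does not."""
        rng = np.random.default_rng(7)
        n = 300
        asep_agr = np.concatenate([rng.uniform(0.8, 1.4, 120), rng.uniform(1.5, 2.2, 180)])
        alp = np.where(asep_agr <= 1.43, rng.normal(140, 15, n), rng.normal(75, 15, n))
        got = rng.normal(22, 5, n)
        cohort = build_cohort(
            [0.9, 1.0, 1.1],
            asep_agr,
            aseptic={"alp": alp, "got": got, "age": rng.normal(70, 8, n)},
            infected={"alp": [80.0] * 3, "got": [22.0] * 3, "age": [70.0] * 3},
        )
        res = false_positive_analysis(cohort, 1.43, ["alp", "got"])
        by_var = {r.variable: r for r in res.comparisons}
        assert by_var["alp"].p_value < 0.001
        assert by_var["got"].p_value > 0.01
        # the planted confounder also correlates with AGR among aseptics
        corr = {tuple(c.variable_pair): c for c in res.correlations}
        assert corr[("agr", "alp")].rho < -0.5

    def test_no_false_positive_stratum_is_informative_error(self):
        cohort = build_cohort([0.9, 1.0], [1.8, 1.9, 2.0])
        with pytest.raises(ValueError, match="false-positive"):
            false_positive_analysis(cohort, 1.0, ["alp"])

    def test_null_confounders_give_or_near_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        asep_agr = rng.uniform(0.9, 2.1, n)
        cohort = build_cohort(
            [1.0, 1.1],
            asep_agr,
            aseptic={"got": rng.normal(22, 5, n), "age": rng.normal(70, 8, n)},
            infected={"got": [22.0, 23.0], "age": [70.0, 71.0]},
        )
        res = false_positive_analysis(cohort, 1.43, ["got"])
        assert res.logistic[0].or_ == pytest.approx(1.0, abs=0.1)

    def test_report_has_table2_shape(self, table1_cohort):
        res = false_positive_analysis(
            table1_cohort, 1.43, ["bmi", "creatinine", "uremia", "got", "gpt", "inr", "alp"]
        )
        assert len(res.logistic) == 7
        for row in res.logistic:
            assert row.df == 1
            if row.flagged is None:
                assert row.or_ == pytest.approx(math.exp(row.b), rel=1e-6)
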