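from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from baitscout import clinical_outcomes as clin
from baitscout.io_formats import Cohort

from _oracles import exact_mannwhitney_p, partial_loglik_no_ties


def make_survival(times, events, index=None):
    idx = pd.Index(index if index is not None else range(len(times)),
                   name="sample_id")
    return pd.DataFrame({"time": times, "event": events}, index=idx)


class TestSignatureScore:
    def test_single_gene_is_its_zscore(self, toy_cohort):
        score = clin.signature_score(toy_cohort, ["G1"])
        row = toy_cohort.expression.loc["G1"]
        expected = (row - row.mean()) / row.std(ddof=1)
        pd.testing.assert_series_equal(score, expected, check_names=False)

    def test_three_gene_hand_computation(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [10.0, 10.0, 13.0]],
            index=["A", "B", "C"], columns=["s1", "s2", "s3"])
        surv = make_survival([1, 2, 3], [1, 1, 1], index=["s1", "s2", "s3"])
        cohort = Cohort("C", expr, surv)
        score = clin.signature_score(cohort, ["A", "B", "C"])
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1),
                                                    axis=0)
        expected = z.mean(axis=0)
        pd.testing.assert_series_equal(score, expected, check_names=False)

    def test_constant_gene_excluded_with_warning(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                            index=["FLAT", "VAR"], columns=["a", "b", "c"])
        surv = make_survival([1, 2, 3], [1, 1, 1], index=["a", "b", "c"])
        cohort = Cohort("C", expr, surv)
        with pytest.warns(UserWarning, match="FLAT"):
            score = clin.signature_score(cohort, ["FLAT", "VAR"])
        single = clin.signature_score(cohort, ["VAR"])
        pd.testing.assert_series_equal(score, single)

    def test_no_overlap_errors(self, toy_cohort):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                clin.signature_score(toy_cohort, ["NOPE"])


class TestDichotomize:
    def test_even_split(self):
        scores = pd.Series([-1.0, -0.5, 0.5, 1.0])
        assert list(clin.dichotomize_median(scores)) == \
            ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        assert list(clin.dichotomize_median(scores)) == ["low", "low", "high"]

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning):
            labels = clin.dichotomize_median(pd.Series([2.0, 2.0, 2.0]))
        assert (labels == "low").all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            clin.dichotomize_median(pd.Series([1.0]))


class TestCox:
    def test_six_subject_grid_oracle(self):
        # no ties: compare against direct numerical maximization of the
        # written-out partial likelihood
        x = np.array([0.2, 1.4, -0.8, 2.1, 0.0, -1.3])
        time = np.array([5.0, 8.0, 3.0, 9.0, 6.0, 4.0])
        event = np.array([1, 1, 1, 0, 1, 1])
        fit = clin.cox_univariate(x, make_survival(time, event))
        res = minimize_scalar(
            lambda b: -partial_loglik_no_ties(b, x, time, event),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert fit.beta == pytest.approx(res.x, abs=1e-5)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        t = np.round(rng.exponential(1 / np.exp(0.4 * x)), 1) + 0.1
        c = rng.exponential(2.0, n)
        tt = np.minimum(t, c)
        e = (t <= c).astype(int)
        fit = clin.cox_univariate(x, make_survival(tt, e))
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "T": tt, "E": e}), "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_breslow_matches_statsmodels(self):
        from statsmodels.duration.hazard_regression import PHReg
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=n)
        t = np.round(rng.exponential(1 / np.exp(0.5 * x)), 1) + 0.1
        e = np.ones(n, dtype=int)
        fit = clin.cox_univariate(x, make_survival(t, e), ties="breslow")
        res = PHReg(t, x[:, None], status=e, ties="breslow").fit()
        assert fit.beta == pytest.approx(res.params[0], abs=1e-5)
        assert fit.se == pytest.approx(res.bse[0], abs=1e-5)

    def test_hr_and_ci_consistency(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        t = rng.exponential(1 / np.exp(0.3 * x))
        fit = clin.cox_univariate(x, make_survival(t, np.ones(100, int)))
        lo, hi = fit.ci95
        assert lo < fit.hr < hi
        assert fit.hr == pytest.approx(np.exp(fit.beta))

    def test_affine_invariance_of_z(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=150)
        t = rng.exponential(1 / np.exp(0.5 * x))
        surv = make_survival(t, np.ones(150, int))
        fit = clin.cox_univariate(x, surv)
        fit_scaled = clin.cox_univariate(10.0 * x + 3.0, surv)
        assert fit_scaled.z == pytest.approx(fit.z, abs=1e-5)
        assert fit_scaled.p == pytest.approx(fit.p, abs=1e-6)
        assert fit_scaled.beta == pytest.approx(fit.beta / 10.0, abs=1e-6)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="event"):
            clin.cox_univariate(np.arange(5.0),
                                make_survival(np.arange(1.0, 6.0),
                                              np.zeros(5, int)))

    def test_constant_covariate_error(self):
        with pytest.raises(ValueError, match="constant"):
            clin.cox_univariate(np.ones(5),
                                make_survival(np.arange(1.0, 6.0),
                                              np.ones(5, int)))

    def test_separation_flagged_diverged(self):
        # perfect separation: the covariate orders event times exactly
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        time = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        fit = clin.cox_univariate(x, make_survival(time, np.ones(6, int)))
        assert fit.diverged


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        time = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        labels = pd.Series(["a", "a", "a", "b", "b", "b"])
        out = clin.logrank_test(labels, make_survival(time, event))
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_six_subject_table_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 1, 1, 0, 1])
        labels = pd.Series(["a", "a", "a", "b", "b", "b"])
        out = clin.logrank_test(labels, make_survival(time, event))
        ref = ll_logrank(time[:3], time[3:], event[:3], event[3:])
        assert out["chi2"] == pytest.approx(ref.test_statistic, rel=1e-10)
        assert out["p"] == pytest.approx(ref.p_value, rel=1e-10)

    def test_random_data_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(5)
        n = 80
        g = rng.random(n) < 0.5
        t = np.round(rng.exponential(np.where(g, 1.0, 1.6)), 2) + 0.01
        e = (rng.random(n) < 0.8).astype(int)
        labels = pd.Series(np.where(g, "hi", "lo"))
        out = clin.logrank_test(labels, make_survival(t, e))
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert out["chi2"] == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_null_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        n = 60
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.8).astype(int)
        surv = make_survival(t, e)
        hits = 0
        n_perm = 300
        for _ in range(n_perm):
            labels = pd.Series(np.where(rng.random(n) < 0.5, "a", "b"))
            if labels.nunique() < 2:
                continue
            if clin.logrank_test(labels, surv)["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_perm <= 0.09

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            clin.logrank_test(pd.Series(["a", "a"]),
                              make_survival([1.0, 2.0], [1, 1]))


def fit(gene, cohort, beta, p):
    se = 0.1
    return clin.CoxFit(gene, cohort, beta, se, beta / se, p)


class TestConcordance:
    def test_two_agreeing_cohorts_reproducible(self):
        fits = [fit("g", "c1", 0.5, 0.01), fit("g", "c2", 0.4, 0.03),
                fit("g", "c3", -0.2, 0.4)]
        out = clin.concordance_call(fits)
        assert bool(out.iloc[0]["reproducible"])
        assert out.iloc[0]["n_significant_cohorts"] == 2

    def test_single_significant_cohort_not_reproducible(self):
        fits = [fit("g", "c1", 0.5, 0.01), fit("g", "c2", 0.4, 0.2),
                fit("g", "c3", 0.3, 0.3)]
        assert not clin.concordance_call(fits).iloc[0]["reproducible"]

    def test_direction_clash_not_reproducible(self):
        fits = [fit("g", "c1", 0.5, 0.01), fit("g", "c2", -0.5, 0.01)]
        assert not clin.concordance_call(fits).iloc[0]["reproducible"]

    def test_diverged_fits_excluded(self):
        fits = [fit("g", "c1", 0.5, 0.01),
                clin.CoxFit("g", "c2", 60.0, 0.1, 600.0, 0.0, diverged=True)]
        out = clin.concordance_call(fits)
        assert out.iloc[0]["n_cohorts"] == 1
        assert not out.iloc[0]["reproducible"]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(7)
        fits = [fit(f"g{i}", f"c{j}", rng.normal(), rng.random())
                for i in range(20) for j in range(3)]
        counts = [clin.concordance_call(fits, alpha=a)["reproducible"].sum()
                  for a in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts)


class TestDiffExpression:
    def test_exact_separated_groups(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        b = pd.DataFrame([[4.0, 5.0, 6.0]], index=["g"])
        out = clin.diff_expression(a, b).iloc[0]
        assert out["p"] == pytest.approx(0.1)  # 2 / C(6,3)
        assert out["direction"] == "up"
        assert not out["significant"]

    def test_identical_groups(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        out = clin.diff_expression(a, a.copy()).iloc[0]
        assert out["p"] == pytest.approx(1.0)

    def test_all_tied_gene(self):
        a = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"])
        b = pd.DataFrame([[2.0, 2.0]], index=["g"])
        assert clin.diff_expression(a, b).iloc[0]["p"] == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.permutation(np.arange(14.0))[:6]
            b = np.setdiff1d(np.arange(14.0), a)[:5]
            out = clin.diff_expression(
                pd.DataFrame([a], index=["g"]),
                pd.DataFrame([b], index=["g"])).iloc[0]
            assert out["p"] == pytest.approx(exact_mannwhitney_p(a, b),
                                             abs=1e-9)

    def test_exact_close_to_asymptotic_at_8_8(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(9)
        for _ in range(10):
            pool = rng.permutation(np.arange(16.0))
            a, b = pool[:8], pool[8:]
            exact = mannwhitneyu(a, b, method="exact").pvalue
            asym = mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - asym) < 0.02

    def test_direction_down(self):
        a = pd.DataFrame([[4.0, 5.0, 6.0]], index=["g"])
        b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        assert clin.diff_expression(a, b).iloc[0]["direction"] == "down"


class TestFoldChange:
    def test_published_group_means(self):
        assert clin.fold_change_summary(1.073, 0.5975) == 1.8
        assert clin.fold_change_summary(1.286, 0.8540) == 1.5

    def test_identity(self):
        assert clin.fold_change_summary(3.7, 3.7) == 1.0

    def test_half_up_rounding(self):
        assert clin.fold_change_summary(1.15, 1.0) == 1.2
        assert clin.fold_change_summary(1.25, 1.0) == 1.3

    def test_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            clin.fold_change_summary(1.0, 0.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert clin.pearson_correlation(x, x) == pytest.approx(1.0)
        assert clin.pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert clin.pearson_correlation(x, y) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            clin.pearson_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            clin.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
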