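"""Group summaries, correlations, linear models, and nested F-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cicadasong.stats import (
    StatsError,
    compare_species_features,
    corr_matrix,
    f_test_nested,
    fit_lm,
    summarize,
)
from cicadasong.synth import MorphGroupSpec, default_morph_groups, synth_morphometrics


def expand_noise_free_table():
    """The four species x sex fore-wing cells at their measured means, sd = 0."""
    groups = [
        MorphGroupSpec("chiricahua", "M", 31.3, 0.0, 11),
        MorphGroupSpec("neomexicensis", "M", 28.1, 0.0, 11),
        MorphGroupSpec("chiricahua", "F", 29.1, 0.0, 5),
        MorphGroupSpec("neomexicensis", "F", 26.7, 0.0, 5),
    ]
    return synth_morphometrics(groups, seed=0)


def weighted_ls_oracle():
    """Independent weighted least squares on the four group means.

    Solves the additive two-factor model directly from the normal equations
    with cell weights equal to group sizes; returns the species coefficient
    (neomexicensis minus chiricahua).
    """
    cells = [  # (is_neo, is_male, mean, n)
        (0, 1, 31.3, 11),
        (1, 1, 28.1, 11),
        (0, 0, 29.1, 5),
        (1, 0, 26.7, 5),
    ]
    X = np.array([[1.0, s, m] for s, m, _, _ in cells])
    y = np.array([v for _, _, v, _ in cells])
    w = np.array([n for _, _, _, n in cells], dtype=float)
    beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
    return beta[1]


class TestSummarize:
    def test_closed_form_t_interval(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.sd == pytest.approx(1.581, abs=1e-3)
        assert s.ci_low == pytest.approx(1.037, abs=1e-3)
        assert s.ci_high == pytest.approx(4.963, abs=1e-3)
        assert (s.min, s.max, s.n) == (1.0, 5.0, 5)

    def test_constant_values_collapse_ci(self):
        s = summarize([2.5, 2.5, 2.5])
        assert s.sd == 0.0
        assert s.ci_low == s.mean == s.ci_high == 2.5

    def test_single_value_has_no_ci(self):
        s = summarize([4.2])
        assert not s.has_ci
        assert s.mean == 4.2

    def test_ordering_invariants(self, rng):
        v = rng.normal(10, 2, 40)
        s = summarize(v)
        assert s.ci_low <= s.mean <= s.ci_high
        assert s.min <= s.mean <= s.max


class TestCorrMatrix:
    def test_self_and_exact_linear_correlation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.normal(size=50)})
        r = corr_matrix(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(r.values, r.values.T)

    def test_correlated_morphometrics_recovered(self, rng):
        # 5 variables sharing a common factor with pairwise r = 0.95, n = 32
        n, k, rho = 32, 5, 0.95
        common = rng.standard_normal(n)
        data = {
            f"v{i}": np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(n)
            for i in range(k)
        }
        r = corr_matrix(pd.DataFrame(data))
        off = r.values[~np.eye(k, dtype=bool)]
        assert off.min() > 0.85

    def test_zero_variance_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        r = corr_matrix(df)
        assert np.isnan(r.loc["a", "b"])

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(StatsError):
            corr_matrix(df)


class TestFitLm:
    def test_two_group_exact_fit(self):
        df = pd.DataFrame(
            {"y": [10.0] * 4 + [13.0] * 4, "g": ["a"] * 4 + ["b"] * 4}
        )
        fit = fit_lm(df, "y", ["g"])
        est, _, _, _ = fit.coefficient("g")
        assert est == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_saturated_one_factor_model_reproduces_group_means(self, rng):
        levels = ["a", "b", "c"]
        df = pd.DataFrame(
            {"g": np.repeat(levels, 12), "y": rng.normal(0, 1, 36) + np.repeat([1.0, 4.0, 9.0], 12)}
        )
        fit = fit_lm(df, "y", ["g"])
        means = df.groupby("g")["y"].mean()
        intercept = fit.params["Intercept"]
        assert intercept == pytest.approx(means["a"])
        assert intercept + fit.coefficient("T.b]")[0] == pytest.approx(means["b"])
        assert intercept + fit.coefficient("T.c]")[0] == pytest.approx(means["c"])

    def test_noise_free_table_matches_weighted_ls_oracle(self):
        fit = fit_lm(expand_noise_free_table(), "value_mm", ["species", "sex"])
        est, _, _, _ = fit.coefficient("species")
        oracle = weighted_ls_oracle()
        assert est == pytest.approx(oracle, abs=1e-9)
        assert abs(est) == pytest.approx(2.95, abs=1e-9)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        with pytest.raises(StatsError, match="levels"):
            fit_lm(df, "y", ["g"])

    def test_standardized_residuals_available(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30), "g": ["a", "b"] * 15})
        fit = fit_lm(df, "y", ["g"])
        assert len(fit.standardized_residuals) == 30
        assert np.std(fit.standardized_residuals) == pytest.approx(1.0, abs=0.3)


class TestFTestNested:
    def test_identical_models_give_f_zero_p_one(self):
        df = expand_noise_free_table()
        fit = fit_lm(df, "value_mm", ["species", "sex"])
        res = f_test_nested(fit, fit)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_one_interaction_coefficient_adds_one_df(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(size=40),
                "a": ["x", "y"] * 20,
                "b": ["p"] * 20 + ["q"] * 20,
            }
        )
        reduced = fit_lm(df, "y", ["a", "b"])
        full = fit_lm(df, "y", ["a", "b"], interaction=True)
        res = f_test_nested(reduced, full)
        assert res.df_num == 1

    def test_matches_statsmodels_compare_f_test(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(size=60),
                "a": ["x", "y", "z"] * 20,
                "b": (["p"] * 30 + ["q"] * 30),
            }
        )
        reduced = fit_lm(df, "y", ["a"])
        full = fit_lm(df, "y", ["a", "b"])
        res = f_test_nested(reduced, full)
        f_sm, p_sm, df_sm = full.sm_result.compare_f_test(reduced.sm_result)
        assert res.f_statistic == pytest.approx(f_sm)
        assert res.p_value == pytest.approx(p_sm)
        assert res.df_num == int(df_sm)

    def test_equals_squared_pooled_t_in_two_group_case(self, rng):
        y = np.concatenate([rng.normal(0, 1, 14), rng.normal(0.8, 1, 17)])
        df = pd.DataFrame({"y": y, "g": ["a"] * 14 + ["b"] * 17})
        full = fit_lm(df, "y", ["g"])
        df0 = df.assign(g0="one")
        # intercept-only reduced model, fit without the factor machinery
        import statsmodels.formula.api as smf

        res0 = smf.ols("y ~ 1", data=df0).fit()
        from cicadasong.stats import ModelFit

        reduced = ModelFit(
            response="y", factors=[], interaction=False,
            params=res0.params, bse=res0.bse, tvalues=res0.tvalues,
            pvalues=res0.pvalues, rss=float(res0.ssr),
            df_resid=int(res0.df_resid), r_squared=float(res0.rsquared),
            n=int(res0.nobs), standardized_residuals=np.zeros(31),
        )
        fres = f_test_nested(reduced, full)
        t_pooled, _ = sps.ttest_ind(y[14:], y[:14], equal_var=True)
        assert fres.f_statistic == pytest.approx(t_pooled**2, rel=1e-9)

    def test_non_nested_models_rejected(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "a": ["x", "y"] * 20, "b": ["p"] * 20 + ["q"] * 20}
        )
        fit_a = fit_lm(df, "y", ["a"])
        fit_b = fit_lm(df, "y", ["b"])
        with pytest.raises(StatsError, match="nested"):
            f_test_nested(fit_a, fit_b)


class TestCalibrationAndPower:
    def test_type_one_error_near_nominal(self):
        # no species effect: rejection rate at alpha=0.05 within (0.02, 0.08)
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y = rng.normal(0, 1, 26)
            df = pd.DataFrame({"y": y, "g": ["a"] * 15 + ["b"] * 11})
            fit = fit_lm(df, "y", ["g"])
            if fit.coefficient("g")[3] < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_rep < 0.08

    def test_interaction_power_at_three_sd(self):
        # true interaction of 3 residual SDs: p < 0.01 in >= 90% of replicates
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 200
        cell = 8
        for _ in range(n_rep):
            rows = []
            for sp in (0, 1):
                for sex in (0, 1):
                    mu = 30 - 2 * sp + 1.5 * sex + 3.0 * sp * sex
                    for v in rng.normal(mu, 1.0, cell):
                        rows.append(
                            {"y": v, "species": "ab"[sp], "sex": "mf"[sex]}
                        )
            df = pd.DataFrame(rows)
            reduced = fit_lm(df, "y", ["species", "sex"])
            full = fit_lm(df, "y", ["species", "sex"], interaction=True)
            if f_test_nested(reduced, full).p_value < 0.01:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_species_effect_ci_coverage(self):
        # synthetic fore-wing tables at the measured means/SDs: the additive
        # model's 95% CI covers the population effect (2.95) in >= 90% of reps
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            table = synth_morphometrics(default_morph_groups(), seed=1000 + rep)
            fit = fit_lm(table, "value_mm", ["species", "sex"])
            lo, hi = fit.conf_int("species")
            if lo <= -2.95 <= hi:
                hits += 1
        assert hits / n_rep >= 0.90


class TestCompareSpeciesFeatures:
    def make_features(self, rate_mean, rate_sd, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "burst_rate_hz": rng.normal(rate_mean, rate_sd, n),
                "peak_frequency_hz": rng.normal(7200, 300, n),
            }
        )

    def test_separated_populations_highly_significant(self):
        a = self.make_features(27.8, 0.86, 15, 1)
        b = self.make_features(54.0, 2.32, 11, 2)
        results = compare_species_features(a, b, "neo", "chir")
        by_var = {r.variable: r for r in results}
        assert by_var["burst_rate_hz"].p_value < 1e-6
        assert by_var["burst_rate_hz"].ranges_overlap is False

    def test_identical_groups_give_zero_effect(self):
        a = self.make_features(27.8, 0.86, 15, 5)
        results = compare_species_features(a, a.copy(), "x", "y")
        assert results[0].coefficient == pytest.approx(0.0, abs=1e-9)

    def test_null_p_values_roughly_uniform(self):
        # same population, many seeds: rejection rate 0.05 +- 0.03
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a = self.make_features(27.8, 0.86, 12, 3000 + 2 * rep)
            b = self.make_features(27.8, 0.86, 12, 3001 + 2 * rep)
            r = compare_species_features(a, b, "x", "y", variables=["burst_rate_hz"])
            if r[0].p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_tiny_group_flags_test_absent(self):
        a = self.make_features(27.8, 0.86, 5, 1)
        b = self.make_features(54.0, 2.32, 1, 2)
        r = compare_species_features(a, b, "x", "y", variables=["burst_rate_hz"])
        assert r[0].t_statistic is None
        assert not r[0].summary_b.has_ci

    def test_empty_group_rejected(self):
        a = self.make_features(27.8, 0.86, 5, 1)
        with pytest.raises(StatsError):
            compare_species_features(a, a.iloc[:0], "x", "y")
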