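import numpy as np
import pandas as pd
import pytest

from audseg.validate import (
    GlmTable,
    fit_logistic_wald,
    fit_type3_anova,
    joint_term_ss,
    model_fit_stats,
    partial_eta_squared,
    predictor_comparison_report,
    protective_score,
)


class TestProtectiveScore:
    def _ind(self, rows):
        cols = ["mask", "distancing", "avoid_crowded", "handwash", "open_window"]
        return pd.DataFrame(rows, columns=cols)

    def test_extremes_and_partial(self):
        ind = self._ind([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 0, 0, 1, 0]])
        assert list(protective_score(ind)) == [5, 0, 2]

    def test_missing_policies(self):
        ind = self._ind([[1, np.nan, 1, 1, 1], [1, 1, 1, 1, 1]])
        assert list(protective_score(ind, missing="zero")) == [4, 5]
        assert list(protective_score(ind, missing="drop")) == [5]

    def test_shape_and_values_validated(self):
        with pytest.raises(ValueError):
            protective_score(self._ind([[1, 1, 1, 1, 1]]).iloc[:, :4])
        with pytest.raises(ValueError, match="binary"):
            protective_score(self._ind([[1, 2, 1, 1, 1]]))


class TestPartialEtaSquared:
    def test_values_and_monotonicity(self):
        assert partial_eta_squared(0.0, 5.0) == 0.0
        assert partial_eta_squared(1.0, 1.0) == 0.5
        assert partial_eta_squared(2.0, 1.0) > partial_eta_squared(1.0, 1.0)
        assert partial_eta_squared(1.0, 2.0) < partial_eta_squared(1.0, 1.0)

    def test_degenerate(self):
        assert np.isnan(partial_eta_squared(0.0, 0.0))
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1.0)


class TestType3Anova:
    def test_balanced_one_way_equals_classical(self):
        rng = np.random.default_rng(0)
        g = np.repeat(list("abcd"), 30)
        y = pd.Series(rng.normal(size=120) + np.where(g == "a", 1.0, 0.0))
        glm = fit_type3_anova(y, pd.DataFrame({"grp": g}, index=y.index), ["grp"])
        means = {l: y[g == l].mean() for l in "abcd"}
        ss_between = sum(30 * (m - y.mean()) ** 2 for m in means.values())
        assert glm.table.at["grp", "sum_sq"] == pytest.approx(ss_between)
        assert glm.table.at["grp", "df"] == 3

    def test_orthogonal_terms_type3_equals_sequential(self):
        rng = np.random.default_rng(1)
        # balanced 2x2: factors orthogonal, Type III == sequential SS
        a = np.tile(np.repeat(["a0", "a1"], 25), 2)
        b = np.repeat(["b0", "b1"], 50)
        y = pd.Series(rng.normal(size=100) + (a == "a1") * 0.5 + (b == "b1") * 1.0)
        data = pd.DataFrame({"A": a, "B": b}, index=y.index)
        glm = fit_type3_anova(y, data, ["A", "B"])
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = data.copy()
        d["_y"] = y
        seq = sm.stats.anova_lm(smf.ols("_y ~ C(A) + C(B)", data=d).fit(), typ=1)
        assert glm.table.at["A", "sum_sq"] == pytest.approx(seq.loc["C(A)", "sum_sq"])
        assert glm.table.at["B", "sum_sq"] == pytest.approx(seq.loc["C(B)", "sum_sq"])

    def test_constant_outcome(self):
        g = np.repeat(["a", "b"], 20)
        y = pd.Series(np.ones(40))
        glm = fit_type3_anova(y, pd.DataFrame({"grp": g}, index=y.index), ["grp"])
        assert glm.table.at["grp", "sum_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_ss_additivity(self):
        rng = np.random.default_rng(2)
        g = rng.choice(list("abc"), 200)
        data = pd.DataFrame({"grp": g, "x": rng.normal(size=200)})
        y = pd.Series(rng.normal(size=200) + (g == "b") * 0.7 + data["x"] * 0.3)
        glm = fit_type3_anova(y, data, ["grp"], ["x"])
        t = glm.table
        assert t.at["Corrected Model", "sum_sq"] + t.at["Error", "sum_sq"] == pytest.approx(
            t.at["Corrected Total", "sum_sq"], rel=1e-6
        )
        # MS = SS/df on every term row
        for row in t.index:
            if np.isfinite(t.at[row, "mean_sq"]):
                assert t.at[row, "mean_sq"] == pytest.approx(
                    t.at[row, "sum_sq"] / t.at[row, "df"]
                )


class TestModelFitStats:
    def test_saturated_fit(self):
        g = np.repeat(list("ab"), 20)
        y = pd.Series(np.where(g == "a", 1.0, 3.0))
        glm = fit_type3_anova(y, pd.DataFrame({"grp": g}, index=y.index), ["grp"])
        st = model_fit_stats(glm)
        assert st["r_squared"] == pytest.approx(1.0)

    def test_published_table_reproduction(self):
        """Worked example from the published ANOVA's printed SS/df values."""
        term_ss = {
            "Segments": 1751.359, "Gender": 94.174, "Dummy_Ethnicity": 5.820,
            "EducationSelf": 27.807, "Income": 72.367, "Age": 153.335,
        }
        term_df = {"Segments": 6, "Gender": 1, "Dummy_Ethnicity": 4,
                   "EducationSelf": 1, "Income": 1, "Age": 1}
        tab = GlmTable.from_components(
            term_ss, term_df, ss_error=10340.288, df_error=4841,
            ss_total=13221.440, df_total=4855, ss_intercept=1462.938,
        )
        st = model_fit_stats(tab)
        assert round(st["r_squared"], 3) == 0.218
        assert round(st["adj_r_squared"], 3) == 0.216
        assert round(st["F"]["Segments"], 3) == 136.655
        assert round(st["F"]["Gender"], 3) == 44.089
        assert round(tab.table.at["Segments", "partial_eta_sq"], 3) == 0.145
        assert round(tab.table.at["Age", "partial_eta_sq"], 3) == 0.015


class TestLogisticWald:
    def test_null_predictor_wald_near_df(self):
        """Under independence the Wald statistic averages its df."""
        rng = np.random.default_rng(3)
        stats = []
        for _ in range(100):
            n = 800
            y = pd.Series(rng.integers(0, 2, n).astype(float))
            d = pd.DataFrame({"seg": rng.choice(list("abcd"), n)})
            w = fit_logistic_wald(y, d, ["seg"])
            stats.append(w.at["seg", "wald_chi2"])
        # mean of a chi-square(3) is 3; allow ~3 standard errors
        assert np.mean(stats) == pytest.approx(3.0, abs=3 * np.sqrt(6 / 100))

    def test_known_log_odds_recovered(self):
        rng = np.random.default_rng(4)
        n = 4000
        seg = rng.choice(["a", "b"], n)
        logit = np.where(seg == "a", -2.0, -0.5)
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float))
        d = pd.DataFrame({"seg": seg})
        w = fit_logistic_wald(y, d, ["seg"])
        assert w.at["seg", "p"] < 1e-10
        assert not w.attrs["separation"]

    def test_confidence_interval_coverage(self):
        """95% Wald CIs for a known segment log-odds contrast cover the truth
        at nominal rate over 200 simulations."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        true_beta = 1.0  # log-odds difference b vs a
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 500
            seg = rng.choice(["a", "b"], n)
            logit = np.where(seg == "a", -1.0, -1.0 + true_beta)
            d = pd.DataFrame({"seg": seg, "_y": (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)})
            res = smf.glm("_y ~ C(seg)", data=d, family=sm.families.Binomial()).fit()
            lo, hi = res.conf_int().loc["C(seg)[T.b]"]
            hits += lo <= true_beta <= hi
        coverage = hits / reps
        assert coverage == pytest.approx(0.95, abs=3 * np.sqrt(0.95 * 0.05 / reps) + 0.01)

    def test_one_class_outcome_rejected(self):
        y = pd.Series(np.ones(50))
        d = pd.DataFrame({"seg": np.repeat(["a", "b"], 25)})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_wald(y, d, ["seg"])


class TestPredictorComparison:
    def _fit(self, rng, segment_effect=2.0, n=1500):
        seg = rng.choice(list("abcdefg"), n)
        age = rng.normal(50, 15, n)
        y = pd.Series(
            rng.normal(size=n) + segment_effect * (np.char.find("abcdefg", seg.astype(str)) / 6.0)
        )
        yb = pd.Series((rng.random(n) < np.where(seg == "g", 0.3, 0.05)).astype(float))
        data = pd.DataFrame({"segment": seg, "age": age})
        glm = fit_type3_anova(y, data, ["segment"], ["age"])
        wald = fit_logistic_wald(yb, data, ["segment"], ["age"])
        return glm, wald, y, data

    def test_segment_driven_outcome_dominates(self):
        rng = np.random.default_rng(5)
        glm, wald, y, data = self._fit(rng)
        rep = predictor_comparison_report(glm, wald)
        assert rep["partial_eta_sq"]["segment"] > rep["partial_eta_sq"]["age"]
        assert rep["eta_sq_ratio_demographics_vs_segment"] < 0.5

    def test_null_outcome_all_small(self):
        rng = np.random.default_rng(6)
        glm, wald, _, _ = self._fit(rng, segment_effect=0.0)
        rep = predictor_comparison_report(glm, wald)
        assert all(v < 0.02 for v in rep["partial_eta_sq"].values())

    def test_table_layout(self):
        rng = np.random.default_rng(7)
        glm, wald, y, data = self._fit(rng)
        rows = list(glm.table.index)
        assert rows[0] == "Corrected Model" and rows[1] == "Intercept"
        assert rows[-2:] == ["Total", "Corrected Total"]
        assert "Error" in rows
        ss_joint, df_joint = joint_term_ss(y, data, ["segment"], ["age"], [], ["age"])
        rep = predictor_comparison_report(glm, wald, joint_demographics_ss=ss_joint)
        assert rep["demographics_combined_eta_sq"] >= 0
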