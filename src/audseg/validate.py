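"""Predictive-validity comparison: segments vs demographics.

The segmentation earns its keep if the single seven-level segment variable
predicts health outcomes better than the usual demographic battery.  Two
analyses: a Type III GLM (Unianova-style) on the summative protective-
behaviour score, with partial eta-squared effect sizes per term, and a
logistic regression on vaccine refusal compared through per-term Wald
chi-square statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "protective_score",
    "GlmTable",
    "fit_type3_anova",
    "partial_eta_squared",
    "model_fit_stats",
    "fit_logistic_wald",
    "joint_term_ss",
    "predictor_comparison_report",
]

log = logging.getLogger(__name__)

PROTECTIVE_BEHAVIOURS = ("mask", "distancing", "avoid_crowded", "handwash", "open_window")


def protective_score(indicators: pd.DataFrame, missing: str = "zero") -> pd.Series:
    """Summative 0-5 score over five binary protective-behaviour indicators.

    ``missing="zero"`` treats a missing indicator as not performed;
    ``missing="drop"`` drops respondents with any missing indicator.
    """
    if indicators.shape[1] != 5:
        raise ValueError("expected exactly five behaviour indicators")
    vals = indicators.astype(float)
    bad = ~vals.isin([0.0, 1.0]) & vals.notna()
    if bad.to_numpy().any():
        raise ValueError("indicators must be binary 0/1")
    if missing == "drop":
        vals = vals.dropna()
    elif missing == "zero":
        vals = vals.fillna(0.0)
    else:
        raise ValueError("missing must be 'zero' or 'drop'")
    return vals.sum(axis=1).astype(int)


@dataclass
class GlmTable:
    """Type III ANOVA table in the Unianova layout.

    ``table`` rows: Corrected Model, Intercept, one row per term, Error,
    Total, Corrected Total; columns: sum_sq, df, mean_sq, F, p,
    partial_eta_sq.  Within-machine mean squares are never rounded before
    deriving F.
    """

    table: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    aliased: list[str]

    @classmethod
    def from_components(
        cls,
        term_ss: dict[str, float],
        term_df: dict[str, float],
        ss_error: float,
        df_error: float,
        ss_total: float,
        df_total: float,
        ss_intercept: float | None = None,
        aliased: list[str] | None = None,
    ) -> "GlmTable":
        """Assemble the table from sums of squares and degrees of freedom.

        ``term_ss``/``term_df`` cover the model terms (excluding intercept);
        ``ss_total`` / ``df_total`` are the *corrected* totals.  This is also
        the entry point for reproducing published tables from their printed
        SS/df values.
        """
        ms_error = ss_error / df_error
        # numerical floor: tiny negative SS from matrix arithmetic are zero
        tol = 1e-10 * max(ss_total, 1.0)
        term_ss = {t: (0.0 if -tol < ss < 0 else ss) for t, ss in term_ss.items()}
        rows = {}
        ss_model = max(ss_total - ss_error, 0.0)
        df_model = sum(term_df.values())
        rows["Corrected Model"] = (ss_model, df_model)
        if ss_intercept is not None:
            rows["Intercept"] = (ss_intercept, 1.0)
        for t in term_ss:
            rows[t] = (term_ss[t], term_df[t])
        recs = []
        for name, (ss, df) in rows.items():
            ms = ss / df
            F = ms / ms_error
            p = float(stats.f.sf(F, df, df_error))
            recs.append((name, ss, df, ms, F, p, partial_eta_squared(ss, ss_error)))
        recs.append(("Error", ss_error, df_error, ms_error, np.nan, np.nan, np.nan))
        grand_total = ss_total + (ss_intercept or 0.0)
        recs.append(("Total", grand_total, df_total + 1, np.nan, np.nan, np.nan, np.nan))
        recs.append(("Corrected Total", ss_total, df_total, np.nan, np.nan, np.nan, np.nan))
        table = pd.DataFrame(
            recs, columns=["source", "sum_sq", "df", "mean_sq", "F", "p", "partial_eta_sq"]
        ).set_index("source")
        r2 = ss_model / ss_total if ss_total > 0 else float("nan")
        adj = (
            1.0 - (ss_error / df_error) / (ss_total / df_total)
            if ss_total > 0
            else float("nan")
        )
        return cls(table=table, r_squared=r2, adj_r_squared=adj, aliased=aliased or [])


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be >= 0")
    if ss_effect == 0 and ss_error == 0:
        log.warning("partial eta-squared undefined: both SS are zero")
        return float("nan")
    return ss_effect / (ss_effect + ss_error)


def _formula(categorical: list[str], numeric: list[str]) -> str:
    terms = [f"C(Q('{c}'), Sum)" for c in categorical] + [f"Q('{x}')" for x in numeric]
    return " + ".join(terms) if terms else "1"


def fit_type3_anova(
    y: pd.Series,
    factors: pd.DataFrame,
    categorical: list[str],
    numeric: list[str] = [],
) -> GlmTable:
    """Type III GLM of a numeric outcome on categorical + numeric terms.

    Sum-to-zero (full-rank) coding, marginal SS per term adjusted for all
    others, SPSS-compatible table layout including Intercept, Error, Total
    and Corrected Total rows.  Rank-deficient designs are reported through
    ``aliased`` rather than silently dropped.
    """
    data = factors.copy()
    data["_y"] = y.loc[factors.index].astype(float)
    data = data.dropna()
    for c in categorical:
        if data[c].nunique() < 2:
            raise ValueError(f"factor {c!r} needs >= 2 levels")
    model = smf.ols(f"_y ~ {_formula(categorical, numeric)}", data=data)
    n_params = model.exog.shape[1]
    if len(data) <= n_params:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(model.exog)
    aliased: list[str] = []
    if rank < n_params:
        aliased = ["<rank-deficient design>"]
        log.warning("design matrix rank %d < %d parameters; aliased terms present", rank, n_params)
    res = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a3 = sm.stats.anova_lm(res, typ=3)

    yv = data["_y"].to_numpy()
    ss_error = float(a3.loc["Residual", "sum_sq"])
    df_error = float(a3.loc["Residual", "df"])
    term_ss, term_df = {}, {}
    rename = {f"C(Q('{c}'), Sum)": c for c in categorical}
    rename.update({f"Q('{x}')": x for x in numeric})
    for row in a3.index:
        if row in ("Intercept", "Residual"):
            continue
        term = rename.get(row, row)
        term_ss[term] = float(a3.loc[row, "sum_sq"])
        term_df[term] = float(a3.loc[row, "df"])
    return GlmTable.from_components(
        term_ss=term_ss,
        term_df=term_df,
        ss_error=ss_error,
        df_error=df_error,
        ss_total=float(((yv - yv.mean()) ** 2).sum()),
        df_total=float(len(yv) - 1),
        ss_intercept=float(a3.loc["Intercept", "sum_sq"]),
        aliased=aliased,
    )


def model_fit_stats(glm: GlmTable) -> dict:
    """R-squared, adjusted R-squared and per-term F from unrounded MS."""
    t = glm.table
    for need in ("Corrected Model", "Error", "Corrected Total"):
        if need not in t.index:
            raise ValueError(f"GlmTable missing row {need!r}")
    ss_tot = t.at["Corrected Total", "sum_sq"]
    if ss_tot == 0:
        return {"r_squared": float("nan"), "adj_r_squared": float("nan"), "F": {}}
    ss_err, df_err = t.at["Error", "sum_sq"], t.at["Error", "df"]
    df_tot = t.at["Corrected Total", "df"]
    r2 = t.at["Corrected Model", "sum_sq"] / ss_tot
    adj = 1.0 - (ss_err / df_err) / (ss_tot / df_tot)
    ms_err = ss_err / df_err
    F = {
        name: (t.at[name, "sum_sq"] / t.at[name, "df"]) / ms_err
        for name in t.index
        if name not in ("Error", "Total", "Corrected Total")
    }
    return {"r_squared": float(r2), "adj_r_squared": float(adj), "F": F}


def fit_logistic_wald(
    y: pd.Series,
    factors: pd.DataFrame,
    categorical: list[str],
    numeric: list[str] = [],
) -> pd.DataFrame:
    """Per-term Wald chi-square report from a logistic regression.

    Multi-level factors get a joint (multi-df) Wald test on their
    coefficient block.  Complete or quasi-complete separation is detected
    (non-finite or exploding estimates) and flagged in the ``separation``
    attribute rather than raising.
    """
    data = factors.copy()
    yv = y.loc[factors.index].astype(float)
    if yv.nunique() < 2:
        raise ValueError("outcome must have both classes")
    data["_y"] = yv
    data = data.dropna()
    model = smf.glm(
        f"_y ~ {_formula(categorical, numeric)}",
        data=data,
        family=sm.families.Binomial(),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit()
    separation = (
        not np.all(np.isfinite(res.params))
        or np.abs(res.params).max() > 50
        or any("separation" in str(w.message).lower() for w in caught)
    )
    if separation:
        log.warning("possible separation in logistic fit; Wald statistics unreliable")
    wt = res.wald_test_terms(scalar=True)
    tbl = wt.table.copy()
    rename = {f"C(Q('{c}'), Sum)": c for c in categorical}
    rename.update({f"Q('{x}')": x for x in numeric})
    tbl.index = [rename.get(i, i) for i in tbl.index]
    out = pd.DataFrame(
        {
            "wald_chi2": tbl["statistic"].astype(float),
            "df": tbl["df_constraint"].astype(float),
            "p": tbl["pvalue"].astype(float),
        }
    )
    out.attrs["separation"] = bool(separation)
    return out


def joint_term_ss(
    y: pd.Series,
    factors: pd.DataFrame,
    categorical: list[str],
    numeric: list[str],
    drop_categorical: list[str],
    drop_numeric: list[str],
) -> tuple[float, float]:
    """Joint Type III SS for a group of terms by full-vs-reduced comparison.

    Returns (joint SS, joint df): the increase in error SS when the listed
    terms are removed together from the full model.
    """
    data = factors.copy()
    data["_y"] = y.loc[factors.index].astype(float)
    data = data.dropna()

    def rss(cats, nums):
        res = smf.ols(f"_y ~ {_formula(cats, nums)}", data=data).fit()
        return float(res.ssr), float(res.df_resid)

    rss_full, df_full = rss(categorical, numeric)
    keep_c = [c for c in categorical if c not in drop_categorical]
    keep_n = [x for x in numeric if x not in drop_numeric]
    rss_red, df_red = rss(keep_c, keep_n)
    return rss_red - rss_full, df_red - df_full


def predictor_comparison_report(
    glm: GlmTable,
    wald: pd.DataFrame,
    segment_term: str = "segment",
    joint_demographics_ss: float | None = None,
) -> dict:
    """Juxtapose segment vs demographic effect sizes.

    Reports each term's partial eta-squared and Wald chi-square, the
    demographics' combined partial eta-squared (from the joint Type III SS
    when supplied, otherwise from the sum of the demographic term SS — the
    two differ slightly in non-orthogonal designs), and the ratio of the
    combined demographic eta-squared to the segment eta-squared.
    """
    t = glm.table
    terms = [
        i for i in t.index
        if i not in ("Corrected Model", "Intercept", "Error", "Total", "Corrected Total")
    ]
    if segment_term not in terms:
        raise ValueError(f"{segment_term!r} not among model terms")
    ss_error = t.at["Error", "sum_sq"]
    demo_terms = [i for i in terms if i != segment_term]
    demo_ss = (
        joint_demographics_ss
        if joint_demographics_ss is not None
        else float(t.loc[demo_terms, "sum_sq"].sum())
    )
    eta = {i: float(t.at[i, "partial_eta_sq"]) for i in terms}
    demo_eta = partial_eta_squared(demo_ss, ss_error)
    report = {
        "partial_eta_sq": eta,
        "demographics_combined_eta_sq": demo_eta,
        "eta_sq_ratio_demographics_vs_segment": demo_eta / eta[segment_term]
        if eta[segment_term] > 0
        else float("nan"),
        "wald_chi2": {i: float(wald.at[i, "wald_chi2"]) for i in wald.index if i != "Intercept"},
    }
    return report
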