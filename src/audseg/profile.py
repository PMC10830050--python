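"""Segment profiling tables with pairwise-test letter annotation.

Each profiling variable is summarized per segment (percentages for
categorical levels, means for numeric variables).  Cells are compared
pairwise — a two-proportion z test for percentages, a Welch t test for means,
at a per-comparison .05 level with no multiplicity correction, the market
research convention — and each segment column receives the letters of every
column it significantly exceeds.  The smallest cell in a row therefore never
carries a letter.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "two_proportion_z",
    "pairwise_mean_t",
    "letter_annotation",
    "ProfileTable",
    "build_profile_table",
    "render_profile_table",
]

log = logging.getLogger(__name__)


def two_proportion_z(p1: float, n1: float, p2: float, n2: float) -> tuple[float, float]:
    """Pooled two-sample z test for a difference in proportions (two-sided)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("bases must be >= 1")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def pairwise_mean_t(
    m1: float, s1: float, n1: float, m2: float, s2: float, n2: float
) -> tuple[float, float, float]:
    """Welch two-sample t test from summary statistics (two-sided).

    Returns (t, Welch-Satterthwaite df, p).  With both sds zero the statistic
    is 0 for equal means and +/-inf (p=0, flagged in the log) otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("sds must be >= 0")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        log.warning("degenerate t test: zero variance, unequal means")
        return float(np.sign(m1 - m2) * np.inf), float(n1 + n2 - 2), 0.0
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def letter_annotation(
    row_stats: pd.Series, pvalues: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Letter strings: column j lists every smaller column it beats at alpha.

    ``row_stats`` is indexed by segment (column order fixes the letters
    a, b, c, ...); ``pvalues`` is the symmetric pairwise p matrix.  The
    globally smallest column can never receive a letter.
    """
    cols = list(row_stats.index)
    letters = dict(zip(cols, string.ascii_lowercase))
    out = {}
    for j in cols:
        won = [
            letters[i]
            for i in cols
            if i != j
            and pd.notna(row_stats[i])
            and pd.notna(row_stats[j])
            and row_stats[i] < row_stats[j]
            and pvalues.at[i, j] < alpha
        ]
        out[j] = "".join(sorted(won))
    return pd.Series(out, index=cols)


@dataclass
class ProfileTable:
    """Variable-by-segment statistics with bases and significance letters."""

    stats: pd.DataFrame    # MultiIndex rows (variable, level) x segments
    letters: pd.DataFrame  # same shape, letter strings
    bases: pd.DataFrame    # same shape, base n used for each cell's test
    kinds: pd.Series       # variable -> "percentage" | "mean"


def _kish_neff(w: np.ndarray) -> float:
    sw = w.sum()
    return float(sw**2 / (w**2).sum()) if sw > 0 else 0.0


def build_profile_table(
    assignments: pd.Series | pd.DataFrame,
    variables: pd.DataFrame,
    weights: pd.Series | None = None,
    alpha: float = 0.05,
    segment_order: list[str] | None = None,
    use_effective_base: bool = True,
) -> ProfileTable:
    """Profile variables by segment with significance letters.

    Categorical variables yield one percentage row per level (levels
    exhaustive, so each segment's column sums to 100% within rounding);
    numeric variables yield a mean row.  With weights, cell statistics are
    weighted and tests run on Kish effective bases (configurable off).  An
    empty segment's cells are NaN with empty letters.
    """
    labels = assignments["label"] if isinstance(assignments, pd.DataFrame) else assignments
    labels = labels.loc[variables.index]
    segs = segment_order if segment_order is not None else sorted(labels.dropna().unique())
    w = (
        weights.loc[variables.index].to_numpy(dtype=float)
        if weights is not None
        else np.ones(len(variables))
    )

    stat_rows, letter_rows, base_rows, kinds = {}, {}, {}, {}
    for var in variables.columns:
        col = variables[var]
        numeric = pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2
        kinds[var] = "mean" if numeric else "percentage"
        if numeric:
            levels = ["mean"]
        else:
            levels = sorted(col.dropna().unique(), key=str)
        for level in levels:
            stats_j, bases_j, sds_j = {}, {}, {}
            for s in segs:
                in_seg = (labels == s).to_numpy() & col.notna().to_numpy()
                ws = w[in_seg]
                if ws.sum() == 0:
                    stats_j[s], bases_j[s], sds_j[s] = np.nan, 0.0, np.nan
                    continue
                vals = col.to_numpy()[in_seg]
                neff = _kish_neff(ws) if use_effective_base else float(in_seg.sum())
                bases_j[s] = neff
                if numeric:
                    mean = np.average(vals.astype(float), weights=ws)
                    var_ = np.average((vals.astype(float) - mean) ** 2, weights=ws)
                    nn = in_seg.sum()
                    stats_j[s] = mean
                    sds_j[s] = np.sqrt(var_ * nn / (nn - 1)) if nn > 1 else 0.0
                else:
                    stats_j[s] = float(np.average((vals == level).astype(float), weights=ws))
            row = pd.Series(stats_j, index=segs)
            pv = pd.DataFrame(np.ones((len(segs), len(segs))), index=segs, columns=segs)
            for a_i in range(len(segs)):
                for b_i in range(a_i + 1, len(segs)):
                    sa, sb = segs[a_i], segs[b_i]
                    if (
                        pd.isna(row[sa]) or pd.isna(row[sb])
                        or bases_j[sa] < 2 or bases_j[sb] < 2
                    ):
                        continue
                    if numeric:
                        _, _, p = pairwise_mean_t(
                            row[sa], sds_j[sa], bases_j[sa], row[sb], sds_j[sb], bases_j[sb]
                        )
                    else:
                        _, p = two_proportion_z(row[sa], bases_j[sa], row[sb], bases_j[sb])
                    pv.at[sa, sb] = pv.at[sb, sa] = p
            key = (var, str(level))
            display = row * 100 if not numeric else row
            stat_rows[key] = display
            letter_rows[key] = letter_annotation(row, pv, alpha)
            base_rows[key] = pd.Series(bases_j, index=segs)

    idx = pd.MultiIndex.from_tuples(stat_rows.keys(), names=["variable", "level"])
    return ProfileTable(
        stats=pd.DataFrame(stat_rows.values(), index=idx, columns=segs),
        letters=pd.DataFrame(letter_rows.values(), index=idx, columns=segs),
        bases=pd.DataFrame(base_rows.values(), index=idx, columns=segs),
        kinds=pd.Series(kinds),
    )


def render_profile_table(table: ProfileTable) -> str:
    """Human-readable rendering: statistic line with its letter line below."""
    lines = []
    segs = list(table.stats.columns)
    header = " " * 34 + "".join(f"{s[:12]:>14}" for s in segs)
    lines.append(header)
    letters_hdr = " " * 34 + "".join(f"{l:>14}" for l in string.ascii_lowercase[: len(segs)])
    lines.append(letters_hdr)
    last_var = None
    for (var, level), row in table.stats.iterrows():
        if var != last_var:
            lines.append(str(var).upper())
            last_var = var
        kind = table.kinds[var]
        cells = []
        for s in segs:
            v = row[s]
            cells.append(
                "n/a" if pd.isna(v)
                else (f"{v:.0f}%" if kind == "percentage" else f"{v:.1f}")
            )
        lines.append(f"  {str(level)[:30]:<32}" + "".join(f"{c:>14}" for c in cells))
        lets = table.letters.loc[(var, level)]
        lines.append(" " * 34 + "".join(f"{lets[s]:>14}" for s in segs))
    return "\n".join(lines)
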