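"""Respondent-level variability screening.

Inattentive panellists leave recognizable traces in block-level summary
statistics: straight-liners have (near-)zero variance across several blocks,
and extreme acquiescers sit at the top of the scale with almost no variance
("low variability, high mean") even across contradictory statements.  This
module computes per-respondent per-block means/variances, flags respondents
under configurable rules, and filters them out with an auditable report.

Blocks where a constant answer is perfectly reasonable (life-satisfaction
ratings, behaviour frequencies) are marked exempt in the BlockSpec and do not
count toward the rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BlockSpec, ResponseMatrix

__all__ = ["QCRules", "block_stats", "flag_low_variability", "apply_filter", "run_qc"]

log = logging.getLogger(__name__)

REASONS = ("none", "multi_block_invariant", "global_invariant", "high_mean_low_var")


@dataclass(frozen=True)
class QCRules:
    """Thresholds for the low-variability rules.

    var_eps
        A block counts as invariant when its sample variance is <= var_eps
        (default 0: strictly constant).
    min_invariant_blocks
        Number of invariant non-exempt blocks that triggers removal.
    high_mean_margin
        The "high mean" cut is (scale maximum - high_mean_margin).
    acq_var_max
        Variance ceiling for the high-mean-low-variability (extreme
        acquiescence) rule, applied to the overall non-exempt statistics.
    """

    var_eps: float = 0.0
    min_invariant_blocks: int = 3
    high_mean_margin: float = 0.25
    acq_var_max: float = 0.25


def block_stats(X: ResponseMatrix, blocks: BlockSpec | None = None) -> pd.DataFrame:
    """Per-respondent per-block mean and sample variance (ddof=1).

    Returns a frame indexed by respondent id with MultiIndex columns
    ``(block, "mean"|"var")``.  A block with fewer than two answered items
    has undefined variance (NaN); a respondent with no answered item at all
    in a block has NaN mean as well — error records, not crashes.
    """
    blocks = blocks if blocks is not None else X.blocks
    pieces: dict[tuple[str, str], pd.Series] = {}
    for b in blocks.blocks:
        cols = [c for c in blocks.items(b) if c in X.responses.columns]
        sub = X.responses[cols]
        answered = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        var[answered < 2] = np.nan
        pieces[(b, "mean")] = mean
        pieces[(b, "var")] = var
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["block", "stat"])
    return out


def flag_low_variability(
    stats: pd.DataFrame,
    blocks: BlockSpec,
    rules: QCRules = QCRules(),
    likert_levels: int = 5,
) -> pd.DataFrame:
    """Apply the low-variability rules to block statistics.

    Returns a per-respondent frame with ``flag_invariant``,
    ``flag_acquiescent_extreme`` and a single ``removal_reason`` drawn from
    ``REASONS`` (rule precedence: multi-block invariance, then overall
    invariance, then high-mean-low-variance).
    """
    non_exempt = [b for b in blocks.non_exempt_blocks if (b, "var") in stats.columns]
    var = stats.loc[:, [(b, "var") for b in non_exempt]]
    mean = stats.loc[:, [(b, "mean") for b in non_exempt]]

    invariant_blocks = (var <= rules.var_eps).sum(axis=1)
    # Overall (across all non-exempt blocks): every block invariant AND the
    # block means themselves do not vary beyond the epsilon.
    defined = var.notna().sum(axis=1)
    all_invariant = (var <= rules.var_eps).sum(axis=1) == defined
    mean_spread = mean.var(axis=1, ddof=1).fillna(0.0)
    global_invariant = all_invariant & (defined > 0) & (mean_spread <= rules.var_eps)

    multi_block = invariant_blocks >= rules.min_invariant_blocks
    overall_mean = mean.mean(axis=1)
    overall_var = var.mean(axis=1)
    high_cut = likert_levels - rules.high_mean_margin
    acq_extreme = (overall_mean >= high_cut) & (overall_var <= rules.acq_var_max)

    reason = np.select(
        [multi_block, global_invariant, acq_extreme],
        ["multi_block_invariant", "global_invariant", "high_mean_low_var"],
        default="none",
    )
    return pd.DataFrame(
        {
            "flag_invariant": multi_block | global_invariant,
            "flag_acquiescent_extreme": acq_extreme,
            "removal_reason": reason,
        },
        index=stats.index,
    )


def apply_filter(
    X: ResponseMatrix, flags: pd.DataFrame
) -> tuple[ResponseMatrix, dict[str, int]]:
    """Drop flagged respondents; return the filtered matrix and a report.

    The report counts removals per reason plus ``retained``/``removed``
    totals; the input matrix is left unmodified.
    """
    if not flags.index.equals(X.ids):
        if set(flags.index) != set(X.ids):
            raise ValueError("flags are not aligned with the response matrix")
        flags = flags.loc[X.ids]
    keep = flags["removal_reason"] == "none"
    report = {r: int((flags["removal_reason"] == r).sum()) for r in REASONS if r != "none"}
    report["removed"] = int((~keep).sum())
    report["retained"] = int(keep.sum())
    if report["retained"] == 0 and len(X.ids) > 0:
        log.warning("QC removed every respondent")
    return X.subset(X.ids[keep.to_numpy()]), report


def run_qc(
    X: ResponseMatrix, rules: QCRules = QCRules()
) -> tuple[ResponseMatrix, pd.DataFrame, dict[str, int]]:
    """Convenience wrapper: stats -> flags -> filter."""
    stats = block_stats(X)
    flags = flag_low_variability(stats, X.blocks, rules, X.likert_levels)
    filtered, report = apply_filter(X, flags)
    log.info("QC removed %d of %d respondents", report["removed"], X.n_respondents)
    return filtered, flags, report
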