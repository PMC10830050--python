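"""Question-level and respondent-level (ipsative) standardization.

Most items are z-scored per question so that item means are 0 and sds are 1.
For designated blocks where acquiescence bias concentrates, standardization
is instead performed within each respondent: values are centered on the
respondent's own mean and scaled by the respondent's own sd over those
blocks.  An additive response-style shift (a tendency to agree with
everything) is a pure location effect at the respondent level, so ipsative
scaling removes it exactly while leaving the signed attitude pattern intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BlockSpec, ResponseMatrix

__all__ = [
    "StandardizedMatrix",
    "standardize_by_question",
    "standardize_by_respondent",
    "standardize",
    "standardization_diagnostics",
]

log = logging.getLogger(__name__)


@dataclass
class StandardizedMatrix:
    """Standardized respondents x items values with per-item applied mode."""

    values: pd.DataFrame
    applied_mode: pd.Series  # item -> "question" | "respondent"
    flagged_constant_rows: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def ids(self) -> pd.Index:
        return self.values.index


def standardize_by_question(
    X: ResponseMatrix | pd.DataFrame,
    items: list[str] | None = None,
    on_constant: str = "zero",
) -> StandardizedMatrix:
    """Center each item by its mean and scale by its sample sd (ddof=1).

    Constant columns carry no information; they are set to 0 with a warning
    (``on_constant="error"`` raises instead).  Missing values are excluded
    pairwise and stay missing.
    """
    df = X.responses if isinstance(X, ResponseMatrix) else X
    if items is not None:
        df = df[items]
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    constant = sd.fillna(0.0) == 0.0
    if constant.any():
        if on_constant == "error":
            raise ValueError(f"constant columns: {list(df.columns[constant])[:5]}")
        log.warning("%d constant column(s) set to 0", int(constant.sum()))
    z = (df - mean) / sd.replace(0.0, np.nan)
    z.loc[:, constant] = 0.0
    mode = pd.Series("question", index=df.columns)
    return StandardizedMatrix(values=z, applied_mode=mode)


def standardize_by_respondent(
    X: ResponseMatrix | pd.DataFrame,
    block_subset: list[str] | None = None,
) -> StandardizedMatrix:
    """Ipsative scaling within the designated blocks.

    Each respondent's values over the designated items are centered by that
    respondent's own mean and divided by the respondent's own sample sd over
    those items.  Rows with zero within-respondent sd become 0 and are
    flagged.  The transform is exactly invariant to adding a constant to a
    respondent's row — the acquiescence-correction property.
    """
    if isinstance(X, ResponseMatrix):
        blocks = block_subset if block_subset is not None else sorted(
            X.blocks.respondent_standardized
        )
        cols = X.blocks.items_in(blocks)
        df = X.responses[cols]
    else:
        df = X if block_subset is None else X[block_subset]
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd.fillna(0.0) == 0.0
    z = df.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    z.loc[constant, :] = 0.0
    flagged = df.index[constant]
    if len(flagged):
        log.warning("%d constant row(s) set to 0 and flagged", len(flagged))
    mode = pd.Series("respondent", index=df.columns)
    return StandardizedMatrix(values=z, applied_mode=mode, flagged_constant_rows=flagged)


def standardize(X: ResponseMatrix, respondent_level: bool = True) -> StandardizedMatrix:
    """Dual-mode standardization driven by the BlockSpec.

    Blocks marked ``respondent_standardized`` get ipsative scaling (unless
    ``respondent_level=False``, which forces question-level everywhere — the
    uncorrected comparison arm); all other blocks are question-standardized.
    """
    resp_blocks = sorted(X.blocks.respondent_standardized) if respondent_level else []
    resp_items = X.blocks.items_in(resp_blocks) if resp_blocks else []
    q_items = [c for c in X.responses.columns if c not in set(resp_items)]
    zq = standardize_by_question(X.responses[q_items]) if q_items else None
    parts = []
    modes = []
    flagged = pd.Index([])
    if zq is not None:
        parts.append(zq.values)
        modes.append(zq.applied_mode)
    if resp_items:
        zr = standardize_by_respondent(X.responses[resp_items])
        parts.append(zr.values)
        modes.append(zr.applied_mode)
        flagged = zr.flagged_constant_rows
    values = pd.concat(parts, axis=1)[X.responses.columns]
    mode = pd.concat(modes)[X.responses.columns]
    return StandardizedMatrix(values=values, applied_mode=mode, flagged_constant_rows=flagged)


def standardization_diagnostics(Z: StandardizedMatrix) -> pd.DataFrame:
    """Post-hoc per-column mean/sd report.

    Question-mode columns are 0/1 by construction; respondent-mode columns
    are only approximately so — the report's ``max |mean|`` and
    ``max |sd - 1|`` over respondent-mode columns quantify how close.
    """
    if Z.values.shape[1] == 0:
        return pd.DataFrame(columns=["mode", "mean", "sd"])
    out = pd.DataFrame(
        {
            "mode": Z.applied_mode,
            "mean": Z.values.mean(axis=0),
            "sd": Z.values.std(axis=0, ddof=1),
        }
    )
    resp = out[out["mode"] == "respondent"]
    if len(resp):
        log.info(
            "respondent-mode columns: max|mean|=%.4f max|sd-1|=%.4f",
            resp["mean"].abs().max(),
            (resp["sd"] - 1).abs().max(),
        )
    return out
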