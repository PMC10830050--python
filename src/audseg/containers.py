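"""Core in-memory containers for survey segmentation data.

The central object is :class:`ResponseMatrix`: a respondents x items table of
integer Likert codes together with the item->block map, per-respondent
demographics, binary outcome indicators, sample-source flags and optional
weights.  All tabular payloads are plain pandas objects indexed by respondent
id, so every downstream module can rely on ordinary pandas alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["BlockSpec", "ResponseMatrix"]


@dataclass(frozen=True)
class BlockSpec:
    """Item->block map with per-block screening/standardization roles.

    Parameters
    ----------
    item_block
        Maps every item id to exactly one block id.
    exempt
        Blocks excluded from low-variability screening (blocks where a
        constant response is plausible, e.g. life-satisfaction ratings).
    respondent_standardized
        Blocks standardized at the respondent (ipsative) level instead of the
        question level, the remedy applied where acquiescence bias
        concentrates.
    """

    item_block: Mapping[str, str]
    exempt: frozenset = frozenset()
    respondent_standardized: frozenset = frozenset()

    def __post_init__(self) -> None:
        blocks = set(self.item_block.values())
        if not blocks:
            raise ValueError("BlockSpec needs at least one item")
        unknown = (set(self.exempt) | set(self.respondent_standardized)) - blocks
        if unknown:
            raise ValueError(f"unknown block ids: {sorted(unknown)}")
        if not (blocks - set(self.exempt)):
            raise ValueError("at least one block must be non-exempt")

    @property
    def blocks(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.item_block.values():
            seen.setdefault(b)
        return list(seen)

    @property
    def non_exempt_blocks(self) -> list[str]:
        return [b for b in self.blocks if b not in self.exempt]

    def items(self, block: str) -> list[str]:
        out = [i for i, b in self.item_block.items() if b == block]
        if not out:
            raise KeyError(f"unknown block id: {block!r}")
        return out

    def items_in(self, blocks: Iterable[str]) -> list[str]:
        blocks = list(blocks)
        for b in blocks:
            if b not in set(self.item_block.values()):
                raise KeyError(f"unknown block id: {b!r}")
        want = set(blocks)
        return [i for i, b in self.item_block.items() if b in want]

    def to_dict(self) -> dict:
        return {
            "item_block": dict(self.item_block),
            "exempt": sorted(self.exempt),
            "respondent_standardized": sorted(self.respondent_standardized),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BlockSpec":
        return cls(
            item_block=dict(d["item_block"]),
            exempt=frozenset(d.get("exempt", ())),
            respondent_standardized=frozenset(d.get("respondent_standardized", ())),
        )


@dataclass
class ResponseMatrix:
    """Respondents x Likert-items table plus per-respondent metadata.

    ``responses`` holds float values that are integer Likert codes or NaN for
    missing; the float dtype is deliberate so that missingness survives
    round-trips without a sentinel.
    """

    responses: pd.DataFrame
    blocks: BlockSpec
    likert_levels: int = 5
    demographics: pd.DataFrame | None = None
    outcomes: pd.DataFrame | None = None
    sample_source: pd.Series | None = None
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        missing = set(self.responses.columns) - set(self.blocks.item_block)
        if missing:
            raise ValueError(f"items without a block: {sorted(missing)[:5]}")
        if self.responses.index.has_duplicates:
            raise ValueError("duplicate respondent ids")
        for attr in ("demographics", "outcomes", "sample_source", "weights"):
            obj = getattr(self, attr)
            if obj is not None and not obj.index.equals(self.responses.index):
                raise ValueError(f"{attr} index does not match responses index")

    @property
    def ids(self) -> pd.Index:
        return self.responses.index

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def items(self) -> list[str]:
        return list(self.responses.columns)

    def copy(self) -> "ResponseMatrix":
        return replace(
            self,
            responses=self.responses.copy(),
            demographics=None if self.demographics is None else self.demographics.copy(),
            outcomes=None if self.outcomes is None else self.outcomes.copy(),
            sample_source=None if self.sample_source is None else self.sample_source.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )

    def subset(self, ids: Iterable) -> "ResponseMatrix":
        """Restrict to the given respondent ids (order preserved)."""
        idx = pd.Index(ids)
        bad = idx.difference(self.responses.index)
        if len(bad):
            raise KeyError(f"unknown respondent ids: {list(bad[:5])}")
        return replace(
            self,
            responses=self.responses.loc[idx],
            demographics=None if self.demographics is None else self.demographics.loc[idx],
            outcomes=None if self.outcomes is None else self.outcomes.loc[idx],
            sample_source=None if self.sample_source is None else self.sample_source.loc[idx],
            weights=None if self.weights is None else self.weights.loc[idx],
        )
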