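"""Synthetic Likert-survey populations with known latent segments.

The generator emulates the statistical structure the segmentation analysis
assumes: respondents belong to one of ``n_segments`` latent segments (plus a
small "central" group with no distinctive views), each segment has its own
centroid in a ~10-dimensional attitude-factor space, items load on factors
with signed loadings and are observed as integer Likert codes, and a minority
of respondents exhibit response styles (acquiescence: uniform shift toward
the agreement pole on designated blocks; straight-lining: one constant answer
throughout).  Binary outcomes (vaccination status, past-two-week protective
behaviours) are drawn from segment-specific rates.

Ground truth (segment membership and response-style flags) is returned
alongside the data so recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BlockSpec, ResponseMatrix

__all__ = [
    "SynthConfig",
    "SEGMENT_NAMES",
    "default_config",
    "generate_population",
    "inject_acquiescence",
    "inject_straightliners",
    "attach_outcomes",
]

#: Canonical segment names, ordered as profiled in reporting (columns a..g).
SEGMENT_NAMES = (
    "trusting_complier",
    "concerned_cooperator",
    "fearful_overwhelmed",
    "informed_responsible",
    "nonchalant",
    "unconcerned_uncooperative",
    "skeptical_resister",
)

CENTRAL = "central"

# Factor names for the ten-factor default instrument.
FACTOR_NAMES = (
    "manageability",
    "effectiveness",
    "concern",
    "well_being",
    "self_care",
    "sociability",
    "self_reliance",
    "world_anxiety",
    "guidance_trust",
    "health_anxiety",
)

# Segment centroid pattern (segments x factors), in within-segment sd units
# before scaling.  Signs follow the narrative profile of each segment
# (e.g. resisters: risks "manageable"/dismissed, low trust in guidance).
_CENTROID_PATTERN = np.array(
    [
        # man   eff   con   wb    sc    soc   sr    wa    gt    ha
        [-1.0,  1.0,  0.5,  1.0,  1.0,  0.0,  0.0,  0.5,  1.5,  0.5],
        [-1.0,  1.0,  1.0,  0.0,  0.0,  0.0, -0.5,  1.0,  0.5,  1.0],
        [-1.5,  0.0,  1.5, -1.5, -0.5, -0.5, -1.0,  1.5, -1.0,  1.5],
        [ 0.0,  0.5,  0.0,  1.0,  1.0,  0.5,  1.5,  0.0,  0.5,  0.0],
        [ 0.5,  0.0, -0.5,  0.0,  0.0,  1.0,  0.0, -0.5, -0.5, -0.5],
        [ 1.5, -1.0, -1.5,  0.0, -0.5,  1.5,  0.0, -1.0, -1.0, -1.5],
        [ 1.5, -1.5, -1.0, -0.5,  0.0,  0.5,  1.0, -0.5, -2.0, -1.0],
    ]
)

# Reported population shares are (14,14,13,13,15,21,15)% which total 105%;
# normalized onto the simplex for sampling.
_RAW_SHARES = np.array([0.14, 0.14, 0.13, 0.13, 0.15, 0.21, 0.15])
DEFAULT_MIXING = tuple(_RAW_SHARES / _RAW_SHARES.sum())

#: Outcome rates per segment (rows ordered as SEGMENT_NAMES), patterned on the
#: published vaccination-status and protective-behaviour percentages; the two
#: behaviours without published rates are set to plausible interpolations.
DEFAULT_OUTCOME_RATES = pd.DataFrame(
    {
        "vax_boosted":    [0.88, 0.80, 0.72, 0.83, 0.59, 0.39, 0.46],
        "vax_no_booster": [0.09, 0.13, 0.16, 0.11, 0.21, 0.22, 0.19],
        "vax_refusal":    [0.005, 0.01, 0.03, 0.02, 0.02, 0.08, 0.24],
        "mask":           [0.96, 0.92, 0.88, 0.92, 0.76, 0.53, 0.69],
        "handwash":       [0.90, 0.87, 0.81, 0.80, 0.62, 0.46, 0.50],
        "distancing":     [0.86, 0.77, 0.73, 0.62, 0.55, 0.35, 0.28],
        "avoid_crowded":  [0.82, 0.76, 0.71, 0.64, 0.52, 0.36, 0.33],
        "open_window":    [0.70, 0.66, 0.63, 0.58, 0.50, 0.42, 0.44],
    },
    index=list(SEGMENT_NAMES),
)

# Demographic profiles per segment: mean age, share female, ethnicity
# distribution, social grade distribution, mean education (1-5) and income
# band (1-7), patterned on the published demographic profile table.
_AGE_MEAN = dict(zip(SEGMENT_NAMES, [58, 54, 48, 56, 43, 36, 48]))
_FEMALE = dict(zip(SEGMENT_NAMES, [0.44, 0.51, 0.64, 0.40, 0.55, 0.51, 0.53]))
_ETHNICITY = {
    s: dict(zip(["white", "asian", "black", "other"], p))
    for s, p in zip(
        SEGMENT_NAMES,
        [
            [0.90, 0.06, 0.02, 0.02],
            [0.88, 0.07, 0.03, 0.02],
            [0.88, 0.07, 0.02, 0.03],
            [0.91, 0.05, 0.02, 0.02],
            [0.81, 0.12, 0.04, 0.03],
            [0.81, 0.09, 0.05, 0.05],
            [0.92, 0.03, 0.03, 0.02],
        ],
    )
}
_SOCIAL_GRADE = {
    s: dict(zip(["AB", "C1C2", "DE"], np.asarray(p) / np.sum(p)))
    for s, p in zip(
        SEGMENT_NAMES,
        [
            [0.33, 0.49, 0.18],
            [0.22, 0.54, 0.24],
            [0.17, 0.47, 0.36],
            [0.28, 0.51, 0.21],
            [0.23, 0.54, 0.23],
            [0.20, 0.55, 0.25],
            [0.17, 0.53, 0.31],
        ],
    )
}
_EDU_MEAN = dict(zip(SEGMENT_NAMES, [3.6, 3.2, 2.8, 3.5, 3.0, 2.9, 2.8]))
_INCOME_MEAN = dict(zip(SEGMENT_NAMES, [4.5, 4.0, 3.2, 4.4, 3.8, 3.3, 3.2]))


def _default_item_spec() -> list[tuple[str, str, float, str]]:
    """Default 112-item instrument: (item id, factor, signed loading, block).

    Twelve blocks; the two manageability blocks (b01, b02) are where the
    acquiescence remedy applies and carry deliberately sign-imbalanced
    loadings, mirroring attitude batteries that are mostly positively keyed.
    Block b07 (well-being/satisfaction) and b08 (self-care/sociability
    behaviour frequency) are exempt from low-variability screening.
    """
    mags = [0.70, 0.80, 0.60, 0.75, 0.85, 0.65]
    spec: list[tuple[str, str, float, str]] = []

    def add(prefix: str, factor: str, blocks: Sequence[tuple[str, int]], neg: set[int]):
        j = 0
        for block, count in blocks:
            for _ in range(count):
                j += 1
                sign = -1.0 if j in neg else 1.0
                spec.append((f"{prefix}_{j:02d}", factor, sign * mags[j % len(mags)], block))

    add("man", "manageability", [("b01", 11), ("b02", 11)], {3, 7, 10, 13, 17, 20, 22})
    add("eff", "effectiveness", [("b03", 12), ("b04", 12), ("b05", 11)], {5, 12, 19, 26, 33})
    add("con", "concern", [("b06", 7), ("b12", 7)], {4, 9, 13})
    add("wb", "well_being", [("b07", 12)], {3, 8, 11})
    add("sc", "self_care", [("b08", 4)], set())
    add("soc", "sociability", [("b08", 6)], {2, 5})
    add("sr", "self_reliance", [("b09", 5)], {4})
    add("wa", "world_anxiety", [("b10", 6)], {5})
    add("gt", "guidance_trust", [("b11", 3)], {2})
    add("ha", "health_anxiety", [("b11", 5)], {3})
    return spec


@dataclass
class SynthConfig:
    """Configuration of one synthetic survey population.

    The defaults are the study conditions the package's tests and worked
    examples run under: ~5,500 respondents, 7 segments at the published
    (normalized) shares, a 2% central group, 10% acquiescent respondents
    shifted 1.5 scale points toward agreement on the two designated blocks,
    and 4% straight-liners.
    """

    n_respondents: int = 5507
    n_segments: int = 7
    mixing_proportions: Sequence[float] = DEFAULT_MIXING
    segment_names: Sequence[str] = SEGMENT_NAMES
    factor_names: Sequence[str] = FACTOR_NAMES
    factor_centroids: np.ndarray | None = None  # segments x factors
    centroid_scale: float = 2.0
    item_loading_spec: Sequence[tuple[str, str, float, str]] = field(
        default_factory=_default_item_spec
    )
    exempt_blocks: Sequence[str] = ("b07", "b08")
    acquiescence_blocks: Sequence[str] = ("b01", "b02")
    likert_levels: int = 5
    within_sd: float = 1.0
    noise_sd: float = 0.8
    acquiescence_fraction: float = 0.10
    acquiescence_shift: float = 2.5
    straightliner_fraction: float = 0.04
    central_fraction: float = 0.02
    outcome_rates: pd.DataFrame | None = None  # segment (+central) x outcome
    booster_fraction: float = 0.25
    telephone_fraction: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        mix = np.asarray(self.mixing_proportions, dtype=float)
        if len(mix) != self.n_segments:
            raise ValueError("mixing_proportions length must equal n_segments")
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixing_proportions must be a simplex (sum 1)")
        if len(self.segment_names) != self.n_segments:
            raise ValueError("segment_names length must equal n_segments")
        if self.factor_centroids is None:
            if (self.n_segments, len(self.factor_names)) != _CENTROID_PATTERN.shape:
                raise ValueError(
                    "factor_centroids must be given explicitly unless using the "
                    "default 7-segment, 10-factor geometry"
                )
            self.factor_centroids = _CENTROID_PATTERN * self.centroid_scale
        self.factor_centroids = np.asarray(self.factor_centroids, dtype=float)
        if self.factor_centroids.shape != (self.n_segments, len(self.factor_names)):
            raise ValueError("factor_centroids must be n_segments x n_factors")
        known = set(self.factor_names)
        for item, factor, loading, _block in self.item_loading_spec:
            if factor not in known:
                raise ValueError(f"item {item!r} loads on unknown factor {factor!r}")
            if not np.isfinite(loading) or loading == 0:
                raise ValueError(f"item {item!r} has invalid loading {loading!r}")
        for frac in (
            self.acquiescence_fraction,
            self.straightliner_fraction,
            self.central_fraction,
            self.booster_fraction,
            self.telephone_fraction,
            self.missing_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.acquiescence_shift < 0:
            raise ValueError("noise_sd and acquiescence_shift must be >= 0")
        if self.outcome_rates is None:
            if tuple(self.segment_names) == SEGMENT_NAMES:
                rates = DEFAULT_OUTCOME_RATES.copy()
                rates.loc[CENTRAL] = rates.mean(axis=0)
                self.outcome_rates = rates
        if self.outcome_rates is not None:
            vals = self.outcome_rates.to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("outcome_rates must lie in [0, 1]")
            need = set(self.segment_names) | {CENTRAL}
            if not need <= set(self.outcome_rates.index):
                raise ValueError("outcome_rates needs a row per segment plus 'central'")

    def block_spec(self) -> BlockSpec:
        return BlockSpec(
            item_block={item: block for item, _f, _l, block in self.item_loading_spec},
            exempt=frozenset(self.exempt_blocks),
            respondent_standardized=frozenset(self.acquiescence_blocks),
        )


def default_config(**overrides) -> SynthConfig:
    """The default study-conditions configuration, with keyword overrides."""
    return SynthConfig(**overrides)


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _discretize(latent: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of each column over mean +/- 3 sd, clipped.

    Monotone in the latent value and reproduces floor/ceiling pile-up for
    extreme respondents.
    """
    out = np.empty_like(latent, dtype=float)
    for j in range(latent.shape[1]):
        y = latent[:, j]
        s = y.std(ddof=1) if len(y) > 1 else 0.0
        if s == 0:
            out[:, j] = (levels + 1) // 2
            continue
        lo = y.mean() - 3 * s
        width = 6 * s / levels
        codes = 1 + np.floor((y - lo) / width)
        out[:, j] = np.clip(codes, 1, levels)
    return out


def generate_population(config: SynthConfig) -> tuple[ResponseMatrix, pd.DataFrame]:
    """Generate one synthetic population and its ground-truth table.

    Returns
    -------
    (ResponseMatrix, truth)
        ``truth`` has one row per respondent: ``true_segment`` (a segment
        name or ``"central"``), ``acquiescent`` and ``straightliner`` flags,
        and ``sample_source`` (core/booster/telephone).
    """
    cfg = config
    n = cfg.n_respondents
    rngs = _substreams(
        cfg.seed,
        [
            "segments", "central", "factors", "items", "styles",
            "straightline_values", "demographics", "outcomes", "source", "missing",
        ],
    )
    ids = pd.Index([f"r{i:05d}" for i in range(n)], name="respondent_id")
    blocks = cfg.block_spec()
    items = [it for it, _f, _l, _b in cfg.item_loading_spec]

    if n == 0:
        empty = ResponseMatrix(
            responses=pd.DataFrame(index=ids, columns=items, dtype=float),
            blocks=blocks,
            likert_levels=cfg.likert_levels,
        )
        truth = pd.DataFrame(
            index=ids,
            columns=["true_segment", "acquiescent", "straightliner", "sample_source"],
        )
        return empty, truth

    # --- latent segment membership -------------------------------------
    seg_idx = rngs["segments"].choice(
        cfg.n_segments, size=n, p=np.asarray(cfg.mixing_proportions, dtype=float)
    )
    central = rngs["central"].random(n) < cfg.central_fraction
    seg_names = np.asarray(cfg.segment_names, dtype=object)
    true_segment = np.where(central, CENTRAL, seg_names[seg_idx])

    # --- latent factor scores ------------------------------------------
    mix = np.asarray(cfg.mixing_proportions, dtype=float)
    grand = mix @ cfg.factor_centroids
    centers = cfg.factor_centroids[seg_idx]
    centers = np.where(central[:, None], grand[None, :], centers)
    n_fac = len(cfg.factor_names)
    f = centers + rngs["factors"].normal(0.0, cfg.within_sd, size=(n, n_fac))

    # --- item responses -------------------------------------------------
    fac_pos = {name: j for j, name in enumerate(cfg.factor_names)}
    load = np.zeros((n_fac, len(items)))
    for j, (item, factor, loading, _b) in enumerate(cfg.item_loading_spec):
        load[fac_pos[factor], j] = loading
    latent = f @ load
    if cfg.noise_sd > 0:
        latent = latent + rngs["items"].normal(0.0, cfg.noise_sd, size=latent.shape)
    codes = _discretize(latent, cfg.likert_levels)
    X = ResponseMatrix(
        responses=pd.DataFrame(codes, index=ids, columns=items),
        blocks=blocks,
        likert_levels=cfg.likert_levels,
    )

    # --- response styles (mutually exclusive flags) ---------------------
    u = rngs["styles"].random(n)
    straight = u < cfg.straightliner_fraction
    acq = (~straight) & (u < cfg.straightliner_fraction + cfg.acquiescence_fraction)

    truth = pd.DataFrame(
        {
            "true_segment": true_segment,
            "acquiescent": acq,
            "straightliner": straight,
        },
        index=ids,
    )

    if cfg.acquiescence_shift > 0 and acq.any():
        X = inject_acquiescence(X, truth, cfg.acquiescence_blocks, cfg.acquiescence_shift)
    if straight.any():
        X = inject_straightliners(X, truth, rng=rngs["straightline_values"])

    # --- demographics ----------------------------------------------------
    X.demographics = _draw_demographics(true_segment, rngs["demographics"])

    # --- outcomes --------------------------------------------------------
    if cfg.outcome_rates is not None:
        X = attach_outcomes(X, truth, cfg.outcome_rates, rng=rngs["outcomes"])

    # --- sample source and weights --------------------------------------
    v = rngs["source"].random(n)
    source = np.where(
        v < cfg.telephone_fraction,
        "telephone",
        np.where(v < cfg.telephone_fraction + cfg.booster_fraction, "booster", "core"),
    )
    X.sample_source = pd.Series(source, index=ids, name="sample_source")
    truth["sample_source"] = X.sample_source
    X.weights = pd.Series(1.0, index=ids, name="weight")

    if cfg.missing_rate > 0:
        mask = rngs["missing"].random(X.responses.shape) < cfg.missing_rate
        X.responses = X.responses.mask(mask)

    return X, truth


def _draw_demographics(true_segment: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(true_segment)
    age = np.empty(n)
    female = np.empty(n, dtype=object)
    ethnicity = np.empty(n, dtype=object)
    grade = np.empty(n, dtype=object)
    edu = np.empty(n)
    income = np.empty(n)
    grand_age = float(np.mean(list(_AGE_MEAN.values())))
    for i, seg in enumerate(true_segment):
        if seg == CENTRAL:
            a_mu, fem, eth, grd = grand_age, 0.51, _ETHNICITY["nonchalant"], _SOCIAL_GRADE["nonchalant"]
            e_mu, i_mu = 3.1, 3.8
        else:
            a_mu, fem = _AGE_MEAN[seg], _FEMALE[seg]
            eth, grd = _ETHNICITY[seg], _SOCIAL_GRADE[seg]
            e_mu, i_mu = _EDU_MEAN[seg], _INCOME_MEAN[seg]
        age[i] = np.clip(rng.normal(a_mu, 13.0), 18, 90)
        female[i] = "female" if rng.random() < fem else "male"
        ethnicity[i] = rng.choice(list(eth), p=list(eth.values()))
        grade[i] = rng.choice(list(grd), p=list(grd.values()))
        edu[i] = np.clip(np.round(rng.normal(e_mu, 1.2)), 1, 5)
        income[i] = np.clip(np.round(rng.normal(i_mu, 1.2)), 1, 7)
    return pd.DataFrame(
        {
            "age": age,
            "gender": female,
            "ethnicity": ethnicity,
            "social_grade": grade,
            "education": edu,
            "income": income,
        },
        index=pd.Index(range(n)),
    ).set_axis(pd.Index([f"r{i:05d}" for i in range(n)], name="respondent_id"), axis=0)


def inject_acquiescence(
    X: ResponseMatrix,
    truth: pd.DataFrame,
    blocks: Iterable[str],
    shift: float,
) -> ResponseMatrix:
    """Shift flagged respondents' designated-block answers toward agreement.

    Responses move by ``shift`` scale points (rounded back to integer codes)
    and are clipped at the scale maximum; respondents without the
    ``acquiescent`` flag, and items outside ``blocks``, are untouched.  The
    truth table is not modified: acquiescence is a response style layered on
    top of the latent segment, not a change of segment.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    out = X.copy()
    if shift == 0:
        return out
    cols = X.blocks.items_in(blocks)  # raises KeyError on unknown block
    flagged = truth.loc[X.ids, "acquiescent"].to_numpy(dtype=bool)
    if flagged.any():
        sub = out.responses.loc[flagged, cols]
        out.responses.loc[flagged, cols] = np.minimum(
            float(X.likert_levels), np.round(sub + shift)
        )
    return out


def inject_straightliners(
    X: ResponseMatrix,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Replace flagged respondents' answers with one constant per respondent.

    The constant is drawn uniformly from the scale and applied to every item
    of every non-exempt block (exempt blocks keep their original values, as
    a constant answer there is unremarkable).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = X.copy()
    flagged = truth.loc[X.ids, "straightliner"].to_numpy(dtype=bool)
    if not flagged.any():
        return out
    cols = X.blocks.items_in(X.blocks.non_exempt_blocks)
    values = rng.integers(1, X.likert_levels + 1, size=int(flagged.sum())).astype(float)
    out.responses.loc[flagged, cols] = values[:, None]
    return out


def attach_outcomes(
    X: ResponseMatrix,
    truth: pd.DataFrame,
    outcome_rates: pd.DataFrame,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Draw binary outcome columns from each respondent's true-segment rates."""
    vals = outcome_rates.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("outcome probabilities must lie in [0, 1]")
    segs = truth.loc[X.ids, "true_segment"]
    missing = set(segs.unique()) - set(outcome_rates.index)
    if missing:
        raise ValueError(f"outcome_rates missing rows for segments: {sorted(missing)}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    probs = outcome_rates.loc[segs].to_numpy(dtype=float)
    draws = (rng.random(probs.shape) < probs).astype(int)
    out = X.copy()
    out.outcomes = pd.DataFrame(draws, index=X.ids, columns=outcome_rates.columns)
    return out
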