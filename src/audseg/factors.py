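"""Factor construction, scoring, reliability, and meta-factors.

Measures are built empirically: exploratory factor analysis (principal-axis
factoring with varimax or oblimin rotation) proposes item sets; each factor
is a signed-loading weighted sum of standardized items (negative loadings
reverse-code items pointing the other way); Cronbach's alpha — computed after
flipping negatively keyed items — gates reliability at the conventional 0.7;
correlated first-order factors can be combined into a smaller set of
second-order "meta-factors".
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .standardize import StandardizedMatrix

__all__ = [
    "FactorModel",
    "cronbach_alpha",
    "model_alpha",
    "fit_efa",
    "score_factors",
    "build_meta_factors",
    "refine_to_reliable",
    "RefinementResult",
    "default_factor_models",
    "align_loadings",
    "tucker_congruence",
]

log = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """A named factor: items with signed loadings, reliability, lineage."""

    name: str
    items: list[tuple[str, float]]
    alpha: float = float("nan")
    role: str = "base"  # "base" | "meta"
    parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role == "base" and len(self.items) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 items")
        for item, loading in self.items:
            if not np.isfinite(loading) or loading == 0:
                raise ValueError(f"factor {self.name!r}: invalid loading for {item!r}")

    @property
    def item_ids(self) -> list[str]:
        return [i for i, _ in self.items]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [{"id": i, "loading": l} for i, l in self.items],
            "alpha": None if np.isnan(self.alpha) else self.alpha,
            "role": self.role,
            "parents": list(self.parents),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        return cls(
            name=d["name"],
            items=[(e["id"], float(e["loading"])) for e in d["items"]],
            alpha=float("nan") if d.get("alpha") is None else float(d["alpha"]),
            role=d.get("role", "base"),
            parents=list(d.get("parents", [])),
        )


def save_models(models: list[FactorModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=2)


def load_models(path) -> list[FactorModel]:
    with open(path) as fh:
        return [FactorModel.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency reliability of a multi-item scale.

    alpha = k/(k-1) * (1 - sum(item variances) / variance of the sum), with
    sample (ddof=1) variances.  Items must already be keyed in a consistent
    direction.  Returns NaN (with a warning) when the total score does not
    vary.
    """
    M = np.asarray(item_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    k = M.shape[1]
    item_vars = M.var(axis=0, ddof=1)
    total_var = M.sum(axis=1).var(ddof=1)
    if total_var == 0:
        log.warning("zero total-score variance: alpha undefined")
        return float("nan")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def model_alpha(Z: pd.DataFrame | StandardizedMatrix, model: FactorModel) -> float:
    """Alpha for a factor model's items, reverse-coding negative loadings."""
    df = Z.values if isinstance(Z, StandardizedMatrix) else Z
    missing = [i for i in model.item_ids if i not in df.columns]
    if missing:
        raise KeyError(f"items not in data: {missing[:5]}")
    keyed = df[model.item_ids] * np.sign([l for _, l in model.items])
    return cronbach_alpha(keyed.to_numpy())


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------

def _paf(R: np.ndarray, m: int, max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Principal-axis factoring: iterated communalities on the reduced R."""
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        R = R + 1e-6 * np.eye(p)
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    h = np.clip(smc, 0.0, 0.999)
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:m]
        lam = np.clip(w[idx], 0.0, None)
        L = V[:, idx] * np.sqrt(lam)
        h_new = np.clip((L**2).sum(axis=1), 0.0, 0.9999)
        if np.max(np.abs(h_new - h)) < tol:
            return L
        h = h_new
    raise RuntimeError(f"principal-axis factoring did not converge in {max_iter} iterations")


def _principal(R: np.ndarray, m: int) -> np.ndarray:
    """Principal-component extraction from a correlation matrix."""
    w, V = np.linalg.eigh(R)
    idx = np.argsort(w)[::-1][:m]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def _varimax(A: np.ndarray, max_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    p, m = A.shape
    if m < 2:
        return A.copy()
    R = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L**3 - (1.0 / p) * L @ np.diag((L**2).sum(axis=0)))
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return A @ R


def _quartimin_obj(L: np.ndarray) -> tuple[float, np.ndarray]:
    L2 = L**2
    N = np.ones((L.shape[1], L.shape[1])) - np.eye(L.shape[1])
    X = L2 @ N
    return float((L2 * X).sum()) / 4.0, L * X


def _oblimin(A: np.ndarray, max_iter: int = 500, tol: float = 1e-6) -> np.ndarray:
    """Oblique quartimin rotation by gradient projection."""
    p, m = A.shape
    if m < 2:
        return A.copy()
    T = np.eye(m)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_obj(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2
        for _ in range(60):
            Xm = T - al * Gp
            v = 1.0 / np.sqrt((Xm**2).sum(axis=0))
            Tt = Xm * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin_obj(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    return L


def fit_efa(
    Z: StandardizedMatrix | pd.DataFrame,
    n_factors: int,
    rotation: str = "oblimin",
    method: str = "paf",
) -> pd.DataFrame:
    """Item x factor loadings after extraction and rotation.

    method: "paf" (principal-axis) or "principal" (component extraction).
    rotation: "oblimin" (oblique quartimin), "varimax", or "none".
    Deterministic given the data; columns carry a sign convention (each
    column's loading sum is nonnegative).
    """
    df = Z.values if isinstance(Z, StandardizedMatrix) else Z
    if n_factors >= df.shape[1]:
        raise ValueError("n_factors must be < number of items")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    R = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix has undefined entries (constant items?)")
    extract = {"paf": _paf, "principal": _principal}[method]
    A = extract(R, n_factors)
    rotated = {"oblimin": _oblimin, "varimax": _varimax, "none": lambda x: x.copy()}[
        rotation
    ](A)
    signs = np.where(rotated.sum(axis=0) < 0, -1.0, 1.0)
    rotated = rotated * signs
    return pd.DataFrame(
        rotated, index=df.columns, columns=[f"factor_{j+1}" for j in range(n_factors)]
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_factors(
    Z: StandardizedMatrix | pd.DataFrame,
    models: list[FactorModel],
    renormalize: bool = True,
) -> pd.DataFrame:
    """Respondent x factor scores: signed-loading sums of standardized items.

    Scores are renormalized to unit sample sd over respondents (skipped for a
    degenerate zero-variance score, which is left at 0 with a warning).
    """
    df = Z.values if isinstance(Z, StandardizedMatrix) else Z
    out = {}
    for m in models:
        missing = [i for i in m.item_ids if i not in df.columns]
        if missing:
            raise KeyError(f"factor {m.name!r}: missing item {missing[0]!r}")
        loadings = pd.Series({i: l for i, l in m.items})
        s = (df[m.item_ids] * loadings).sum(axis=1, min_count=1)
        if renormalize:
            sd = s.std(ddof=1)
            if sd and np.isfinite(sd) and sd > 0:
                s = s / sd
            else:
                log.warning("factor %s has zero score variance", m.name)
        out[m.name] = s
    return pd.DataFrame(out, index=df.index)


def build_meta_factors(
    scores: pd.DataFrame, n_meta: int
) -> tuple[pd.DataFrame, list[FactorModel]]:
    """Combine correlated first-order factors into second-order meta-factors.

    Principal-component extraction (with varimax) on the factor-score
    correlation matrix; each meta-factor records the parent factors it draws
    on (|loading| >= 0.3) and the full weight vector.  Meta scores are
    unit-sd weighted sums of the base scores.
    """
    if n_meta >= scores.shape[1]:
        raise ValueError("n_meta must be < number of base factors")
    R = np.corrcoef(scores.to_numpy(dtype=float), rowvar=False)
    L = _varimax(_principal(R, n_meta))
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    base = list(scores.columns)
    models: list[FactorModel] = []
    meta_scores = {}
    for j in range(n_meta):
        name = f"meta_{j+1}"
        weights = [(base[i], float(L[i, j])) for i in range(len(base)) if L[i, j] != 0]
        parents = [base[i] for i in range(len(base)) if abs(L[i, j]) >= 0.3]
        models.append(FactorModel(name=name, items=weights, role="meta", parents=parents))
        s = scores.to_numpy() @ L[:, j]
        sd = s.std(ddof=1)
        meta_scores[name] = s / sd if sd > 0 else s
    return pd.DataFrame(meta_scores, index=scores.index), models


# ---------------------------------------------------------------------------
# reliability refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    model: FactorModel
    reached: bool
    history: list[tuple[str, str, float]] = field(default_factory=list)


def refine_to_reliable(
    model: FactorModel,
    candidate_items: list[str],
    Z: StandardizedMatrix | pd.DataFrame,
    alpha_min: float = 0.7,
    max_steps: int = 50,
) -> RefinementResult:
    """Greedy item drop/add search maximizing alpha.

    Stops at the first model reaching ``alpha_min``; otherwise returns the
    best model found with ``reached=False`` (never raises for an exhausted
    pool).  Added items are keyed by the sign of their correlation with the
    current factor score.
    """
    if not 0 < alpha_min < 1:
        raise ValueError("alpha_min must be in (0, 1)")
    df = Z.values if isinstance(Z, StandardizedMatrix) else Z
    current = replace(model, items=list(model.items))
    current.alpha = model_alpha(df, current)
    history: list[tuple[str, str, float]] = []
    if current.alpha >= alpha_min:
        return RefinementResult(replace(model, alpha=current.alpha), True, history)
    pool = [c for c in candidate_items if c in df.columns and c not in current.item_ids]
    for _ in range(max_steps):
        if current.alpha >= alpha_min:
            return RefinementResult(current, True, history)
        best: tuple[float, str, str, list] | None = None
        if len(current.items) > 2:
            for i, (item, _) in enumerate(current.items):
                trial = current.items[:i] + current.items[i + 1:]
                a = model_alpha(df, replace(current, items=trial))
                if np.isfinite(a) and (best is None or a > best[0]):
                    best = (a, "drop", item, trial)
        score = (df[current.item_ids] * [l for _, l in current.items]).sum(axis=1)
        for cand in pool:
            r = df[cand].corr(score)
            sign = -1.0 if (np.isfinite(r) and r < 0) else 1.0
            trial = current.items + [(cand, sign)]
            a = model_alpha(df, replace(current, items=trial))
            if np.isfinite(a) and (best is None or a > best[0]):
                best = (a, "add", cand, trial)
        if best is None or best[0] <= current.alpha + 1e-12:
            break
        a, op, item, trial = best
        current = replace(current, items=trial, alpha=a)
        history.append((op, item, a))
        if op == "add":
            pool.remove(item)
    reached = current.alpha >= alpha_min
    if not reached:
        log.warning(
            "factor %s refinement stopped at alpha=%.3f < %.2f",
            current.name, current.alpha, alpha_min,
        )
    return RefinementResult(current, reached, history)


# ---------------------------------------------------------------------------
# shipped defaults and alignment utilities
# ---------------------------------------------------------------------------

def default_factor_models() -> list[FactorModel]:
    """The ten shipped factor definitions of the default instrument.

    Item sets and signed loadings mirror the synthetic generator's default
    loading structure (22-item manageability, 35-item effectiveness, 14-item
    concern, 12-item well-being, 4-item self-care, 6-item sociability,
    5-item self-reliance, 6-item world-anxiety, 3-item guidance-trust,
    5-item health-anxiety).
    """
    from .synth import _default_item_spec  # local import avoids a cycle

    grouped: dict[str, list[tuple[str, float]]] = {}
    for item, factor, loading, _block in _default_item_spec():
        grouped.setdefault(factor, []).append((item, loading))
    return [FactorModel(name=f, items=items) for f, items in grouped.items()]


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    num = float(np.dot(a, b))
    den = float(np.sqrt(np.dot(a, a) * np.dot(b, b)))
    return num / den if den > 0 else float("nan")


def align_loadings(estimated: pd.DataFrame, true: pd.DataFrame) -> pd.DataFrame:
    """Permute/sign-flip estimated factor columns to best match true columns.

    Matching maximizes total |congruence| via the assignment problem; the
    returned frame has the true frame's column order and matched signs.
    """
    E = estimated.to_numpy()
    T = true.loc[estimated.index].to_numpy()
    C = np.zeros((T.shape[1], E.shape[1]))
    for i in range(T.shape[1]):
        for j in range(E.shape[1]):
            C[i, j] = tucker_congruence(T[:, i], E[:, j])
    rows, cols = linear_sum_assignment(-np.abs(C))
    out = np.zeros_like(T)
    for i, j in zip(rows, cols):
        out[:, i] = E[:, j] * np.sign(C[i, j])
    return pd.DataFrame(out, index=estimated.index, columns=true.columns)
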