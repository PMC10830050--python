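"""Hybrid segmentation engine.

The workflow combines k-means (with repeated-run stability assessment),
classical multidimensional scaling for the respondent map, a polar-coordinate
sectoring diagnostic, explicit handling of the "central" group of respondents
with no distinctive views, nearest-centroid refinement (one k-means
iteration), a bootstrap-derived threshold for deciding when a respondent has
genuinely changed segment between two builds, and QDA allocation of holdout
(booster) respondents to the fixed segmentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "SegmentModel",
    "SegmentationResult",
    "run_kmeans_stable",
    "embed_mds",
    "polar_sector_segments",
    "excise_central",
    "assign_nearest_centroid",
    "one_step_reassign",
    "bootstrap_move_threshold",
    "rebuild_match_rate",
    "qda_allocate",
    "segment_respondents",
]

log = logging.getLogger(__name__)

CENTRAL = "central"


@dataclass
class SegmentModel:
    """k centroids in factor space plus optional map/threshold metadata."""

    centroids: pd.DataFrame  # segments x factors
    central_segment_id: str | None = None
    mds_coords: pd.DataFrame | None = None
    move_threshold: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids.to_numpy(dtype=float))):
            raise ValueError("centroids must be finite")

    @property
    def names(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_dict(self) -> dict:
        return {
            "segments": self.names,
            "centroids": self.centroids.to_dict(orient="index"),
            "central_segment_id": self.central_segment_id,
            "move_threshold": self.move_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentModel":
        cent = pd.DataFrame.from_dict(d["centroids"], orient="index").loc[d["segments"]]
        return cls(
            centroids=cent,
            central_segment_id=d.get("central_segment_id"),
            move_threshold=d.get("move_threshold"),
        )


@dataclass
class SegmentationResult:
    model: SegmentModel
    assignments: pd.DataFrame  # label, source, moved, dist_<segment>...
    stability: float
    n_moved: int


# ---------------------------------------------------------------------------
# clustering and mapping
# ---------------------------------------------------------------------------

def run_kmeans_stable(
    F: pd.DataFrame,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    segment_names: list[str] | None = None,
) -> tuple[SegmentModel, float]:
    """Repeated k-means; keep the best-inertia run, report label stability.

    Stability is the mean pairwise adjusted Rand index over the ``n_runs``
    labelings (1.0 when every run lands on the same partition; by convention
    1.0 as well for k=1, where ARI of identical one-cluster labelings is 1).
    """
    if k > len(F):
        raise ValueError("k exceeds number of respondents")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = F.to_numpy(dtype=float)
    rng = np.random.SeedSequence(seed)
    runs = []
    for child in rng.spawn(n_runs):
        km = KMeans(n_clusters=k, n_init=1, random_state=np.random.default_rng(child).integers(2**31))
        labels = km.fit_predict(X)
        runs.append((km.inertia_, labels, km.cluster_centers_))
    aris = [
        adjusted_rand_score(runs[i][1], runs[j][1])
        for i in range(n_runs)
        for j in range(i + 1, n_runs)
    ]
    stability = float(np.mean(aris)) if aris else 1.0
    best = min(runs, key=lambda r: r[0])
    names = segment_names if segment_names is not None else [f"segment_{j+1}" for j in range(k)]
    if len(names) != k:
        raise ValueError("segment_names length must equal k")
    centroids = pd.DataFrame(best[2], index=names, columns=F.columns)
    model = SegmentModel(centroids=centroids)
    return model, stability


def embed_mds(data, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling to a 2-D map.

    Accepts either raw coordinates (respondents x features; the embedding is
    then the exact classical-scaling solution, computed as centered PCA,
    which coincides with Torgerson scaling of Euclidean distances) or a
    symmetric zero-diagonal distance matrix.  The output is centered at the
    origin and deterministic up to the fixed sign convention.
    """
    df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data, float))
    M = df.to_numpy(dtype=float)
    n = M.shape[0]
    is_dist = (
        M.shape[0] == M.shape[1]
        and np.allclose(np.diag(M), 0.0)
        and df.index.equals(df.columns)
    )
    if is_dist:
        if (M < 0).any() or not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric and nonnegative")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (M**2) @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:n_components]
        lam = np.clip(w[idx], 0.0, None)
        coords = V[:, idx] * np.sqrt(lam)
    else:
        C = M - M.mean(axis=0)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        coords = U[:, :n_components] * s[:n_components]
    # sign convention: the largest-magnitude entry of each axis is positive
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(coords, index=df.index, columns=[f"dim_{j+1}" for j in range(coords.shape[1])])


def polar_sector_segments(
    coords: pd.DataFrame, radius_cutoff: float, n_sectors: int = 36
) -> tuple[pd.Series, pd.Series]:
    """Polar-coordinate sectoring of a centered 2-D respondent map.

    Points with radius <= ``radius_cutoff`` are masked central; the rest get
    sector labels ``floor(theta / (360/n_sectors))`` with theta in [0, 360)
    (half-open: theta = 0 falls in sector 0).
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    xy = coords.to_numpy(dtype=float)[:, :2]
    r = np.hypot(xy[:, 0], xy[:, 1])
    theta = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
    sector = np.floor(theta / (360.0 / n_sectors)).astype(int)
    sector = np.minimum(sector, n_sectors - 1)  # guard the theta==360 edge
    central = r <= radius_cutoff
    sectors = pd.Series(sector, index=coords.index, name="sector")
    sectors[central] = -1
    return sectors, pd.Series(central, index=coords.index, name="central")


def excise_central(points: pd.DataFrame, target_fraction: float = 0.02) -> pd.Series:
    """Mark the ceil(fraction * n) smallest-radius respondents as central.

    Radius is the Euclidean norm of the row (factor scores or map
    coordinates, both centered representations); ties break by respondent id.
    """
    if not 0.0 <= target_fraction < 1.0:
        raise ValueError("target_fraction must be in [0, 1)")
    n = len(points)
    m = math.ceil(target_fraction * n)
    radius = pd.Series(
        np.linalg.norm(points.to_numpy(dtype=float), axis=1), index=points.index
    )
    order = sorted(points.index, key=lambda i: (radius[i], str(i)))
    mask = pd.Series(False, index=points.index, name="central")
    mask[order[:m]] = True
    return mask


# ---------------------------------------------------------------------------
# assignment and refinement
# ---------------------------------------------------------------------------

def _distances(F: pd.DataFrame, model: SegmentModel) -> np.ndarray:
    if list(F.columns) != list(model.centroids.columns):
        raise ValueError("factor dimensions do not match centroid dimensions")
    return cdist(F.to_numpy(dtype=float), model.centroids.to_numpy(dtype=float))


def assign_nearest_centroid(
    F: pd.DataFrame,
    model: SegmentModel,
    current_labels: pd.Series | None = None,
    source: str = "nearest",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Euclidean nearest-centroid assignment (ties to the lowest index).

    Returns the assignment frame (label, per-segment distances, moved flag)
    and, when current labels are given, the current-vs-nearest confusion
    matrix.
    """
    D = _distances(F, model)
    names = model.names
    labels = pd.Series([names[j] for j in D.argmin(axis=1)], index=F.index, name="label")
    out = pd.DataFrame({"label": labels, "source": source}, index=F.index)
    for j, name in enumerate(names):
        out[f"dist_{name}"] = D[:, j]
    confusion = None
    if current_labels is not None:
        current_labels = current_labels.loc[F.index]
        out["moved"] = (labels != current_labels).to_numpy()
        confusion = pd.crosstab(
            current_labels.rename("current"), labels.rename("nearest")
        ).reindex(index=names, columns=names, fill_value=0)
    else:
        out["moved"] = False
    return out, confusion


def one_step_reassign(
    F: pd.DataFrame, labels: pd.Series, model: SegmentModel
) -> tuple[pd.Series, SegmentModel, int]:
    """Move every respondent to its nearest centroid, then recompute centroids.

    Exactly one iteration of Lloyd's k-means from the given centroids.  A
    segment left empty keeps its previous centroid (with a warning).
    """
    assign, confusion = assign_nearest_centroid(F, model, current_labels=labels)
    new_labels = assign["label"]
    n_moved = int(confusion.to_numpy().sum() - np.trace(confusion.to_numpy()))
    centroids = model.centroids.copy()
    for name in model.names:
        members = F.loc[new_labels == name]
        if len(members):
            centroids.loc[name] = members.mean(axis=0)
        else:
            log.warning("segment %s empty after reassignment; centroid retained", name)
    new_model = SegmentModel(
        centroids=centroids,
        central_segment_id=model.central_segment_id,
        mds_coords=model.mds_coords,
        move_threshold=model.move_threshold,
    )
    return new_labels, new_model, n_moved


def bootstrap_move_threshold(
    F: pd.DataFrame,
    labels: pd.Series,
    model: SegmentModel,
    n_boot: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Bootstrap null threshold for a "real" segment move.

    Each bootstrap resample (respondents with replacement) perturbs the
    centroids; for every original respondent we record the apparent
    improvement d(x, own centroid*) - min_j d(x, centroid_j*) that sampling
    variability alone induces.  The returned threshold is the given quantile
    of that null distribution: label changes improving the distance by less
    than this are within resampling noise.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    labels = labels.loc[F.index]
    X = F.to_numpy(dtype=float)
    names = model.names
    lab_idx = np.array([names.index(l) for l in labels])
    rng = np.random.default_rng(seed)
    n = len(F)
    gaps = []
    base = model.centroids.to_numpy(dtype=float)
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        cent = base.copy()
        for j in range(len(names)):
            members = take[lab_idx[take] == j]
            if len(members):
                cent[j] = X[members].mean(axis=0)
        D = cdist(X, cent)
        gaps.append(D[np.arange(n), lab_idx] - D.min(axis=1))
    return float(np.quantile(np.concatenate(gaps), quantile))


def rebuild_match_rate(
    assign_a: pd.DataFrame, assign_b: pd.DataFrame, delta: float = 0.0
) -> float:
    """Fraction of respondents on which two segmentation builds agree.

    A respondent matches when the labels agree outright, or when they differ
    but switching from build a's label to build b's label improves the
    distance (in build b's geometry) by no more than ``delta`` — an
    edge-of-segment move within resampling noise, not a real disagreement.
    """
    if not assign_a.index.equals(assign_b.index):
        if set(assign_a.index) != set(assign_b.index):
            raise ValueError("assignment frames cover different respondents")
        assign_b = assign_b.loc[assign_a.index]
    la = assign_a["label"]
    lb = assign_b["label"]
    same = (la == lb).to_numpy()
    improvement = np.array(
        [
            assign_b.at[i, f"dist_{la[i]}"] - assign_b.at[i, f"dist_{lb[i]}"]
            for i in assign_a.index
        ]
    )
    matched = same | (improvement <= delta)
    return float(matched.mean())


# ---------------------------------------------------------------------------
# booster allocation
# ---------------------------------------------------------------------------

class _GaussianQda:
    """Per-class Gaussian classifier with class-specific covariances.

    Priors are empirical class frequencies.  A class covariance that is
    singular (or has fewer members than dimensions) is ridge-regularized with
    lambda * I; the ``regularized`` flag records whether that happened.
    """

    def __init__(self, reg_lambda: float = 1e-3):
        self.reg_lambda = reg_lambda

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GaussianQda":
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, self.precisions_, self.log_terms_ = [], [], []
        self.regularized = False
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            cov = (
                np.cov(Xc, rowvar=False).reshape(d, d)
                if len(Xc) > 1
                else np.zeros((d, d))
            )
            w = np.linalg.eigvalsh(cov)
            if len(Xc) <= d or w.min() < 1e-10 * max(w.max(), 1.0):
                cov = cov + self.reg_lambda * np.eye(d)
                self.regularized = True
            sign, logdet = np.linalg.slogdet(cov)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(cov))
            self.log_terms_.append(np.log(len(Xc) / len(X)) - 0.5 * logdet)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((len(X), len(self.classes_)))
        for j, (mu, P, lt) in enumerate(
            zip(self.means_, self.precisions_, self.log_terms_)
        ):
            diff = X - mu
            scores[:, j] = lt - 0.5 * np.einsum("ij,jk,ik->i", diff, P, diff)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.decision(X).argmax(axis=1)]


def qda_allocate(
    F_core: pd.DataFrame,
    labels_core: pd.Series,
    F_new: pd.DataFrame,
    reg_lambda: float = 1e-3,
) -> tuple[pd.Series, float, dict]:
    """Allocate holdout respondents to segments by QDA trained on the core.

    Per-class Gaussians with their own covariances and empirical priors.
    Singular or near-singular class covariances (tiny classes, collinear
    factors) trigger a ridge-regularized refit with a warning.  The report
    carries training accuracy, the training confusion matrix, and the share
    of misallocated core respondents whose predicted segment is "adjacent"
    (the respondent's own next-nearest segment by centroid distance).
    """
    labels_core = labels_core.loc[F_core.index]
    X0 = F_core.to_numpy(dtype=float)
    y0 = labels_core.to_numpy()
    qda = _GaussianQda(reg_lambda=reg_lambda).fit(X0, y0)
    if qda.regularized:
        log.warning("QDA class covariance regularized with lambda=%g", reg_lambda)

    train_pred = pd.Series(qda.predict(X0), index=F_core.index)
    accuracy = float((train_pred == labels_core).mean())
    confusion = pd.crosstab(labels_core.rename("true"), train_pred.rename("pred"))

    # adjacency of misallocations: is the wrong prediction the respondent's
    # second-nearest segment centroid?
    names = [str(c) for c in qda.classes_]
    centroids = np.vstack([X0[y0 == c].mean(axis=0) for c in qda.classes_])
    D = cdist(X0, centroids)
    order = np.argsort(D, axis=1)
    mis = (train_pred != labels_core).to_numpy()
    adjacent = 0
    for i in np.where(mis)[0]:
        ranked = [names[j] for j in order[i]]
        ranked.remove(str(labels_core.iloc[i]))
        if str(train_pred.iloc[i]) == ranked[0]:
            adjacent += 1
    report = {
        "training_accuracy": accuracy,
        "confusion": confusion,
        "misallocated": int(mis.sum()),
        "adjacent_fraction": adjacent / mis.sum() if mis.any() else float("nan"),
        "regularized": bool(qda.regularized),
    }
    labels_new = pd.Series(qda.predict(F_new.to_numpy(dtype=float)), index=F_new.index, name="label")
    return labels_new, accuracy, report


# ---------------------------------------------------------------------------
# default orchestrated path
# ---------------------------------------------------------------------------

def segment_respondents(
    F: pd.DataFrame,
    k: int = 7,
    central_fraction: float = 0.02,
    n_runs: int = 20,
    seed: int = 0,
    seed_segments: dict[str, list] | None = None,
    segment_names: list[str] | None = None,
    bootstrap: bool = False,
    n_boot: int = 200,
) -> SegmentationResult:
    """Default segmentation path on a factor-score matrix.

    1. map respondents by classical MDS and mark the most central
       ``central_fraction`` (no strong views) for exclusion;
    2. stable k-means with ``k`` clusters on the remaining respondents
       (optionally after carving out config-designated seed-respondent
       segments, the mechanism for reinstating a judgment-defined segment);
    3. reinstate the central group as its own segment;
    4. one nearest-centroid refinement pass over everyone.
    """
    coords = embed_mds(F)
    central_mask = excise_central(coords, central_fraction)
    seed_segments = seed_segments or {}
    seeded_ids: set = set()
    for ids in seed_segments.values():
        seeded_ids |= set(ids)
    core_ids = [i for i in F.index if not central_mask[i] and i not in seeded_ids]
    model_core, stability = run_kmeans_stable(
        F.loc[core_ids], k, n_runs=n_runs, seed=seed, segment_names=segment_names
    )

    centroids = model_core.centroids.copy()
    init_labels, _ = assign_nearest_centroid(F.loc[core_ids], model_core)
    labels = pd.Series(index=F.index, dtype=object)
    labels.loc[core_ids] = init_labels["label"]
    for name, ids in seed_segments.items():
        ids = [i for i in ids if i in F.index]
        centroids.loc[name] = F.loc[ids].mean(axis=0)
        labels.loc[ids] = name
    central_id = None
    if central_mask.any():
        central_id = CENTRAL
        centroids.loc[CENTRAL] = F.loc[central_mask].mean(axis=0)
        labels.loc[central_mask[central_mask].index] = CENTRAL

    model = SegmentModel(
        centroids=centroids, central_segment_id=central_id, mds_coords=coords
    )
    final_labels, model, n_moved = one_step_reassign(F, labels, model)
    if bootstrap:
        model.move_threshold = bootstrap_move_threshold(
            F, final_labels, model, n_boot=n_boot, seed=seed
        )
    assignments, _ = assign_nearest_centroid(F, model, current_labels=labels)
    log.info(
        "segmentation: k=%d (+%d seeded, central=%s) stability=%.3f moved=%d",
        k, len(seed_segments), central_id is not None, stability, n_moved,
    )
    return SegmentationResult(
        model=model, assignments=assignments, stability=stability, n_moved=n_moved
    )
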