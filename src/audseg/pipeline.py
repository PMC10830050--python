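"""End-to-end pipeline: simulate -> qc -> standardize -> factors -> segment
-> profile -> validate, with file I/O and a reproducibility manifest.

Every stage reads and writes plain delimited text (CSV with a header row) or
JSON, records its parameters and seed in the run manifest, and can be
skipped when its input files are supplied externally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import BlockSpec, ResponseMatrix
from .factors import default_factor_models, model_alpha, score_factors
from .profile import build_profile_table, render_profile_table
from .qc import QCRules, run_qc
from .segment import qda_allocate, segment_respondents
from .standardize import standardize
from .synth import SynthConfig, generate_population
from .validate import (
    PROTECTIVE_BEHAVIOURS,
    fit_logistic_wald,
    fit_type3_anova,
    joint_term_ss,
    predictor_comparison_report,
    protective_score,
)

__all__ = ["run_pipeline", "read_responses", "write_responses", "default_pipeline_config"]

log = logging.getLogger(__name__)


def default_pipeline_config(seed: int = 0, n_respondents: int = 5507) -> dict:
    """The default declarative configuration (one dict, one auditable place)."""
    return {
        "seed": seed,
        "synth": {"n_respondents": n_respondents},
        "qc": {"var_eps": 0.0, "min_invariant_blocks": 3},
        "standardize": {"respondent_level": True},
        "factors": {"alpha_min": 0.7},
        "segment": {
            "k": 7,
            "central_fraction": 0.02,
            "n_runs": 20,
            "bootstrap": False,
            "qda_booster": True,
        },
        "profile": {"alpha": 0.05},
        "validate": {
            "categorical": ["segment", "gender", "ethnicity"],
            "numeric": ["education", "income", "age"],
        },
    }


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_responses(X: ResponseMatrix, path, meta_path=None) -> None:
    """Write a ResponseMatrix as responses.csv plus a JSON sidecar.

    The sidecar records the block map, Likert range and which columns are
    demographics/outcomes, so a read round-trips exactly.
    """
    path = Path(path)
    parts = [X.responses]
    meta = {
        "likert_levels": X.likert_levels,
        "blocks": X.blocks.to_dict(),
        "demographics": [],
        "outcomes": [],
    }
    if X.demographics is not None:
        parts.append(X.demographics)
        meta["demographics"] = list(X.demographics.columns)
    if X.outcomes is not None:
        parts.append(X.outcomes)
        meta["outcomes"] = list(X.outcomes.columns)
    if X.sample_source is not None:
        parts.append(X.sample_source.rename("sample_source"))
    if X.weights is not None:
        parts.append(X.weights.rename("weight"))
    pd.concat(parts, axis=1).to_csv(path, index_label="respondent_id")
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2))


def read_responses(path, meta_path=None) -> ResponseMatrix:
    """Read responses.csv (+ sidecar) back into a ResponseMatrix.

    Likert cells must be integers or empty (missing); non-integer cells and
    duplicate respondent ids are errors naming the offender.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text())
    blocks = BlockSpec.from_dict(meta["blocks"])
    df = pd.read_csv(path, index_col="respondent_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate respondent ids: {list(dupes[:5])}")
    items = [c for c in df.columns if c in blocks.item_block]
    resp = df[items]
    for col in items:
        vals = resp[col].dropna()
        if not np.allclose(vals, np.round(vals)):
            bad = vals.index[~np.isclose(vals, np.round(vals))][0]
            raise ValueError(f"non-integer Likert value at row {bad!r}, column {col!r}")
    demo = df[meta["demographics"]] if meta["demographics"] else None
    outc = df[meta["outcomes"]] if meta["outcomes"] else None
    return ResponseMatrix(
        responses=resp.astype(float),
        blocks=blocks,
        likert_levels=meta["likert_levels"],
        demographics=demo,
        outcomes=outc,
        sample_source=df["sample_source"] if "sample_source" in df else None,
        weights=df["weight"] if "weight" in df else None,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir, truth: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline per the declarative config; return manifest.

    When ``config["input"]["responses"]`` is given the simulate stage is
    skipped and data are read from file; otherwise a synthetic population is
    generated (and its truth table written, enabling recovery metrics in the
    manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {**default_pipeline_config(), **config}
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "software_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": [],
    }

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": {k: v for k, v in params.items()},
                "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
                "timestamp": time.time(),
            }
        )

    # --- simulate / load -------------------------------------------------
    if cfg.get("input", {}).get("responses"):
        X = read_responses(cfg["input"]["responses"], cfg["input"].get("meta"))
        record("load", {"path": str(cfg["input"]["responses"])}, [])
    else:
        synth_cfg = SynthConfig(seed=seed, **cfg.get("synth", {}))
        X, truth = generate_population(synth_cfg)
        rpath = outdir / "responses.csv"
        write_responses(X, rpath)
        truth.to_csv(outdir / "truth.csv")
        record(
            "simulate",
            {"n_respondents": synth_cfg.n_respondents, "seed": seed},
            [rpath, outdir / "truth.csv"],
        )

    # --- qc ---------------------------------------------------------------
    rules = QCRules(**cfg.get("qc", {}))
    X, flags, report = run_qc(X, rules)
    (outdir / "qc_report.json").write_text(json.dumps(report, indent=2))
    record("qc", vars(rules) | {"removed": report["removed"]}, [outdir / "qc_report.json"])

    # --- standardize ------------------------------------------------------
    Z = standardize(X, **cfg.get("standardize", {}))
    record("standardize", cfg.get("standardize", {}), [])

    # --- factors ----------------------------------------------------------
    models = default_factor_models()
    alphas = {m.name: float(model_alpha(Z, m)) for m in models}
    for m in models:
        m.alpha = alphas[m.name]
    F = score_factors(Z, models)
    fpath = outdir / "factor_scores.csv"
    F.to_csv(fpath, index_label="respondent_id")
    (outdir / "factor_models.json").write_text(
        json.dumps([m.to_dict() for m in models], indent=2)
    )
    record("factors", {"alphas": alphas}, [fpath, outdir / "factor_models.json"])

    # --- segment ----------------------------------------------------------
    seg_cfg = dict(cfg.get("segment", {}))
    use_qda = seg_cfg.pop("qda_booster", False)
    core_mask = (
        X.sample_source != "booster"
        if (use_qda and X.sample_source is not None)
        else pd.Series(True, index=X.ids)
    )
    F_core = F.loc[core_mask]
    result = segment_respondents(F_core, seed=seed, **seg_cfg)
    assignments = result.assignments
    qda_report = None
    if use_qda and (~core_mask).any():
        new_labels, acc, qda_report = qda_allocate(
            F_core, assignments["label"], F.loc[~core_mask]
        )
        booster = pd.DataFrame({"label": new_labels, "source": "qda", "moved": False})
        assignments = pd.concat([assignments, booster]).loc[F.index]
    apath = outdir / "assignments.csv"
    assignments.to_csv(apath, index_label="respondent_id")
    (outdir / "segment_model.json").write_text(json.dumps(result.model.to_dict(), indent=2))
    seg_params = {
        "stability": result.stability,
        "n_moved": result.n_moved,
        "seed": seed,
        **seg_cfg,
    }
    if qda_report is not None:
        seg_params["qda_training_accuracy"] = qda_report["training_accuracy"]
    record("segment", seg_params, [apath, outdir / "segment_model.json"])

    # --- profile ----------------------------------------------------------
    variables = pd.concat(
        [d for d in (X.demographics, X.outcomes) if d is not None], axis=1
    )
    table = build_profile_table(
        assignments["label"],
        variables,
        weights=X.weights,
        alpha=cfg.get("profile", {}).get("alpha", 0.05),
        segment_order=result.model.names,
    )
    table.stats.to_csv(outdir / "profile_stats.csv")
    table.letters.to_csv(outdir / "profile_letters.csv")
    (outdir / "profile.txt").write_text(render_profile_table(table))
    record("profile", cfg.get("profile", {}), [outdir / "profile_stats.csv"])

    # --- validate ---------------------------------------------------------
    val_report = None
    if X.outcomes is not None and set(PROTECTIVE_BEHAVIOURS) <= set(X.outcomes.columns):
        y = protective_score(X.outcomes[list(PROTECTIVE_BEHAVIOURS)])
        vcfg = cfg.get("validate", {})
        data = X.demographics.copy()
        data["segment"] = assignments["label"]
        glm = fit_type3_anova(y, data, vcfg["categorical"], vcfg["numeric"])
        glm.table.to_csv(outdir / "glm_table.csv")
        wald = None
        if "vax_refusal" in X.outcomes.columns:
            wald = fit_logistic_wald(
                X.outcomes["vax_refusal"], data, vcfg["categorical"], vcfg["numeric"]
            )
            wald.to_csv(outdir / "wald.csv")
        if wald is not None:
            demo_c = [c for c in vcfg["categorical"] if c != "segment"]
            joint_ss, _ = joint_term_ss(
                y, data, vcfg["categorical"], vcfg["numeric"], demo_c, vcfg["numeric"]
            )
            val_report = predictor_comparison_report(
                glm, wald, segment_term="segment", joint_demographics_ss=joint_ss
            )
            (outdir / "predictor_comparison.json").write_text(
                json.dumps(val_report, indent=2, default=float)
            )
        record(
            "validate",
            {"r_squared": glm.r_squared, "adj_r_squared": glm.adj_r_squared},
            [outdir / "glm_table.csv"],
        )

    # --- recovery metrics against ground truth ---------------------------
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        common = assignments.index.intersection(truth.index)
        ari = adjusted_rand_score(
            truth.loc[common, "true_segment"], assignments.loc[common, "label"]
        )
        manifest["recovery"] = {"ari_vs_truth": float(ari), "n_compared": int(len(common))}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
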