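"""End-to-end demonstration pipeline: simulate -> normalize -> screen -> diagnose.

The pipeline stitches the stages together on synthetic data the way a cohort
analysis would run on real feature tables:

1. a repeatability study is simulated and its per-feature variance
   components / ICCs estimated on the log2 scale (the error structures);
2. a case-control cohort is simulated with disease driven by the true
   feature levels, the observed table is sLMNLT-normalized, and every
   feature is screened by naive logistic regression with RCAL and SIMEX
   corrections plus Benjamini-Hochberg adjustment;
3. cutoff diagnostics are computed for the standard urological markers
   (f/tPSA, lower indicates disease; PCA3 score, higher indicates disease).

Every random stage carries an explicit seed derived from the config seed,
and a manifest records versions, seeds and stage parameters, so reruns are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import assign_groups, univariate_screen
from .diagnostics import metrics_at_cutoff, roc_auc
from .preprocessing import LodModel, slmnlt
from .synthetic_data import (
    CaseControlDesign,
    RepeatabilityDesign,
    generate_case_control_study,
    generate_repeatability_study,
)
from .io import write_feature_table
from .variability import feature_table_icc, summarize_features

__all__ = ["default_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def default_config(seed: int = 0, outdir: str = "peptivar_demo") -> dict:
    """A complete demo configuration; every field may be overridden."""
    return {
        "seed": seed,
        "outdir": outdir,
        "n_features": 12,
        "repeatability": {
            "n_subjects": 20,
            "spots_per_sample": 5,
            "sigma_b2": 0.170,
            "sigma_w2": 0.184,
        },
        "cohort": {
            "n_cases": 70,
            "n_controls": 76,
            "n_aah": 2,
            "mu": 0.0,
            "sigma_b2": 1.0,
            "sigma_w2": 0.5,
            "beta_scale": 0.8,
            "n_active": 3,
            "lod_fraction": 0.05,
        },
        "slod_strategy": "lod_half",
        "simex": {"B": 50, "lambdas": [0.5, 1.0, 1.5, 2.0]},
        "diagnostics": [
            {"score": "ft_psa", "cutoff": 10.0, "direction": "less"},
            {"score": "pca3_score", "cutoff": 35.0, "direction": "greater"},
        ],
    }


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: dict) -> dict:
    """Run the full demo pipeline; returns the artifact paths written.

    See :func:`default_config` for the schema.  A failed stage raises
    :class:`PipelineError` naming the stage.
    """
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    p = int(cfg["n_features"])
    artifacts = {}

    # -- stage 1: repeatability study -> error structures -------------------
    @_stage("variability")
    def stage_variability():
        rep_cfg = cfg["repeatability"]
        design = RepeatabilityDesign(
            n_subjects=rep_cfg["n_subjects"],
            samples_per_subject=tuple([2] * (rep_cfg["n_subjects"] - 4) + [3] * 4),
            spots_per_sample=rep_cfg["spots_per_sample"],
            n_features=p,
            sigma_b2=rep_cfg["sigma_b2"],
            sigma_w2=rep_cfg["sigma_w2"],
            seed=seed,
        )
        rep_table = generate_repeatability_study(design)
        lod = LodModel(slod=float(np.quantile(rep_table.values, 0.02)),
                       strategy=cfg["slod_strategy"])
        rep_log2 = slmnlt(rep_table, lod)
        icc_frame = feature_table_icc(rep_log2)
        icc_frame.to_csv(outdir / "icc.csv", index=False)
        write_feature_table(rep_table, outdir / "repeatability.csv",
                            dialect="long", seed=seed)
        return icc_frame

    icc_frame = stage_variability()
    artifacts["icc"] = str(outdir / "icc.csv")

    # -- stage 2: cohort simulation + sLMNLT + screen -----------------------
    @_stage("associate")
    def stage_associate():
        co = cfg["cohort"]
        beta = np.zeros(p)
        beta[: int(co["n_active"])] = co["beta_scale"]
        design = CaseControlDesign(
            n_cases=co["n_cases"], n_controls=co["n_controls"], n_features=p,
            mu=co["mu"], sigma_b2=co["sigma_b2"], sigma_w2=co["sigma_w2"],
            beta_true=beta, lod_fraction=co["lod_fraction"],
            n_aah=co["n_aah"], seed=seed + 1,
        )
        table, pheno = generate_case_control_study(design)
        write_feature_table(table, outdir / "features.csv", dialect="long",
                            seed=seed + 1)
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        slod = table.meta.attrs.get("slod", 0.0) or float(
            np.quantile(table.values, 0.02))
        lod = LodModel(slod=slod, strategy=cfg["slod_strategy"])
        log2_table = slmnlt(table, lod)
        groups = assign_groups(pheno["histology"], scheme="two-group")
        keep = ~groups.excluded
        screen = univariate_screen(
            type(log2_table)(
                log2_table.values[keep], log2_table.mz,
                log2_table.meta.loc[keep],
                log2_table.below_lod[keep], log2_table.state,
            ),
            groups.outcome[keep],
            icc_per_feature=icc_frame["icc"].to_numpy(),
            sigma_w2_per_feature=icc_frame["sigma_w2"].to_numpy(),
            simex_kwargs={**cfg["simex"], "seed": seed + 2},
        )
        screen.to_csv(outdir / "screen.csv", index=False)
        return pheno, screen

    pheno, screen = stage_associate()
    artifacts["features"] = str(outdir / "features.csv")
    artifacts["phenotypes"] = str(outdir / "phenotypes.csv")
    artifacts["screen"] = str(outdir / "screen.csv")

    # -- stage 3: marker diagnostics ----------------------------------------
    @_stage("diagnose")
    def stage_diagnose():
        rows = []
        y = pheno.loc[pheno["histology"] != "AAH", "outcome"].to_numpy()
        sub = pheno[pheno["histology"] != "AAH"]
        for spec_d in cfg["diagnostics"]:
            scores = sub[spec_d["score"]].to_numpy()
            auc, auc_ci = roc_auc(scores, y, direction=spec_d["direction"])
            m = metrics_at_cutoff(scores, y, spec_d["cutoff"], spec_d["direction"])
            rows.append({
                "score": spec_d["score"], "cutoff": spec_d["cutoff"],
                "direction": spec_d["direction"], "auc": auc,
                "auc_lo": auc_ci[0], "auc_hi": auc_ci[1],
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "lr_pos": m.lr_pos, "lr_neg": m.lr_neg,
            })
        frame = pd.DataFrame(rows)
        frame.to_csv(outdir / "diagnostics.csv", index=False)
        return frame

    stage_diagnose()
    artifacts["diagnostics"] = str(outdir / "diagnostics.csv")

    manifest = {
        "package": "peptivar",
        "version": __version__,
        "seed": seed,
        "stage_seeds": {"variability": seed, "cohort": seed + 1, "simex": seed + 2},
        "config": cfg,
        "icc_summary": summarize_features(icc_frame["icc"].to_numpy()),
        "n_screened": int(len(screen)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
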