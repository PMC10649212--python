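"""End-to-end orchestration: generate -> exposure -> association -> farm factors -> ML.

A run is described by a :class:`RunConfig` (loadable from YAML).  Every stage
reads and writes plain CSV so stages can also be run and tested in
isolation; ``run_all`` chains them and writes a JSON manifest with row
counts, the seed, and a checksum per artifact.  Reruns under the same config
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import assoc, farm_factors, ml, synthetic
from .exposure import flock_exposure
from .schedule import build_schedule

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger("broilerenv")


@dataclass
class RunConfig:
    outdir: str = "runs/demo"
    seed: int = 0
    n_flocks: int = 80
    n_farms: int = 29
    schedule_anchors: tuple = ((0, 30.0), (27, 21.0))
    qc_completeness_min: float = 0.995
    qc_t_physical: tuple = (-5.0, 45.0)
    alpha: float = 0.05
    k_range: tuple = (2, 3, 4)
    rf_trees: int = 200
    ann_nodes_grid: tuple = (1, 3)
    cv_folds: int = 5
    generator_overrides: dict = field(default_factory=dict)

    def generator_config(self) -> synthetic.GeneratorConfig:
        cfg = synthetic.GeneratorConfig(
            n_farms=self.n_farms, n_flocks=self.n_flocks, seed=self.seed,
            schedule_anchors=tuple(tuple(a) for a in self.schedule_anchors),
        )
        for key, value in self.generator_overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown generator option {key!r}")
            setattr(cfg, key, value)
        cfg.validate()
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _write(frame: pd.DataFrame, outdir: str, name: str, manifest: dict) -> str:
    path = os.path.join(outdir, f"{name}.csv")
    frame.to_csv(path, index=False)
    digest = hashlib.sha256(open(path, "rb").read()).hexdigest()
    manifest["artifacts"][name] = {"path": path, "rows": len(frame), "sha256": digest}
    return path


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {"seed": config.seed, "config": asdict(config), "artifacts": {}}

    gen_cfg = config.generator_config()
    dataset = synthetic.generate(gen_cfg)
    log.info("generated %d flocks on %d farms (%d env rows)",
             len(dataset.flocks), len(dataset.farms), len(dataset.env))
    for name in ("env", "flocks", "farms", "performance", "truth", "fault_manifest"):
        _write(getattr(dataset, name), config.outdir, name, manifest)

    schedule = build_schedule(tuple(tuple(a) for a in config.schedule_anchors))
    schedule.frame.reset_index().pipe(_write, config.outdir, "schedule", manifest)

    exposure, qc = flock_exposure(
        dataset.env, dataset.flocks, schedule,
        completeness_min=config.qc_completeness_min,
        t_physical=tuple(config.qc_t_physical),
    )
    log.info("QC kept %d/%d flocks", int(qc["keep"].sum()), len(qc))
    _write(exposure, config.outdir, "exposure", manifest)
    _write(qc, config.outdir, "qc_report", manifest)

    table = assoc.association_table(exposure, dataset.performance, alpha=config.alpha)
    _write(table, config.outdir, "association", manifest)

    perf35 = dataset.performance[dataset.performance["age_day"] == 35]
    flocks35 = (dataset.flocks.drop(columns=["region"])
                .merge(perf35, on="flock_id")
                .merge(dataset.farms, on="farm_id"))
    factors = {
        "altitude": "continuous", "litter_reuse_cycles": "continuous",
        "downtime_d": "continuous", "distance_km": "continuous",
        "distance_h": "continuous", "region": "categorical",
        "technification": "categorical", "hatchery": "categorical",
        "litter_type": "categorical",
    }
    clusters, anova = farm_factors.factor_analysis(
        flocks35, factors, k_range=tuple(config.k_range),
        seed=config.seed, alpha=config.alpha)
    _write(clusters, config.outdir, "clusters", manifest)
    _write(anova, config.outdir, "anova", manifest)

    ml_report, importances = _ml_stage(dataset, config)
    _write(ml_report, config.outdir, "ml_cv", manifest)
    _write(importances, config.outdir, "importance", manifest)

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _ml_feature_table(dataset: synthetic.SyntheticDataset, response_age: int = 35):
    """Wide per-flock table: <=21-d performance + sex + farm attributes."""
    perf = dataset.performance
    early = perf[perf["age_day"] <= 21].pivot(
        index="flock_id", columns="age_day",
        values=["bw", "bw_gain", "fcr", "week_mortality"])
    early.columns = [f"{v}_{a}d" for v, a in early.columns]
    late = perf[perf["age_day"] == response_age].set_index("flock_id")[["bw", "fcr"]]
    late.columns = [f"{c}_{response_age}d" for c in late.columns]
    farm_cols = ["farm_id", "region", "technification", "hatchery", "litter_type",
                 "altitude", "litter_reuse_cycles", "distance_km", "downtime_d",
                 "pct_open_sided", "pct_retrofitted", "pct_concrete_floor"]
    table = (dataset.flocks[["flock_id", "farm_id", "sex"]]
             .merge(dataset.farms[farm_cols], on="farm_id")
             .drop(columns=["farm_id"])
             .set_index("flock_id")
             .join(early).join(late))
    return table.reset_index(drop=True)


def _ml_stage(dataset: synthetic.SyntheticDataset, config: RunConfig):
    table = _ml_feature_table(dataset)
    report_rows = []
    importance_frames = []
    for response in ("bw_35d", "fcr_35d"):
        other = "fcr_35d" if response == "bw_35d" else "bw_35d"
        raw = table.drop(columns=[other]).dropna()
        mm = ml.encode_and_scale(raw, response)

        mlr_cv = ml.cross_validate_mlr(raw, response, k=config.cv_folds,
                                       seed=config.seed)
        mlr = ml.fit_mlr_selected(mm.X, mm.y)
        imp = ml.mlr_contribution(mlr, mm.X, mm.y)
        importance_frames.append(imp.table.assign(method=imp.method, response=response))
        report_rows.append({"response": response, "model": "mlr",
                            "mean_r2": mlr_cv.mean_r2, "mean_rmse": mlr_cv.mean_rmse})

        rf = ml.fit_rf(mm.X, mm.y, n_trees=config.rf_trees, k=config.cv_folds,
                       seed=config.seed)
        imp = ml.permutation_importance(rf, mm.X, mm.y, seed=config.seed)
        importance_frames.append(imp.table.assign(method=imp.method, response=response))
        report_rows.append({"response": response, "model": "rf",
                            "mean_r2": rf.cv.mean_r2, "mean_rmse": rf.cv.mean_rmse})

        ann = ml.fit_ann(mm.X, mm.y, nodes_grid=tuple(config.ann_nodes_grid),
                         k=config.cv_folds, seed=config.seed)
        imp = ml.olden_importance(ann, feature_names=mm.columns)
        importance_frames.append(imp.table.assign(method=imp.method, response=response))
        report_rows.append({"response": response, "model": "ann",
                            "mean_r2": ann.cv.mean_r2, "mean_rmse": ann.cv.mean_rmse})
    return pd.DataFrame(report_rows), pd.concat(importance_frames, ignore_index=True)
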