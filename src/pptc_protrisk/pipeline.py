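"""End-to-end pipeline orchestration.

A single :class:`PipelineConfig` drives the full chain

    simulate -> preprocess -> deps -> clin-cox -> train -> stratify

with one master seed from which every stage's RNG seed is derived by
hashing, so a run is reproduced exactly by its config.  Each stage writes
its tables under the run directory; a manifest records the config hash, the
derived seeds and a SHA-256 checksum of every output file (no timestamps,
so reruns are byte-comparable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import io as pio
from .containers import CLINICAL_FEATURES
from .preprocess import (
    IMPUTERS,
    correct_batch,
    filter_by_missingness,
    merge_replicates,
    qc_report,
    replace_nonpositive,
)
from .differential import call_deps
from .clinical import compare_age_codings, univariate_screen, descriptive_stats
from .models import build_model, evaluate_cindex, split_train_test
from .stratification import (
    compute_crank,
    compute_threshold,
    evaluate_stratification,
    predict_survival_curve,
    stratify,
)
from .synthetic import SimConfig, config_to_dict, generate_cohort

_SIM_FIELDS = {f.name for f in dc_fields(SimConfig)}


class StabilityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_repeats: int = 100
    top_k: int = 50
    min_count: int = 50
    importance_repeats: int = 5


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    seed: int = 0
    sim: dict = {"n_proteins": 2000, "n_pm": 200, "n_pb": 150, "n_am": 0,
                 "n_batches": 10, "n_replicate_pairs": 6}
    na_threshold: float = 0.85
    imputer: str = "sequential"
    combat_covariates: list | None = None
    fc_model: float = 1.2
    fc_enrich: float = 1.5
    alpha: float = 0.05
    dep_mode: str = "leak_free"          # or "full_cohort"
    split_ratio: float = 0.6
    stratify_split: bool = True
    model: str = "ProtRsf"
    hyper_grid: dict = {
        "n_estimators": [150, 300],
        "max_features": ["sqrt"],
        "min_samples_leaf": [6, 15],
    }
    stability: StabilityConfig = StabilityConfig()
    max_pool: int = 1548
    crank_horizon: float | None = None

    @field_validator("sim")
    @classmethod
    def _check_sim(cls, v):
        unknown = set(v) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
        return v

    @field_validator("imputer")
    @classmethod
    def _check_imputer(cls, v):
        if v not in IMPUTERS:
            raise ValueError(f"imputer must be one of {sorted(IMPUTERS)}")
        return v

    @field_validator("dep_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("leak_free", "full_cohort"):
            raise ValueError("dep_mode must be leak_free or full_cohort")
        return v


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) from the master seed by hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage in order and return the manifest dictionary.

    Any stage failure propagates with the stage name prefixed; outputs of
    completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "seeds": {},
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, path: Path):
        written.append(path)
        manifest["outputs"][str(path.relative_to(out))] = _checksum(path)

    stage = "simulate"
    try:
        seed = stage_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        sim_cfg = SimConfig(**{**config.sim, "seed": seed})
        matrix, clinical, truth = generate_cohort(sim_cfg)
        pio.write_matrix(matrix, out / "matrix.tsv", out / "samples.tsv")
        pio.write_clinical(clinical, out / "clinical.csv")
        pio.write_truth(truth, out / "truth.json")
        for f in ("matrix.tsv", "samples.tsv", "clinical.csv", "truth.json"):
            emit(stage, out / f)
        manifest["stages"][stage] = {
            "n_proteins": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "event_fraction": truth.achieved_event_fraction,
            "sim_config": config_to_dict(sim_cfg),
        }

        stage = "preprocess"
        qc = qc_report(matrix)
        pio.write_json(qc.to_dict(), out / "qc.json")
        emit(stage, out / "qc.json")
        m = filter_by_missingness(matrix, config.na_threshold)
        m.require_history("filter")
        m = IMPUTERS[config.imputer](m)
        m.require_history("impute")
        m = correct_batch(m, covariates=config.combat_covariates)
        m.require_history("combat")
        m = replace_nonpositive(m.to_linear())
        m.require_history("replace_nonpositive")
        m = merge_replicates(m)
        m.require_history("merge")
        processed = m.to_log2()
        pio.write_matrix(processed, out / "matrix_processed.tsv", out / "samples_processed.tsv")
        emit(stage, out / "matrix_processed.tsv")
        emit(stage, out / "samples_processed.tsv")
        manifest["stages"][stage] = {
            "n_proteins": int(processed.values.shape[0]),
            "n_samples": int(processed.values.shape[1]),
            "history": processed.history,
            "median_pooled_cv": qc.median_pooled_cv,
        }

        stage = "split"
        seed = stage_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        split = split_train_test(clinical, config.split_ratio, seed,
                                 config.stratify_split)
        pio.write_json({"train": split.train_ids, "test": split.test_ids},
                       out / "split.json")
        emit(stage, out / "split.json")

        stage = "deps"
        subsets = None
        if config.dep_mode == "leak_free":
            subsets = {"PM": [s for s in split.train_ids
                              if s in processed.values.columns]}
        dep_model = call_deps(processed, "PM", "PB", config.fc_model,
                              config.alpha, sample_subsets=subsets)
        dep_enrich = call_deps(processed, "PM", "PB", config.fc_enrich,
                               config.alpha, sample_subsets=subsets)
        dep_model.to_csv(out / "deps_fc1.2.csv")
        dep_enrich.to_csv(out / "deps_fc1.5.csv")
        emit(stage, out / "deps_fc1.2.csv")
        emit(stage, out / "deps_fc1.5.csv")
        manifest["stages"][stage] = {
            "mode": config.dep_mode,
            "n_dep_model": int((dep_model["call"] != "ns").sum()),
            "n_dep_enrich": int((dep_enrich["call"] != "ns").sum()),
        }

        stage = "clin_cox"
        screen = univariate_screen(clinical)
        age_cmp = compare_age_codings(clinical)
        pio.write_json(
            {
                "descriptives": descriptive_stats(clinical),
                "univariate": screen.reset_index().to_dict(orient="records"),
                "age_coding_winners": age_cmp["winners"],
                "aic_continuous": age_cmp["continuous"].aic,
                "aic_categorical": age_cmp["categorical"].aic,
            },
            out / "clinical_cox.json",
        )
        emit(stage, out / "clinical_cox.json")
        manifest["stages"][stage] = {
            "n_significant_univariate": int(screen["significant"].sum()),
            "age_coding_winners": age_cmp["winners"],
        }

        stage = "train"
        seed = stage_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        pool = dep_model.loc[dep_model["call"] != "ns"]
        pool = pool.sort_values("p_adj", kind="stable").head(config.max_pool)
        pool_ids = list(pool.index)
        prot = processed.values.loc[pool_ids].T  # samples x proteins
        clin_X = clinical[CLINICAL_FEATURES].astype(float)
        if config.model in ("CliCox", "CliRsf"):
            X_all = clin_X
        elif config.model in ("ProtCox", "ProtRsf"):
            X_all = prot.loc[clinical.index]
        else:
            X_all = pd.concat([clin_X, prot.loc[clinical.index]], axis=1)
        X_train = X_all.loc[split.train_ids]
        y_tr = clinical.loc[split.train_ids]
        grid = config.hyper_grid if config.model in ("CliRsf", "ProtRsf", "CliProtRsf") else {}
        model = build_model(
            config.model, X_train, y_tr["event"], y_tr["time"], seed=seed,
            hyper_grid=grid,
            stability_kwargs=config.stability.model_dump()
            if config.model in ("ProtRsf", "CliProtRsf") else None,
        )
        X_test = X_all.loc[split.test_ids]
        y_te = clinical.loc[split.test_ids]
        cinds = {
            "train": evaluate_cindex(model, X_train, y_tr["event"], y_tr["time"]),
            "cv": model.cv_cindex,
            "test": evaluate_cindex(model, X_test, y_te["event"], y_te["time"]),
        }
        panel = pd.DataFrame({"feature": model.features})
        panel.to_csv(out / "panel.csv", index=False)
        emit(stage, out / "panel.csv")
        if hasattr(model.selection, "counts"):
            model.selection.counts.rename("count").to_csv(out / "stability_counts.csv")
            emit(stage, out / "stability_counts.csv")
        pio.write_json({"model": config.model, "params": model.params,
                        "n_features": len(model.features), "c_index": cinds},
                       out / "model.json")
        emit(stage, out / "model.json")
        manifest["stages"][stage] = {"c_index": cinds,
                                     "panel_size": len(model.features)}

        stage = "stratify"
        times, S = predict_survival_curve(model, X_all.loc[clinical.index])
        horizon = config.crank_horizon or float(times[-1])
        cranks = pd.Series(compute_crank(times, S, horizon), index=clinical.index)
        thr = compute_threshold(cranks.loc[split.train_ids],
                                clinical.loc[split.train_ids, "event"])
        labels = pd.Series(stratify(cranks, thr), index=clinical.index)
        strat = evaluate_stratification(
            labels, clinical[["event", "time"]], thr,
            partitions={"train": split.train_ids, "test": split.test_ids},
        )
        cranks.rename("crank").to_csv(out / "cranks.csv")
        emit(stage, out / "cranks.csv")
        pio.write_json(strat.to_dict(), out / "stratification.json")
        emit(stage, out / "stratification.json")
        manifest["stages"][stage] = {"threshold": thr,
                                     "accuracy": strat.accuracy}
    except Exception as exc:  # annotate failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    pio.write_json(manifest, out / "manifest.json")
    return manifest


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(**payload)
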