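"""End-to-end pipeline runs driven by one config file.

A run executes the stages of the screening workflow in dependency
order — simulate → clean → select → train → evaluate → percept →
screen — writing each stage's outputs (all CSV/JSON) before the next
starts, and finishes with a manifest: config hash, package version,
per-stage output digests and the seeds used.  Deterministic stages
reproduce identical digests on re-run, which is the pipeline's
provenance contract.

The two historical phases of the method are both expressible as
configs: "v1" = forward selection + SVM scored over repeated 80/20
splits; "v2" = CV-RFE + a model-averaged random-forest ensemble.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem_table import DescriptorMatrix, clean_matrix, standardize
from .evaluation import repeated_kfold, repeated_split, binarize_activity
from .feature_selection import cv_rfe, sfs_select
from .models import ModelSpec, build_ensemble
from .percept import (
    compute_thresholds,
    descriptor_frequency_table,
    fit_percept_models,
    select_exemplars,
)
from .screening import (
    CandidateRecord,
    FilterConfig,
    apply_filters,
    nearest_known_repellent,
    records_to_frame,
    score_library,
)
from .synthetic_data import SyntheticConfig, make_dataset, write_dataset

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

STAGE_ORDER = ("simulate", "clean", "select", "train", "evaluate", "percept", "screen")


@dataclass
class RunConfig:
    """Flat per-stage configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d.get("stages", {})) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "run")),
            stages=d.get("stages", {}),
        )

    def to_dict(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, "stages": self.stages}

    def stage(self, name: str) -> Optional[dict]:
        block = self.stages.get(name)
        if block is None or not block.get("enabled", True):
            return None
        return block


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    digests: dict = field(default_factory=dict)  # stage -> {filename: sha256}
    timestamps: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "digests": self.digests,
            "timestamps": self.timestamps,
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_dir(stage_dir: Path) -> dict[str, str]:
    return {
        str(p.relative_to(stage_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file()
    }


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _validate_stage_inputs(config: RunConfig) -> None:
    """Fail before execution when a disabled stage starves a later one."""
    have_data = config.stage("simulate") is not None
    for name in ("clean", "select", "train"):
        block = config.stage(name)
        if block is None:
            continue
        if not have_data and "descriptors_csv" not in block:
            raise ValueError(
                f"stage {name!r} enabled but no simulate stage and no "
                "descriptors_csv input configured"
            )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash covers the scientific content (seed + stage parameters), not the
    # output location, so runs into different directories compare equal
    config_hash = hashlib.sha256(
        json.dumps({"seed": config.seed, "stages": config.stages},
                   sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash, package_version=__version__, seed=config.seed
    )
    _validate_stage_inputs(config)

    state: dict = {}
    for stage in STAGE_ORDER:
        block = config.stage(stage)
        if block is None:
            continue
        stage_dir = out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            _STAGE_FUNCS[stage](block, config, state, stage_dir)
        except Exception as exc:  # abort with stage name + partial manifest
            _write_manifest(out, manifest)
            raise PipelineError(stage, exc, manifest) from exc
        manifest.digests[stage] = _digest_dir(stage_dir)
        manifest.timestamps[stage] = time.time()
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: RunManifest) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(block, config, state, stage_dir):
    syn = SyntheticConfig(
        n_chemicals=block.get("n_chemicals", 201),
        n_features=block.get("n_features", 500),
        n_informative=block.get("n_informative", 18),
        effect_sizes=block.get("effect_sizes"),
        nuisance_correlation=block.get("nuisance_correlation", 0.3),
        noise_sd=block.get("noise_sd", 1.0),
        seed=config.seed,
    )
    dataset = make_dataset(
        syn,
        percept_sparsity=block.get("percept_sparsity"),
        percept_descriptors=block.get("percept_descriptors", 146),
        binary_top_fraction=block.get("binary_top_fraction"),
    )
    write_dataset(dataset, stage_dir)
    state["dataset"] = dataset
    state["X"] = dataset.descriptors
    state["y"] = dataset.response
    state["labels"] = dataset.labels
    state["syn_config"] = syn


def _load_inputs(block, state):
    if "descriptors_csv" in block:
        X = DescriptorMatrix.from_csv(block["descriptors_csv"])
        resp = pd.read_csv(block["response_csv"])
        state["X"] = X
        state["y"] = resp["repellency"].to_numpy()
        if "active" in resp.columns:
            state["labels"] = resp["active"].to_numpy()


def _stage_clean(block, config, state, stage_dir):
    _load_inputs(block, state)
    cleaned, report = clean_matrix(
        state["X"],
        max_missing_frac=block.get("max_missing_frac", 0.2),
        near_zero_var_freq_ratio=block.get("near_zero_var_freq_ratio", 19.0),
        pairwise_corr_cutoff=block.get("pairwise_corr_cutoff", 0.99),
    )
    cleaned.to_csv(stage_dir / "descriptors_clean.csv")
    (stage_dir / "cleaning_report.json").write_text(
        json.dumps(report.to_dict(), indent=1)
    )
    state["X"] = cleaned


def _stage_select(block, config, state, stage_dir):
    _load_inputs(block, state)
    X, y = state["X"], state["y"]
    method = block.get("method", "sfs")
    if method == "sfs":
        result = sfs_select(
            X,
            y,
            max_features=block.get("max_features", 18),
            tol=block.get("tol", 0.0),
            method=block.get("correlation", "pearson"),
        )
        pd.DataFrame(
            {"feature": result.selected, "multiple_correlation": result.correlation_path}
        ).to_csv(stage_dir / "sfs_selection.csv", index=False)
        state["selected"] = result.selected
    elif method == "cv_rfe":
        task = block.get("task", "regression")
        target = y
        if task == "classification":
            target = (
                state["labels"]
                if state.get("labels") is not None
                else binarize_activity(y, block.get("top_fraction", 0.4))[0]
            )
        ranking = cv_rfe(
            X,
            target,
            learner=block.get("learner", "random_forest"),
            subset_sizes=block.get("subset_sizes"),
            k=block.get("k", 5),
            repeats=block.get("repeats", 1),
            task=task,
            seed=config.seed,
            hyperparameters=block.get("hyperparameters"),
        )
        pd.DataFrame(
            {
                "feature": ranking.frequency.index,
                "frequency": ranking.frequency.values,
                "mean_importance": ranking.importance.reindex(
                    ranking.frequency.index
                ).values,
            }
        ).to_csv(stage_dir / "ranking.csv", index=False)
        pd.DataFrame(
            sorted(ranking.performance_by_n.items()),
            columns=["subset_size", "cv_score"],
        ).to_csv(stage_dir / "performance_by_n.csv", index=False)
        state["selected"] = ranking.top_features()
    else:
        raise ValueError(f"unknown selection method {method!r}")
    (stage_dir / "selected_features.json").write_text(json.dumps(state["selected"]))


def _train_spec(block, config) -> ModelSpec:
    return ModelSpec(
        learner=block.get("learner", "random_forest"),
        task=block.get("task", "regression"),
        hyperparameters=block.get("hyperparameters", {}),
        tuning_grid=block.get("tuning_grid"),
        seed=config.seed,
    )


def _train_target(block, state):
    if block.get("task", "regression") == "classification":
        if state.get("labels") is not None:
            return np.asarray(state["labels"])
        return binarize_activity(state["y"], block.get("top_fraction", 0.4))[0]
    return state["y"]


def _stage_train(block, config, state, stage_dir):
    _load_inputs(block, state)
    selected = state.get("selected", state["X"].feature_names)
    X_sel = state["X"].subset_features(selected)
    X_std = standardize(X_sel)
    spec = _train_spec(block, config)
    ensemble = build_ensemble(
        spec,
        X_std,
        _train_target(block, state),
        feature_pool=selected,
        n_members=block.get("n_members", 25),
        features_per_member=block.get("features_per_member"),
        row_fraction=block.get("row_fraction", 0.8),
        seed=config.seed,
    )
    ensemble.save(stage_dir / "ensemble")
    # directory archives are not digestible as single files; record a pointer
    (stage_dir / "ensemble_path.json").write_text(
        json.dumps({"archive": "ensemble"})
    )
    state["ensemble"] = ensemble
    state["train_std"] = X_std
    state["train_spec"] = spec


def _stage_evaluate(block, config, state, stage_dir):
    spec = state.get("train_spec") or _train_spec(block, config)
    selected = state.get("selected", state["X"].feature_names)
    X_sel = standardize(state["X"].subset_features(selected))
    y = _train_target(block, state)
    metric = block.get("metric", "auc" if spec.task == "classification" else "r")
    scheme = block.get("scheme", "split")
    if scheme == "split":
        report = repeated_split(
            spec, X_sel, y,
            train_frac=block.get("train_frac", 0.8),
            repeats=block.get("repeats", 100),
            metric=metric, seed=config.seed,
        )
    elif scheme == "kfold":
        report = repeated_kfold(
            spec, X_sel, y,
            k=block.get("k", 5), repeats=block.get("repeats", 20),
            metric=metric, seed=config.seed,
        )
    else:
        raise ValueError(f"unknown evaluation scheme {scheme!r}")
    pd.DataFrame(
        {"round": np.arange(len(report.per_round_scores)),
         "score": report.per_round_scores}
    ).to_csv(stage_dir / "per_round_scores.csv", index=False)
    (stage_dir / "summary.json").write_text(
        json.dumps({"scheme": report.scheme, "metric": report.metric,
                    "mean_score": report.mean_score})
    )
    state["evaluation"] = report


def _stage_percept(block, config, state, stage_dir):
    dataset = state.get("dataset")
    if dataset is None or dataset.percepts is None:
        raise ValueError("percept stage needs simulated percepts or a training CSV")
    train = dataset.percepts
    spec = ModelSpec("random_forest", "regression",
                     {"trees": block.get("trees", 100)}, None, config.seed)
    models = fit_percept_models(train, state["X"], spec)
    thresholds = compute_thresholds(train)
    predictions = models.predict(state["X"])
    exemplars = select_exemplars(predictions, thresholds)
    table = descriptor_frequency_table(exemplars, top_k=block.get("top_k"))
    predictions.to_csv(stage_dir / "predicted_usage.csv", index_label="chem_id")
    thresholds.rename("threshold").to_csv(stage_dir / "thresholds.csv",
                                          index_label="descriptor")
    table.rename("count").to_csv(stage_dir / "descriptor_frequency.csv",
                                 index_label="descriptor")
    state["exemplars"] = exemplars


def _stage_screen(block, config, state, stage_dir):
    ensemble = state.get("ensemble")
    if ensemble is None:
        raise ValueError("screen stage requires a trained ensemble")
    if "library_csv" in block:
        library = DescriptorMatrix.from_csv(block["library_csv"])
    else:
        syn = state["syn_config"]
        lib_cfg = SyntheticConfig(
            n_chemicals=block.get("library_n", 200),
            n_features=syn.n_features,
            n_informative=syn.n_informative,
            effect_sizes=syn.effect_sizes,
            nuisance_correlation=syn.nuisance_correlation,
            noise_sd=syn.noise_sd,
            seed=config.seed + 1,
        )
        lib_data = make_dataset(lib_cfg)
        library = DescriptorMatrix(
            lib_data.descriptors.data.rename(index=lambda s: "L" + s)
        )
    train_std = state["train_std"]
    lib_sel = library.subset_features(train_std.feature_names)
    lib_std = DescriptorMatrix(
        (lib_sel.data - train_std.standardization["center"])
        / train_std.standardization["scale"],
        standardization=train_std.standardization,
    )
    scored = score_library(ensemble, lib_std,
                           reference_chem=block.get("reference_chem"))
    # known repellents: the highest-responding training chemicals
    y = np.asarray(state["y"], dtype=float)
    n_known = min(block.get("n_known", 10), len(y))
    known_idx = np.argsort(-y, kind="stable")[:n_known]
    known = train_std.subset_rows(known_idx.tolist())
    exemplars = state.get("exemplars", {})
    records = []
    for chem_id, row in scored.iterrows():
        nearest = nearest_known_repellent(lib_std.data.loc[chem_id], known)
        records.append(
            CandidateRecord(
                chem_id=chem_id,
                repellency_score=float(row["score"]),
                percept_exemplars=set(exemplars.get(chem_id, set())),
                ca_activity=None,
                tox_category=block.get("default_tox_category", "III"),
                nearest_repellent=nearest,
            )
        )
    fcfg = FilterConfig(
        min_repellency_score=block.get("min_repellency_score"),
        max_ca_activity=block.get("max_ca_activity"),
        excluded_tox_categories=set(block.get("excluded_tox_categories", ["I", "II"])),
        top_n=block.get("top_n", 50),
        lenient_missing=block.get("lenient_missing", True),
    )
    survivors, annotated = apply_filters(records, fcfg)
    records_to_frame(annotated).to_csv(stage_dir / "candidates_all.csv", index=False)
    records_to_frame(survivors).to_csv(stage_dir / "survivors.csv", index=False)
    state["survivors"] = survivors


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "clean": _stage_clean,
    "select": _stage_select,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "percept": _stage_percept,
    "screen": _stage_screen,
}
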