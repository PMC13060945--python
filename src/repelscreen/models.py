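"""Learner contracts and the model-averaged ensemble.

Two learners are supported, matching common practice for small QSAR
training sets: a support vector machine with a radial-basis-function
kernel (sensitive, needs standardized features) and a random forest
(robust, two tunable parameters: trees and variables-per-split).  The
numerics are delegated to scikit-learn; the contribution here is the
wiring around them:

* :func:`fit_learner` — a uniform fit/predict contract (regression
  values, or class-1 scores in [0,1]: forest vote fractions, or a
  logistic map of the SVM margin), with optional inner-CV tuning;
* :func:`build_ensemble` — the model-averaged ensemble in which every
  member sees a random feature subset drawn from a selected pool and a
  random subsample of training chemicals, and the prediction is the
  unweighted mean over members — the deliberate slight underfit used
  when few observations are available;
* :func:`fit_shuffled_null` — shuffled-label controls: otherwise
  identical models trained on permuted outcomes, establishing the
  chance-level performance band a real model must exceed.

Fitted ensembles serialize to a plain-file archive (JSON manifest of
member feature subsets, row subsets, seeds and hyperparameters, plus
the training data as CSV); loading refits deterministically from those
seeds, so predictions are bit-reproducible from the archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR

from .chem_table import DescriptorMatrix
from .evaluation import _as_frame

__all__ = [
    "ModelSpec",
    "FittedLearner",
    "EnsembleModel",
    "fit_learner",
    "build_ensemble",
    "fit_shuffled_null",
]

ARCHIVE_VERSION = 1

# Default tuning grids; the cited R packages' conventions, overridable.
_SVM_COSTS = (0.25, 1.0, 4.0, 16.0)
_SVM_GAMMA_FACTORS = (0.1, 0.5, 1.0, 2.0)
_RF_TREES = 500


@dataclass
class ModelSpec:
    """Which learner, which task, and (optionally) how to tune it."""

    learner: str = "random_forest"  # {"svm_rbf", "random_forest"}
    task: str = "regression"  # {"regression", "classification"}
    hyperparameters: dict = field(default_factory=dict)
    tuning_grid: Optional[list[dict]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in ("svm_rbf", "random_forest"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.tuning_grid is not None and not self.tuning_grid:
            raise ValueError("tuning_grid must be nonempty when given")


class FittedLearner:
    """Uniform prediction contract over fitted scikit-learn estimators.

    ``predict`` returns regression values for a regression task and
    class-1 scores in [0,1] for classification (forest vote fractions,
    or a logistic map of the SVM margin).
    """

    def __init__(self, estimator, spec: ModelSpec, feature_names: list[str]):
        self.estimator = estimator
        self.spec = spec
        self.feature_names = feature_names

    def predict(self, X) -> np.ndarray:
        data = _as_frame(X)[self.feature_names]
        if self.spec.task == "classification":
            if hasattr(self.estimator, "predict_proba"):
                return self.estimator.predict_proba(data.to_numpy())[:, 1]
            # SVM: logistic map of the margin — monotone, in [0,1];
            # these are ranking scores, not calibrated probabilities
            margin = self.estimator.decision_function(data.to_numpy())
            return 1.0 / (1.0 + np.exp(-margin))
        return self.estimator.predict(data.to_numpy())


def _make_estimator(spec: ModelSpec, n_features: int, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.learner == "svm_rbf":
        cost = hp.get("cost", 1.0)
        gamma = hp.get("gamma", 1.0 / n_features)
        if spec.task == "classification":
            return SVC(C=cost, gamma=gamma, kernel="rbf", random_state=seed)
        return SVR(C=cost, gamma=gamma, kernel="rbf")
    trees = hp.get("trees", _RF_TREES)
    mtry = hp.get("variables_per_split")
    if mtry is None:
        mtry = "sqrt" if spec.task == "classification" else max(1, n_features // 3)
    cls = RandomForestClassifier if spec.task == "classification" else RandomForestRegressor
    return cls(n_estimators=trees, max_features=mtry, random_state=seed, n_jobs=1)


def _default_grid(spec: ModelSpec, n_features: int) -> list[dict]:
    if spec.learner == "svm_rbf":
        base_gamma = 1.0 / n_features
        return [
            {"cost": c, "gamma": base_gamma * f}
            for c in _SVM_COSTS
            for f in _SVM_GAMMA_FACTORS
        ]
    return [
        {"trees": _RF_TREES, "variables_per_split": mtry}
        for mtry in sorted({max(1, int(np.sqrt(n_features))), max(1, n_features // 3)})
    ]


def fit_learner(spec: ModelSpec, X, y: Sequence[float]) -> FittedLearner:
    """Fit one learner; inner CV over the tuning grid when requested.

    ``tuning_grid="default"`` selects a conventional grid for the
    learner.  For classification a single-class outcome is an error.
    """
    data = _as_frame(X)
    y = np.asarray(y)
    if data.isna().any().any():
        raise ValueError("descriptor matrix contains missing values; clean it first")
    if spec.task == "classification":
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("classification requires both classes in y")
    grid = spec.tuning_grid
    if grid == "default":
        grid = _default_grid(spec, data.shape[1])
    if grid:
        best, best_score = None, -np.inf
        from sklearn.model_selection import cross_val_score

        for point in grid:
            trial = ModelSpec(spec.learner, spec.task, {**spec.hyperparameters, **point},
                              None, spec.seed)
            est = _make_estimator(trial, data.shape[1], spec.seed)
            scoring = "roc_auc" if spec.task == "classification" else "r2"
            k = min(5, len(y)) if spec.task == "regression" else min(
                5, int(np.bincount(y).min()))
            k = max(2, k)
            score = cross_val_score(est, data.to_numpy(), y, cv=k, scoring=scoring).mean()
            if score > best_score:
                best, best_score = point, score
        spec = ModelSpec(spec.learner, spec.task, {**spec.hyperparameters, **best},
                         None, spec.seed)
    est = _make_estimator(spec, data.shape[1], spec.seed)
    est.fit(data.to_numpy(), y)
    return FittedLearner(est, spec, list(data.columns))


@dataclass
class _Member:
    features: list[str]
    rows: list[int]
    seed: int
    model: Optional[FittedLearner] = None


class EnsembleModel:
    """Model-averaged ensemble over feature and training subsamples."""

    def __init__(self, spec: ModelSpec, members: list[_Member],
                 feature_pool: list[str], train_X: pd.DataFrame, train_y: np.ndarray):
        if not members:
            raise ValueError("ensemble requires at least one member")
        self.spec = spec
        self.members = members
        self.feature_pool = feature_pool
        self._train_X = train_X
        self._train_y = train_y

    def predict(self, X) -> np.ndarray:
        data = _as_frame(X)
        preds = np.stack([m.model.predict(data[m.features]) for m in self.members])
        return preds.mean(axis=0)

    # -- plain-file serialization ------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": ARCHIVE_VERSION,
            "spec": {
                "learner": self.spec.learner,
                "task": self.spec.task,
                "hyperparameters": self.spec.hyperparameters,
                "seed": self.spec.seed,
            },
            "feature_pool": self.feature_pool,
            "members": [
                {"features": m.features, "rows": m.rows, "seed": m.seed}
                for m in self.members
            ],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        train = self._train_X.copy()
        train["__response__"] = self._train_y
        train.to_csv(path / "training_data.csv", index_label="chem_id")

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest["version"] != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {manifest['version']}")
        train = pd.read_csv(path / "training_data.csv", index_col="chem_id")
        y = train.pop("__response__").to_numpy()
        spec = ModelSpec(**manifest["spec"])
        members = [
            _Member(features=m["features"], rows=m["rows"], seed=m["seed"])
            for m in manifest["members"]
        ]
        model = cls(spec, members, manifest["feature_pool"], train, y)
        model._refit()
        return model

    def _refit(self) -> None:
        for m in self.members:
            sub_X = self._train_X.iloc[m.rows][m.features]
            sub_y = self._train_y[m.rows]
            mspec = ModelSpec(self.spec.learner, self.spec.task,
                              self.spec.hyperparameters, self.spec.tuning_grid, m.seed)
            m.model = fit_learner(mspec, sub_X, sub_y)


def build_ensemble(
    spec: ModelSpec,
    X,
    y: Sequence[float],
    feature_pool: Sequence[str],
    n_members: int = 50,
    features_per_member: Optional[int] = None,
    row_fraction: float = 0.8,
    seed: int = 0,
) -> EnsembleModel:
    """Train the model-averaged ensemble.

    Each member draws a uniform random feature subset (without
    replacement) from ``feature_pool`` and a uniform random row subset
    of size ``ceil(row_fraction * n)``; the ensemble prediction is the
    unweighted mean over members.
    """
    feature_pool = list(feature_pool)
    if not feature_pool:
        raise ValueError("feature_pool is empty")
    data = _as_frame(X)
    y = np.asarray(y)
    if features_per_member is None:
        features_per_member = max(1, len(feature_pool) // 2)
    if features_per_member > len(feature_pool):
        raise ValueError("features_per_member exceeds feature pool size")
    n = len(y)
    n_rows = int(np.ceil(row_fraction * n))
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        feats = sorted(rng.choice(feature_pool, size=features_per_member, replace=False))
        rows = sorted(rng.choice(n, size=n_rows, replace=False).tolist())
        members.append(_Member(features=list(feats), rows=rows,
                               seed=int(rng.integers(0, 2**31 - 1))))
    ens = EnsembleModel(spec, members, feature_pool, data, y)
    ens._refit()
    return ens


def fit_shuffled_null(
    spec: ModelSpec,
    X,
    y: Sequence[float],
    n_shuffles: int = 20,
    eval_fn: Optional[Callable] = None,
    seed: int = 0,
) -> np.ndarray:
    """Chance-level performance band from shuffled-label replicates.

    Labels are permuted before training each replicate; evaluation is
    otherwise identical to the real pipeline.  ``eval_fn(spec, X,
    y_shuffled, seed)`` must return one score; the default is the mean
    5-fold AUC (classification) or mean 5-fold Pearson R (regression).
    Returns the sample of null scores.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    y = np.asarray(y)
    if eval_fn is None:
        from .evaluation import repeated_kfold

        metric = "auc" if spec.task == "classification" else "r"

        def eval_fn(spec, X, y_perm, s):
            return repeated_kfold(spec, X, y_perm, k=5, repeats=1,
                                  metric=metric, seed=s).mean_score

    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_shuffles):
        y_perm = rng.permutation(y)
        scores.append(eval_fn(spec, X, y_perm, int(rng.integers(0, 2**31 - 1))))
    return np.array(scores)
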