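"""Odor-percept prediction, exemplar thresholding, frequency tables.

Human panelists rate odorants against a vocabulary of 146 odor-character
descriptors ("fruity", "perfumery", ...); the rating for each descriptor
is the % usage — the fraction of panelists who found it relevant, on a
0-100 scale.  This module

* fits one independent regression model per descriptor from the
  physicochemical descriptor matrix (:func:`fit_percept_models`),
* thresholds predicted usages into exemplar descriptors at 2x the
  descriptor's training mean (:func:`compute_thresholds`,
  :func:`select_exemplars`, strict inequality at the threshold),
* tabulates exemplar occurrences across a chemical set into a
  descriptor frequency table (:func:`descriptor_frequency_table`), and
* validates predictions by per-chemical ROC against observed
  annotation sets (:func:`percept_roc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import _as_frame, roc_auc
from .models import ModelSpec, fit_learner

__all__ = [
    "PerceptModelSet",
    "fit_percept_models",
    "compute_thresholds",
    "select_exemplars",
    "descriptor_frequency_table",
    "percept_roc",
]


@dataclass
class PerceptModelSet:
    """One regression model per odor descriptor, plus degenerate flags."""

    models: dict[str, object]
    descriptor_names: list[str]
    constant_zero: list[str] = field(default_factory=list)

    def predict(self, X) -> pd.DataFrame:
        """Predicted % usage per chemical × descriptor, clipped to [0,100]."""
        data = _as_frame(X)
        out = {}
        for name in self.descriptor_names:
            model = self.models[name]
            if model is None:
                out[name] = np.zeros(len(data))
            else:
                out[name] = np.clip(model.predict(data), 0.0, 100.0)
        return pd.DataFrame(out, index=data.index)


def fit_percept_models(
    train: pd.DataFrame, X_train, spec: Optional[ModelSpec] = None
) -> PerceptModelSet:
    """Fit per-descriptor usage models from chemical structure features.

    ``train`` is chemicals × descriptors of % usage in [0,100] with the
    same chemical ids as ``X_train``.  An all-zero descriptor column
    cannot support a model and is replaced by a constant-zero
    predictor, flagged in ``constant_zero``.
    """
    data = _as_frame(X_train)
    if list(train.index) != list(data.index):
        raise ValueError("percept training set and descriptor matrix ids differ")
    if ((train.values < 0) | (train.values > 100)).any():
        raise ValueError("% usage values must lie in [0,100]")
    if spec is None:
        spec = ModelSpec("random_forest", "regression", {"trees": 200})
    models: dict[str, object] = {}
    constant_zero = []
    for name in train.columns:
        col = train[name].to_numpy(dtype=float)
        if np.all(col == 0):
            models[name] = None
            constant_zero.append(name)
        else:
            models[name] = fit_learner(spec, data, col)
    return PerceptModelSet(
        models=models, descriptor_names=list(train.columns), constant_zero=constant_zero
    )


def compute_thresholds(train: pd.DataFrame) -> pd.Series:
    """Per-descriptor exemplar threshold: 2x the training-mean % usage."""
    return 2.0 * train.mean(axis=0)


def select_exemplars(
    predictions: pd.DataFrame, thresholds: pd.Series
) -> dict[str, set[str]]:
    """Exemplar descriptors per chemical: predicted usage strictly above
    the threshold (a prediction exactly at the threshold is excluded)."""
    missing = set(predictions.columns) - set(thresholds.index)
    if missing:
        raise ValueError(f"thresholds missing for descriptors: {sorted(missing)}")
    thr = thresholds.reindex(predictions.columns)
    mask = predictions.gt(thr, axis=1)
    return {
        chem: set(predictions.columns[row.to_numpy()])
        for chem, row in mask.iterrows()
    }


def descriptor_frequency_table(
    exemplar_sets: Mapping[str, set[str]], top_k: Optional[int] = None
) -> pd.Series:
    """Occurrences of each descriptor across chemicals' exemplar sets.

    Sorted descending, ties by descriptor name; ``top_k`` returns the
    head (e.g. the top-25 view exported for a word cloud).
    """
    counts: dict[str, int] = {}
    for exemplars in exemplar_sets.values():
        for d in exemplars:
            counts[d] = counts.get(d, 0) + 1
    table = pd.Series(counts, dtype=int)
    table = table.sort_index().sort_values(ascending=False, kind="mergesort")
    if top_k is not None:
        table = table.head(top_k)
    return table


def percept_roc(
    predictions: pd.DataFrame, observed: Mapping[str, Sequence[str]]
) -> tuple[dict[str, float], float, list[str]]:
    """Validate predicted profiles against observed annotation sets.

    For each chemical the predicted usages over all descriptors are
    ranked and scored by ROC against binary membership in the observed
    descriptor set.  Chemicals with an empty or full observed set have
    no defined ROC and are skipped (returned in the flag list).
    Returns (per-chemical AUC, mean AUC, skipped chemicals).
    """
    per_chem: dict[str, float] = {}
    skipped: list[str] = []
    n_desc = predictions.shape[1]
    for chem in observed:
        if chem not in predictions.index:
            raise KeyError(f"no predictions for chemical {chem!r}")
        obs = set(observed[chem])
        unknown = obs - set(predictions.columns)
        if unknown:
            raise ValueError(f"{chem}: unknown descriptors {sorted(unknown)}")
        if len(obs) == 0 or len(obs) == n_desc:
            skipped.append(chem)
            continue
        labels = predictions.columns.isin(obs).astype(int)
        scores = predictions.loc[chem].to_numpy(dtype=float)
        per_chem[chem] = roc_auc(scores, labels).auc
    if not per_chem:
        raise ValueError("no chemical had a scorable annotation set")
    mean_auc = float(np.mean(list(per_chem.values())))
    return per_chem, mean_auc, skipped
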