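"""Resampling schemes and performance metrics.

The screening models are judged the way the field judges small-n QSAR
models: repeated stratified k-fold cross-validation, repeated random
80/20 train/test splits, ROC/AUC for the classification view and
Pearson R / R-squared for the regression view, plus the helpers used to
binarize a continuous activity ("active" = top fraction of the
distribution) and to summarise many split scores into a few bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats as _sstats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, KFold

__all__ = [
    "ROCResult",
    "ResampleReport",
    "roc_auc",
    "repeated_kfold",
    "repeated_split",
    "binarize_activity",
    "bin_scores",
    "pearson_r",
    "r2",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ResampleReport:
    """Per-round scores of a repeated resampling evaluation."""

    scheme: str
    per_round_scores: np.ndarray
    seed: int
    metric: str
    extras: dict = field(default_factory=dict)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.per_round_scores))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC curve and trapezoidal AUC.

    Tied scores step diagonally (simultaneous step), which makes the
    trapezoidal area equal to the tie-corrected Mann-Whitney statistic
    (#concordant + 0.5 * #tied) / #pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("roc_auc requires both classes present")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for constant input")
    return float(_sstats.pearsonr(x, y)[0])


def r2(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Squared Pearson correlation of predicted vs observed."""
    return pearson_r(predicted, observed) ** 2


def binarize_activity(
    y: Sequence[float], top_fraction: float = 0.4
) -> tuple[np.ndarray, float]:
    """Label the top ``top_fraction`` of the activity distribution active.

    The threshold is the (1 - top_fraction) quantile; values tied at
    the threshold are all promoted to active (deterministic,
    conservative), so with heavy ties the achieved positive fraction
    can exceed the request — it is returned, never silently re-split.
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("cannot binarize a constant activity vector")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    threshold = np.quantile(y, 1.0 - top_fraction)
    labels = (y >= threshold).astype(int)
    return labels, float(labels.mean())


def bin_scores(scores: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Mean of contiguous equal-size groups of scores, in round order.

    With 100 split scores and 10 bins this is the 10-bin summary used
    to display per-split R-squared values; any remainder is spread over
    the first groups.
    """
    scores = np.asarray(scores, dtype=float)
    if n_bins > len(scores):
        raise ValueError("n_bins exceeds number of scores")
    return np.array([chunk.mean() for chunk in np.array_split(scores, n_bins)])


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

Metric = Union[str, Callable[[np.ndarray, np.ndarray], float]]


def _score(metric: Metric, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if callable(metric):
        return float(metric(y_true, y_pred))
    if metric == "auc":
        return roc_auc(y_pred, y_true).auc
    if metric == "r":
        return pearson_r(y_pred, y_true)
    if metric == "r2":
        return r2(y_pred, y_true)
    if metric == "rmse":
        return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    raise ValueError(f"unknown metric {metric!r}")


def _fit_predict(spec, X_train, y_train, X_test):
    # local import to avoid a circular module dependency
    from .models import fit_learner

    model = fit_learner(spec, X_train, y_train)
    return model.predict(X_test)


def repeated_kfold(
    spec,
    X,
    y: Sequence[float],
    k: int = 5,
    repeats: int = 20,
    metric: Metric = "auc",
    seed: int = 0,
) -> ResampleReport:
    """Repeated k-fold cross-validation (e.g. 20 independent 5-fold CVs).

    Folds are stratified by class for classification; each repeat
    re-randomises the fold assignment.  A class with fewer members than
    k triggers a warning and a fall back to unstratified folds.
    Per-fold metric values are recorded (k * repeats rounds).
    """
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError("need at least k samples")
    data = _as_frame(X)
    rng = np.random.default_rng(seed)
    stratify = spec.task == "classification"
    if stratify and np.bincount(y.astype(int)).min() < k:
        warnings.warn("a class has fewer members than k; using unstratified folds")
        stratify = False
    scores = []
    for _ in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        splitter = (
            StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            if stratify
            else KFold(n_splits=k, shuffle=True, random_state=rs)
        )
        for tr, te in splitter.split(data, y if stratify else None):
            pred = _fit_predict(spec, data.iloc[tr], y[tr], data.iloc[te])
            scores.append(_score(metric, y[te], pred))
    return ResampleReport(
        scheme=f"kfold(k={k}, repeats={repeats})",
        per_round_scores=np.array(scores),
        seed=seed,
        metric=metric if isinstance(metric, str) else metric.__name__,
    )


def repeated_split(
    spec,
    X,
    y: Sequence[float],
    train_frac: float = 0.8,
    repeats: int = 100,
    metric: Metric = "auc",
    seed: int = 0,
) -> ResampleReport:
    """Repeated random train/test splits (e.g. 100 80/20 splits)."""
    y = np.asarray(y)
    n = len(y)
    data = _as_frame(X)
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("train_frac leaves an empty partition")
    rng = np.random.default_rng(seed)
    stratify = spec.task == "classification"
    scores = []
    for _ in range(repeats):
        while True:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if not stratify or (len(np.unique(y[tr])) > 1 and len(np.unique(y[te])) > 1):
                break
        pred = _fit_predict(spec, data.iloc[tr], y[tr], data.iloc[te])
        scores.append(_score(metric, y[te], pred))
    return ResampleReport(
        scheme=f"split(frac={train_frac}, repeats={repeats})",
        per_round_scores=np.array(scores),
        seed=seed,
        metric=metric if isinstance(metric, str) else metric.__name__,
    )


def _as_frame(X):
    """Accept a DescriptorMatrix or a plain DataFrame."""
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        return X
    return X.data
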