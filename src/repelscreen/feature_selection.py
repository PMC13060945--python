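"""Feature selection: greedy forward search and cross-validated RFE.

Two procedures cover the two phases of the screening pipeline:

* :func:`sfs_select` — sequential forward selection: an iterative
  search over the descriptor pool that greedily maximizes the
  correlation between the model of the selected features and the %
  repellency.  The objective is made precise as the multiple
  correlation of a least-squares fit on the candidate subset (Pearson
  correlation between fitted and observed response); Spearman is
  available by flag.

* :func:`cv_rfe` — recursive feature elimination wrapped in repeated
  k-fold cross-validation.  Per data partition the learner is fitted,
  per-feature importance is computed, the feature set is pruned to each
  requested subset size, and each pruned model predicts the held-out
  partition.  Aggregated over hundreds of rounds this converges on the
  optimal number of features and an aggregate rank: the frequency at
  which each feature lands in the optimally-sized subset.

Importance is learner-appropriate: the random forest gets permutation
importance (% increase in held-out-style error after shuffling one
feature); the SVM, which has no native bootstrap test set, gets a
filter metric per feature — a lowess pseudo R² for regression or the
single-feature AUC for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import _as_frame, roc_auc

__all__ = [
    "SFSResult",
    "FeatureRanking",
    "sfs_select",
    "cv_rfe",
    "permutation_importance",
    "filterwise_importance",
]


@dataclass
class SFSResult:
    selected: list[str]
    correlation_path: list[float]
    stop_reason: str  # {"max_reached", "tolerance"}


@dataclass
class FeatureRanking:
    """Aggregate output of cross-validated recursive feature elimination."""

    frequency: pd.Series  # rounds in which the feature was in the counted subset
    importance: pd.Series  # mean full-pool importance across rounds
    optimal_n: int
    performance_by_n: dict[int, float]
    n_rounds: int
    metric: str

    def top_features(self, n: Optional[int] = None) -> list[str]:
        """Top-n features by frequency (ties by importance, then name)."""
        n = self.optimal_n if n is None else n
        order = pd.DataFrame(
            {"freq": self.frequency, "imp": self.importance.reindex(self.frequency.index)}
        )
        order = order.sort_values(
            by=["freq", "imp"], ascending=False, kind="mergesort"
        )
        # stable mergesort + name-sorted index makes ties deterministic
        return list(order.index[:n])


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------


def _multiple_correlation(Xc: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between OLS-fitted and observed response."""
    A = np.column_stack([np.ones(len(y)), Xc])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    if np.std(fitted) == 0:
        return 0.0
    return float(np.corrcoef(fitted, y)[0, 1])


def sfs_select(
    X,
    y: Sequence[float],
    max_features: int,
    tol: float = 0.0,
    method: str = "pearson",
) -> SFSResult:
    """Greedy forward selection maximizing the multiple correlation.

    At each step every unselected feature is scored by the correlation
    between the observed response and a least-squares fit on the
    selected set plus that feature; the argmax is added (ties broken by
    feature-name order).  Stops at ``max_features`` or when the
    improvement drops below ``tol``.  ``method="spearman"`` runs the
    identical search on rank-transformed data.
    """
    data = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("response is constant; correlation undefined")
    if data.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")
    if max_features > data.shape[1]:
        raise ValueError("max_features exceeds available features")
    if method == "spearman":
        data = data.rank()
        y = _sstats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    values = data.to_numpy()
    names = list(data.columns)
    selected: list[int] = []
    path: list[float] = []
    best_so_far = 0.0
    stop_reason = "max_reached"
    while len(selected) < max_features:
        best_score, best_j = -np.inf, None
        for j in range(values.shape[1]):
            if j in selected:
                continue
            score = _multiple_correlation(values[:, selected + [j]], y)
            # strict > plus name-ordered scan = ties go to the earlier name
            if score > best_score + 1e-15 or (
                best_j is not None
                and abs(score - best_score) <= 1e-15
                and names[j] < names[best_j]
            ):
                best_score, best_j = score, j
        improvement = best_score - best_so_far
        if selected and improvement < tol:
            stop_reason = "tolerance"
            break
        selected.append(best_j)
        path.append(best_score)
        best_so_far = best_score
    return SFSResult(
        selected=[names[j] for j in selected],
        correlation_path=path,
        stop_reason=stop_reason,
    )


# ---------------------------------------------------------------------------
# Importance measures
# ---------------------------------------------------------------------------


def _error(metric: str, y: np.ndarray, pred: np.ndarray) -> float:
    if metric == "rmse":
        return float(np.sqrt(np.mean((y - pred) ** 2)))
    if metric == "auc":
        return 1.0 - roc_auc(pred, y).auc
    raise ValueError(f"unknown error metric {metric!r}")


def permutation_importance(
    model,
    X_test,
    y_test: Sequence[float],
    feature: str,
    metric: str = "rmse",
    seed: int = 0,
    n_repeats: int = 1,
) -> float:
    """% increase in error after permuting one feature.

    importance = 100 * (error_permuted - error_baseline) / error_baseline,
    with error = RMSE (regression) or 1 - AUC (classification).  A zero
    baseline error yields 0 when the permuted error is also 0, else
    +infinity (the feature is the model).
    """
    data = _as_frame(X_test)
    if feature not in data.columns:
        raise KeyError(f"feature {feature!r} not present")
    y = np.asarray(y_test)
    base = _error(metric, y, model.predict(data))
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_repeats):
        perm = data.copy()
        perm[feature] = rng.permutation(perm[feature].to_numpy())
        errs.append(_error(metric, y, model.predict(perm)))
    permuted = float(np.mean(errs))
    if base == 0.0:
        return 0.0 if permuted == 0.0 else float("inf")
    return 100.0 * (permuted - base) / base


def _batch_permutation_importance(
    model, data: pd.DataFrame, y: np.ndarray, metric: str, rng: np.random.Generator
) -> pd.Series:
    """Permutation importance of every column, one shuffle each.

    In-place column swap avoids copying the matrix per feature; used
    inside the RFE loop where importance for hundreds of features is
    recomputed at every elimination step.
    """
    base = _error(metric, y, model.predict(data))
    arr = data.to_numpy().copy()
    frame = pd.DataFrame(arr, index=data.index, columns=data.columns)
    out = {}
    for j, name in enumerate(data.columns):
        original = arr[:, j].copy()
        arr[:, j] = rng.permutation(original)
        err = _error(metric, y, model.predict(frame))
        arr[:, j] = original
        if base == 0.0:
            out[name] = 0.0 if err == 0.0 else float("inf")
        else:
            out[name] = 100.0 * (err - base) / base
    return pd.Series(out)


def filterwise_importance(X, y: Sequence[float], feature: str, task: str) -> float:
    """Single-feature filter importance for learners without a native one.

    Regression: squared correlation between the response and a lowess
    smooth of the response on the feature (pseudo R² from nonlinear
    regression).  Classification: the single-feature AUC folded to
    max(AUC, 1-AUC), so an anti-correlated perfect predictor scores 1.
    Constant features score 0.
    """
    data = _as_frame(X)
    x = data[feature].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0:
        return 0.0
    if task == "regression":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smooth = lowess(y, x, frac=0.6, return_sorted=False)
        if np.std(smooth) == 0:
            return 0.0
        return float(np.corrcoef(y, smooth)[0, 1] ** 2)
    if task == "classification":
        auc = roc_auc(x, y.astype(int)).auc
        return float(max(auc, 1.0 - auc))
    raise ValueError(f"unknown task {task!r}")


def _filterwise_all(data: pd.DataFrame, y: np.ndarray, task: str) -> pd.Series:
    return pd.Series(
        {name: filterwise_importance(data, y, name, task) for name in data.columns}
    )


# ---------------------------------------------------------------------------
# Cross-validated recursive feature elimination
# ---------------------------------------------------------------------------


def _top_n(importance: pd.Series, n: int) -> list[str]:
    """Top-n by importance, ties by feature-name order (deterministic)."""
    order = importance.sort_index().sort_values(ascending=False, kind="mergesort")
    return sorted(order.index[:n])


def cv_rfe(
    X,
    y: Sequence[float],
    learner: str = "random_forest",
    subset_sizes: Optional[Sequence[int]] = None,
    k: int = 5,
    repeats: int = 1,
    task: str = "regression",
    seed: int = 0,
    count_mode: str = "optimal",
    hyperparameters: Optional[dict] = None,
) -> FeatureRanking:
    """Recursive feature elimination under repeated k-fold CV.

    Per round (repeat × fold): the learner is fitted on the training
    partition with the current feature set, importance is recomputed,
    the set is pruned to each size in ``subset_sizes`` (descending) in
    turn, and each pruned model predicts the held-out partition.  The
    per-size score (Pearson R for regression, AUC for classification)
    is averaged over rounds; ``optimal_n`` is the argmax.  Frequency
    counts, per round, the features in the subset of the optimal size
    (``count_mode="per_size"`` counts membership in every sized subset
    instead).
    """
    from .models import ModelSpec, fit_learner

    data = _as_frame(X)
    y = np.asarray(y)
    n, p = data.shape
    if subset_sizes is None:
        sizes = [p]
        while sizes[-1] > 2:
            sizes.append(max(2, sizes[-1] // 2))
        subset_sizes = sizes
    subset_sizes = sorted(set(int(s) for s in subset_sizes), reverse=True)
    if subset_sizes[0] > p:
        raise ValueError("subset size exceeds available features")
    if k < 2:
        raise ValueError("k must be >= 2")
    if count_mode not in ("optimal", "per_size"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if task == "classification":
        y = y.astype(int)
    metric = "auc" if task == "classification" else "r"
    err_metric = "auc" if task == "classification" else "rmse"
    hp = hyperparameters or {}

    rng = np.random.default_rng(seed)
    round_subsets: list[dict[int, list[str]]] = []
    round_scores: list[dict[int, float]] = []
    full_importances: list[pd.Series] = []

    for _ in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        if task == "classification" and np.bincount(y).min() >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            split_iter = splitter.split(data, y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
            split_iter = splitter.split(data)
        for tr, te in split_iter:
            X_tr, X_te = data.iloc[tr], data.iloc[te]
            y_tr, y_te = y[tr], y[te]
            current = list(data.columns)
            subsets: dict[int, list[str]] = {}
            scores: dict[int, float] = {}
            spec = ModelSpec(learner, task, hp, None, int(rng.integers(0, 2**31 - 1)))
            model = fit_learner(spec, X_tr[current], y_tr)
            importance = _importance_for(
                learner, model, X_tr[current], y_tr, task, err_metric, rng
            )
            full_importances.append(importance.reindex(data.columns))
            for size in subset_sizes:
                if size < len(current):
                    current = _top_n(importance, size)
                    spec = ModelSpec(
                        learner, task, hp, None, int(rng.integers(0, 2**31 - 1))
                    )
                    model = fit_learner(spec, X_tr[current], y_tr)
                    # true RFE: importance recomputed at every elimination step
                    if size > subset_sizes[-1]:
                        importance = _importance_for(
                            learner, model, X_tr[current], y_tr, task, err_metric, rng
                        )
                subsets[size] = list(current)
                pred = model.predict(X_te[current])
                try:
                    score = (
                        roc_auc(pred, y_te).auc
                        if task == "classification"
                        else float(np.corrcoef(pred, y_te)[0, 1])
                    )
                except ValueError:
                    score = np.nan
                if np.isnan(score):
                    score = 0.0
                scores[size] = score
            round_subsets.append(subsets)
            round_scores.append(scores)

    n_rounds = len(round_scores)
    performance_by_n = {
        size: float(np.mean([r[size] for r in round_scores])) for size in subset_sizes
    }
    optimal_n = max(performance_by_n, key=lambda s: (performance_by_n[s], -s))
    freq = pd.Series(0, index=data.columns, dtype=int)
    for subsets in round_subsets:
        if count_mode == "optimal":
            freq[subsets[optimal_n]] += 1
        else:
            for members in subsets.values():
                freq[members] += 1
    mean_importance = pd.concat(full_importances, axis=1).mean(axis=1)
    return FeatureRanking(
        frequency=freq,
        importance=mean_importance,
        optimal_n=optimal_n,
        performance_by_n=performance_by_n,
        n_rounds=n_rounds,
        metric=metric,
    )


def _importance_for(
    learner: str,
    model,
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    task: str,
    err_metric: str,
    rng: np.random.Generator,
) -> pd.Series:
    if learner == "random_forest":
        return _batch_permutation_importance(model, X_tr, y_tr, err_metric, rng)
    return _filterwise_all(X_tr, y_tr, task)
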