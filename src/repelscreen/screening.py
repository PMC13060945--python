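"""Library scoring and the multi-filter triage cascade.

A trained repellency ensemble scores an arbitrary chemical library
(streamed in row chunks, so library size is unbounded by memory) and
each candidate is annotated the way a screening report presents it:
predicted % repellency relative to a reference repellent (DEET by
convention), predicted odor-percept exemplars, predicted intracellular
Ca²⁺ mobilization, a toxicity category, and the nearest known repellent
with its Euclidean distance in standardized feature space.  Filters are
independent predicates over those annotations; the survivor set is
their conjunction, ranked by repellency score.  Missing filter inputs
fail closed by default (safety-biased), with a lenient switch.

Toxicity is consumed as an input column: either an EPA category I-IV
directly, or a predicted oral LD50 (mg/kg) mapped via the standard
breakpoints (I <= 50 < II <= 500 < III <= 5000 < IV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_table import DescriptorMatrix
from .models import EnsembleModel

__all__ = [
    "CandidateRecord",
    "FilterConfig",
    "score_library",
    "nearest_known_repellent",
    "apply_filters",
    "predict_ca_activity",
    "ld50_to_epa_category",
]

_EPA_BREAKPOINTS = (50.0, 500.0, 5000.0)  # oral LD50 mg/kg: I | II | III | IV


def ld50_to_epa_category(ld50_mg_per_kg: float) -> str:
    """EPA acute-oral toxicity category from a predicted LD50."""
    if np.isnan(ld50_mg_per_kg):
        return "unknown"
    if ld50_mg_per_kg < 0:
        raise ValueError("LD50 must be >= 0")
    for cat, cut in zip(("I", "II", "III"), _EPA_BREAKPOINTS):
        if ld50_mg_per_kg <= cut:
            return cat
    return "IV"


@dataclass
class CandidateRecord:
    """One screened chemical with every triage annotation."""

    chem_id: str
    repellency_score: float
    percept_exemplars: set[str] = field(default_factory=set)
    ca_activity: Optional[float] = None
    tox_category: str = "unknown"
    ld50_pred: Optional[float] = None
    nearest_repellent: Optional[tuple[str, float]] = None
    filter_verdicts: dict[str, str] = field(default_factory=dict)
    final: Optional[bool] = None


@dataclass
class FilterConfig:
    """Enabled triage filters and their thresholds."""

    min_repellency_score: Optional[float] = None
    required_percepts: Optional[set[str]] = None
    forbidden_percepts: Optional[set[str]] = None
    max_ca_activity: Optional[float] = None
    excluded_tox_categories: set[str] = field(default_factory=lambda: {"I", "II"})
    top_n: int = 100
    lenient_missing: bool = False

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def score_library(
    ensemble: EnsembleModel,
    X_library: DescriptorMatrix,
    reference_chem: Optional[str] = None,
    chunk_size: int = 2000,
) -> pd.DataFrame:
    """Ensemble-score every library chemical; optional relative scale.

    When ``reference_chem`` (a library row id) is given, scores are
    rescaled to 100 * score / score(reference), the "% repellency
    relative to DEET" presentation.  Rows are processed in chunks of
    ``chunk_size`` and chunked scoring is bit-identical to whole-matrix
    scoring.  Returns a DataFrame (chem_id index, 'score' column)
    sorted descending with ties broken by chem_id.
    """
    needed = set()
    for m in ensemble.members:
        needed.update(m.features)
    missing = sorted(needed - set(X_library.feature_names))
    if missing:
        raise ValueError(f"library lacks model features: {missing}")
    n = X_library.shape[0]
    parts = []
    for start in range(0, n, chunk_size):
        chunk = X_library.data.iloc[start : start + chunk_size]
        parts.append(ensemble.predict(chunk))
    scores = pd.Series(np.concatenate(parts), index=X_library.chem_ids, name="score")
    if reference_chem is not None:
        if reference_chem not in scores.index:
            raise KeyError(f"reference chemical {reference_chem!r} not in library")
        ref = scores[reference_chem]
        if ref == 0:
            raise ValueError("reference chemical has zero score; relative scale undefined")
        scores = 100.0 * scores / ref
    out = scores.to_frame()
    out = out.sort_index().sort_values("score", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def nearest_known_repellent(
    candidate: pd.Series, known: DescriptorMatrix
) -> tuple[str, float]:
    """Closest known repellent by Euclidean distance (shared standardized
    feature space); ties broken by chem_id order."""
    if known.shape[0] == 0:
        raise ValueError("known-repellent set is empty")
    vec = candidate.reindex(known.feature_names).to_numpy(dtype=float)
    if np.isnan(vec).any():
        raise ValueError("candidate lacks features of the known-repellent space")
    diffs = known.values - vec
    dists = np.sqrt((diffs**2).sum(axis=1))
    best = int(np.argmin(dists))  # argmin takes the first = lowest row order
    return known.chem_ids[best], float(dists[best])


def predict_ca_activity(ensemble: EnsembleModel, X: DescriptorMatrix) -> pd.Series:
    """Predicted relative luminescence (Ca²⁺ mobilization) per chemical,
    on whatever relative scale the ensemble was trained on."""
    needed = set()
    for m in ensemble.members:
        needed.update(m.features)
    missing = sorted(needed - set(X.feature_names))
    if missing:
        raise ValueError(f"matrix lacks Ca2+ model features: {missing}")
    return pd.Series(ensemble.predict(X.data), index=X.chem_ids, name="ca_activity")


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def _verdict(ok: Optional[bool]) -> str:
    if ok is None:
        return "unknown"
    return "pass" if ok else "fail"


def apply_filters(
    records: Iterable[CandidateRecord], config: FilterConfig
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Run the triage cascade over candidate records.

    Each enabled filter writes a per-record verdict ("pass"/"fail"/
    "unknown"); "unknown" (missing input) is treated as fail unless
    ``lenient_missing``.  The final verdict is the conjunction of the
    enabled filters, so the survivor set is independent of filter
    order.  Returns (top-n survivors ranked by repellency score, the
    full annotated record list as audit trail).
    """
    annotated = []
    for rec in records:
        verdicts: dict[str, str] = {}
        if config.min_repellency_score is not None:
            verdicts["repellency"] = _verdict(
                None
                if rec.repellency_score is None or np.isnan(rec.repellency_score)
                else rec.repellency_score >= config.min_repellency_score
            )
        if config.required_percepts is not None:
            verdicts["percept_required"] = _verdict(
                config.required_percepts <= rec.percept_exemplars
            )
        if config.forbidden_percepts is not None:
            verdicts["percept_forbidden"] = _verdict(
                not (config.forbidden_percepts & rec.percept_exemplars)
            )
        if config.max_ca_activity is not None:
            verdicts["ca_activity"] = _verdict(
                None if rec.ca_activity is None else rec.ca_activity <= config.max_ca_activity
            )
        if config.excluded_tox_categories:
            verdicts["toxicity"] = _verdict(
                None
                if rec.tox_category == "unknown"
                else rec.tox_category not in config.excluded_tox_categories
            )
        rec.filter_verdicts = verdicts
        passed = all(
            v == "pass" or (v == "unknown" and config.lenient_missing)
            for v in verdicts.values()
        )
        rec.final = passed
        annotated.append(rec)
    survivors = [r for r in annotated if r.final]
    survivors.sort(key=lambda r: (-r.repellency_score, r.chem_id))
    return survivors[: config.top_n], annotated


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Flatten candidate records into the screening-report table."""
    rows = []
    for r in records:
        rows.append(
            {
                "chem_id": r.chem_id,
                "repellency_score": r.repellency_score,
                "percept_exemplars": ";".join(sorted(r.percept_exemplars)),
                "ca_activity": r.ca_activity,
                "tox_category": r.tox_category,
                "ld50_pred": r.ld50_pred,
                "nearest_repellent": r.nearest_repellent[0] if r.nearest_repellent else None,
                "nearest_distance": r.nearest_repellent[1] if r.nearest_repellent else None,
                **{f"filter_{k}": v for k, v in r.filter_verdicts.items()},
                "final": r.final,
            }
        )
    return pd.DataFrame(rows)
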