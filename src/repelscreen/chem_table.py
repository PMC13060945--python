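"""Chemical tables and descriptor matrices.

The screening pipeline consumes chemicals as rows of a numeric
physicochemical descriptor matrix (the kind of table produced by
descriptor engines such as Dragon or AlvaDesc, or by open-source
tools like RDKit).  This module provides:

* :class:`ChemicalRecord` / :func:`load_chemicals` — identifier +
  SMILES (+ optional name / CAS) tables read from CSV;
* :class:`DescriptorMatrix` — chemicals × features with explicit
  missing values and optional stored standardization statistics;
* :func:`compute_descriptors` — assemble a matrix from SMILES via a
  pluggable backend (commercial engines cannot be redistributed, so
  the backend is a contract; an RDKit-based default is provided);
* :func:`clean_matrix` — drop high-missingness, near-constant and
  redundant (highly correlated) features, impute the remainder;
* :func:`standardize` — per-feature centering/scaling with
  training-set statistics, so Euclidean distances and RBF kernels are
  scale-free and screening sets never leak their own statistics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalRecord",
    "DescriptorMatrix",
    "CleaningReport",
    "load_chemicals",
    "compute_descriptors",
    "clean_matrix",
    "standardize",
    "destandardize",
    "rdkit_backend",
]

# CAS registry numbers: 2-7 digits, 2 digits, 1 check digit.
_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


@dataclass
class ChemicalRecord:
    """One chemical: unique id plus optional structure and metadata."""

    chem_id: str
    smiles: Optional[str] = None
    name: Optional[str] = None
    cas: Optional[str] = None


class DescriptorMatrix:
    """Chemicals × numeric features, NaN marking missing values.

    Thin wrapper over a float DataFrame (index = chemical ids, columns =
    feature names).  ``standardization`` holds per-feature (center,
    scale) learned on a training set; a standardized matrix carries the
    statistics used so screening sets can be mapped into the same space.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        standardization: Optional[pd.DataFrame] = None,
    ) -> None:
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate chemical ids: {dupes}")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if standardization is not None:
            missing = set(self.feature_names) - set(standardization.index)
            if missing:
                raise ValueError(f"standardization lacks features: {sorted(missing)}")
            if (standardization["scale"].reindex(self.feature_names) <= 0).any():
                raise ValueError("standardization scale must be > 0 for all features")
        self.standardization = standardization

    @property
    def chem_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        std = None
        if self.standardization is not None:
            std = self.standardization.loc[list(names)]
        return DescriptorMatrix(self.data[list(names)], std)

    def subset_rows(self, ids_or_index: Sequence) -> "DescriptorMatrix":
        if all(isinstance(i, (int, np.integer)) for i in ids_or_index):
            sub = self.data.iloc[list(ids_or_index)]
        else:
            sub = self.data.loc[list(ids_or_index)]
        return DescriptorMatrix(sub, self.standardization)

    def to_csv(self, path) -> None:
        """Write chemicals as rows, header row of feature names, first column id."""
        self.data.to_csv(path, index_label="chem_id")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="chem_id")
        return cls(df)

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.shape
        tag = " standardized" if self.standardization is not None else ""
        return f"<DescriptorMatrix {n} chemicals x {p} features{tag}>"


@dataclass
class CleaningReport:
    """What :func:`clean_matrix` removed and why."""

    dropped_constant: list[str] = field(default_factory=list)
    dropped_missing: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str]] = field(default_factory=list)
    imputed_cells: int = 0
    failed_chemicals: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.dropped_constant
            or self.dropped_missing
            or self.dropped_correlated
            or self.imputed_cells
        )

    def to_dict(self) -> dict:
        return {
            "dropped_constant": self.dropped_constant,
            "dropped_missing": self.dropped_missing,
            "dropped_correlated": [list(p) for p in self.dropped_correlated],
            "imputed_cells": self.imputed_cells,
            "failed_chemicals": self.failed_chemicals,
        }


def load_chemicals(path) -> list[ChemicalRecord]:
    """Read a chemicals CSV (chem_id [, smiles, name, cas]) into records.

    Duplicate ids are an error; a malformed CAS token is kept as text
    with a warning (upstream sources are messy, but identity matters).
    """
    df = pd.read_csv(path, dtype=str)
    if "chem_id" not in df.columns:
        raise ValueError(f"{path}: no 'chem_id' column")
    dupes = df["chem_id"][df["chem_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate chem_id values: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        cas = row.get("cas")
        cas = None if pd.isna(cas) else str(cas)
        if cas is not None and not _CAS_RE.match(cas):
            warnings.warn(f"chem_id {row['chem_id']}: CAS {cas!r} is malformed; kept as text")
        smiles = row.get("smiles")
        name = row.get("name")
        records.append(
            ChemicalRecord(
                chem_id=str(row["chem_id"]),
                smiles=None if pd.isna(smiles) else str(smiles),
                name=None if pd.isna(name) else str(name),
                cas=cas,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Descriptor backends
# ---------------------------------------------------------------------------

# Backend contract: callable mapping one SMILES string to an ordered
# mapping {feature_name: float}. Feature names must be identical across
# chemicals. A raising backend marks that chemical's row all-missing.
DescriptorBackend = Callable[[str], Mapping[str, float]]


def rdkit_backend(smiles: str) -> dict[str, float]:
    """Open-source default backend: full RDKit 2D descriptor set."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {name: float(fn(mol)) for name, fn in Descriptors.descList}


def compute_descriptors(
    records: Iterable[ChemicalRecord],
    backend: DescriptorBackend = rdkit_backend,
) -> tuple[DescriptorMatrix, CleaningReport]:
    """Assemble a descriptor matrix from SMILES via a pluggable backend.

    Per-chemical backend failures are recorded as all-missing rows (and
    listed in the report), not fatal: a screening library of thousands
    of structures routinely contains a few unparseable entries.
    Inconsistent feature names across chemicals are a backend bug and an
    error.
    """
    records = list(records)
    rows: dict[str, Optional[Mapping[str, float]]] = {}
    feature_names: Optional[list[str]] = None
    failed: list[str] = []
    for rec in records:
        if rec.smiles is None:
            raise ValueError(f"chem_id {rec.chem_id} has no SMILES")
        try:
            vec = backend(rec.smiles)
        except Exception:
            rows[rec.chem_id] = None
            failed.append(rec.chem_id)
            continue
        names = list(vec.keys())
        if feature_names is None:
            feature_names = names
        elif names != feature_names:
            raise ValueError(
                f"backend returned inconsistent feature names for {rec.chem_id}"
            )
        rows[rec.chem_id] = vec
    if feature_names is None:
        raise ValueError("backend failed for every chemical")
    data = pd.DataFrame(
        [
            [np.nan] * len(feature_names)
            if rows[r.chem_id] is None
            else [rows[r.chem_id][f] for f in feature_names]
            for r in records
        ],
        index=[r.chem_id for r in records],
        columns=feature_names,
        dtype=float,
    )
    report = CleaningReport(failed_chemicals=failed)
    return DescriptorMatrix(data), report


# ---------------------------------------------------------------------------
# Cleaning and standardization
# ---------------------------------------------------------------------------


def _near_zero_variance(col: pd.Series, freq_ratio: float) -> bool:
    vals = col.dropna()
    if vals.nunique() <= 1:
        return True
    counts = vals.value_counts()
    if len(counts) < 2:
        return True
    return counts.iloc[0] / counts.iloc[1] > freq_ratio


def clean_matrix(
    X: DescriptorMatrix,
    max_missing_frac: float = 0.2,
    near_zero_var_freq_ratio: float = 19.0,
    pairwise_corr_cutoff: float = 0.95,
) -> tuple[DescriptorMatrix, CleaningReport]:
    """Filter unusable features, then impute what remains.

    Order of operations: (1) drop features with more than
    ``max_missing_frac`` missing cells; (2) drop constant and
    near-constant features (most-common / second-most-common frequency
    ratio above ``near_zero_var_freq_ratio``); (3) for each pair with
    \\|Pearson r\\| above ``pairwise_corr_cutoff``, drop the member with the
    larger mean absolute correlation to everything else (ties by name);
    (4) impute remaining missing cells with the feature median.

    Imputation statistics come from this matrix, which should be the
    training set; cleaning is deterministic and idempotent.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0,1]")
    if not 0 < pairwise_corr_cutoff <= 1:
        raise ValueError("pairwise_corr_cutoff must be in (0,1]")
    report = CleaningReport()
    df = X.data.copy()

    miss_frac = df.isna().mean()
    drop_missing = list(df.columns[miss_frac > max_missing_frac])
    report.dropped_missing = drop_missing
    df = df.drop(columns=drop_missing)

    drop_const = [c for c in df.columns if _near_zero_variance(df[c], near_zero_var_freq_ratio)]
    report.dropped_constant = drop_const
    df = df.drop(columns=drop_const)

    if df.shape[1] == 0:
        raise ValueError("all features dropped during cleaning")

    if df.shape[1] > 1:
        corr = df.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        mean_abs = corr.mean()
        to_drop: list[str] = []
        # caret-style greedy: repeatedly resolve the worst remaining pair
        while True:
            max_r = corr.values.max() if corr.size else 0.0
            if max_r <= pairwise_corr_cutoff:
                break
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            a, b = corr.index[i], corr.columns[j]
            # drop the feature with higher mean absolute correlation; keep
            # the one that is less redundant overall. Ties go to the later name.
            if (mean_abs[a], a) >= (mean_abs[b], b):
                victim, kept = a, b
            else:
                victim, kept = b, a
            to_drop.append(victim)
            report.dropped_correlated.append((victim, kept))
            corr = corr.drop(index=victim, columns=victim)
            mean_abs = mean_abs.drop(victim)
        df = df.drop(columns=to_drop)

    if df.shape[1] == 0:
        raise ValueError("all features dropped during cleaning")

    n_missing = int(df.isna().sum().sum())
    if n_missing:
        df = df.fillna(df.median())
        report.imputed_cells = n_missing
    return DescriptorMatrix(df), report


def standardize(
    X: DescriptorMatrix, reference: Optional[DescriptorMatrix] = None
) -> DescriptorMatrix:
    """Center/scale each feature to mean 0, sd 1.

    When ``reference`` is given (the training set), its statistics are
    used — the contract that keeps screening libraries in the training
    feature space and prevents test-set leakage.
    """
    src = reference if reference is not None else X
    if reference is not None:
        missing = set(X.feature_names) - set(reference.feature_names)
        if missing:
            raise ValueError(f"reference lacks features: {sorted(missing)}")
    if src.standardization is not None:
        stats = src.standardization.loc[X.feature_names]
    else:
        center = src.data[X.feature_names].mean()
        scale = src.data[X.feature_names].std(ddof=0)
        if (scale <= 0).any():
            bad = list(scale.index[scale <= 0])
            raise ValueError(f"zero-variance features at standardization: {bad}")
        stats = pd.DataFrame({"center": center, "scale": scale})
    out = (X.data - stats["center"]) / stats["scale"]
    return DescriptorMatrix(out, standardization=stats)


def destandardize(X: DescriptorMatrix) -> DescriptorMatrix:
    """Invert :func:`standardize` using the stored statistics."""
    if X.standardization is None:
        raise ValueError("matrix carries no standardization statistics")
    stats = X.standardization.loc[X.feature_names]
    return DescriptorMatrix(X.data * stats["scale"] + stats["center"])
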