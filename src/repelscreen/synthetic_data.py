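"""Synthetic study-data generators.

None of the study's inputs are redistributable (commercial descriptor
engines, a literature-curated training set, a copyrighted odor-percept
corpus, raw assay traces), so every downstream stage is exercised on
synthetic data with the statistical structure the analysis assumes:

* a chemicals × features descriptor matrix with a sparse planted set
  of informative features plus correlated nuisance features (emulating
  redundant descriptor families such as autocorrelation series);
* a % repellency response in [0, 100] driven linearly by the planted
  features with additive Gaussian noise;
* percept % usage matrices (146 odor-character descriptors, 0-100);
* Hill-curve luminescence dose-response replicates;
* binomial two-choice trap counts.

Every generator draws from its own counter-based substream of one
global integer seed, so adding a generator never perturbs the others,
and identical configuration gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior_stats import TrapTrial
from .chem_table import DescriptorMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "DoseResponse",
    "TrapTrial",
    "generate_descriptor_matrix",
    "generate_repellency_response",
    "generate_percept_usage",
    "generate_dose_response",
    "generate_trap_counts",
    "make_dataset",
    "noise_sd_for_r2",
    "planted_r2",
]

# fixed substream ids: one per generator
_STREAM_DESCRIPTORS = 0
_STREAM_RESPONSE = 1
_STREAM_PERCEPTS = 2
_STREAM_DOSE = 3
_STREAM_TRAPS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SyntheticConfig:
    """Parameters of the planted-signal descriptor/response generator.

    Defaults emulate the study geometry: 201 training chemicals, a few
    hundred numeric descriptors of which 18 carry the repellency
    signal, the rest pure nuisance partially collinear with the
    informative set, and a % repellency response on a 0-100 scale.
    """

    n_chemicals: int = 201
    n_features: int = 500
    n_informative: int = 18
    effect_sizes: Optional[Sequence[float]] = None
    nuisance_correlation: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    response_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.effect_sizes is None:
            self.effect_sizes = np.ones(self.n_informative)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError("effect_sizes length must equal n_informative")
        if not 0 <= self.nuisance_correlation < 1:
            raise ValueError("nuisance_correlation must be in [0,1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.response_range
        if not lo < hi:
            raise ValueError("response_range must be increasing")


@dataclass
class SyntheticDataset:
    descriptors: DescriptorMatrix
    response: np.ndarray
    informative_feature_ids: list[str]
    percepts: Optional[pd.DataFrame] = None
    labels: Optional[np.ndarray] = None
    truth: dict = field(default_factory=dict)


@dataclass
class DoseResponse:
    doses: np.ndarray  # (n_doses,)
    responses: np.ndarray  # (n_doses, n_replicates)
    truth: dict = field(default_factory=dict)


def _informative_names(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_features))
    return [f"F{i:0{width}d}" for i in range(config.n_informative)]


def generate_descriptor_matrix(config: SyntheticConfig) -> DescriptorMatrix:
    """Planted-signal descriptor matrix.

    The first ``n_informative`` columns are iid standard normal; each
    remaining (nuisance) column mixes one randomly chosen informative
    column with fresh noise so its population correlation with it is
    exactly ``nuisance_correlation``.  Feature names are stable, unique
    and zero-padded (F000, F001, ...); chemical ids likewise (C000...).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_DESCRIPTORS)
    n, p, k = config.n_chemicals, config.n_features, config.n_informative
    rho = config.nuisance_correlation
    informative = rng.standard_normal((n, k))
    n_nuis = p - k
    if n_nuis:
        partners = rng.integers(0, k, size=n_nuis)
        eps = rng.standard_normal((n, n_nuis))
        nuisance = rho * informative[:, partners] + np.sqrt(1 - rho**2) * eps
        values = np.hstack([informative, nuisance])
    else:
        values = informative
    wp = len(str(p))
    wn = len(str(n))
    feature_names = [f"F{i:0{wp}d}" for i in range(p)]
    chem_ids = [f"C{i:0{wn}d}" for i in range(n)]
    return DescriptorMatrix(pd.DataFrame(values, index=chem_ids, columns=feature_names))


def planted_r2(config: SyntheticConfig) -> float:
    """Closed-form latent R²: signal variance / total variance."""
    sig = float(np.sum(np.asarray(config.effect_sizes) ** 2))
    return sig / (sig + config.noise_sd**2)


def noise_sd_for_r2(effect_sizes: Sequence[float], r2: float) -> float:
    """Noise level giving a target latent R² for given effect sizes."""
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0,1]")
    sig = float(np.sqrt(np.sum(np.asarray(effect_sizes, dtype=float) ** 2)))
    return sig * np.sqrt((1 - r2) / r2)


def generate_repellency_response(
    X: DescriptorMatrix, config: SyntheticConfig
) -> np.ndarray:
    """% repellency driven by the planted features.

    latent = X_informative @ effect_sizes + N(0, noise_sd); the latent
    value is mapped affinely (mean of the latent distribution to the
    range midpoint, ±3 total sd to the range edges) and clipped into
    ``response_range``.  The affine map uses the theoretical moments,
    so it is monotone and sample-independent; clipping affects only the
    ~0.3% tail beyond 3 sd.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_RESPONSE)
    names = _informative_names(config)
    latent = X.data[names].to_numpy() @ np.asarray(config.effect_sizes)
    latent = latent + rng.standard_normal(len(latent)) * config.noise_sd
    sd_total = float(
        np.sqrt(np.sum(np.asarray(config.effect_sizes) ** 2) + config.noise_sd**2)
    )
    lo, hi = config.response_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    y = mid + half * latent / (3.0 * sd_total)
    return np.clip(y, lo, hi)


def generate_percept_usage(
    n_chemicals: int,
    n_descriptors: int = 146,
    sparsity: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """% usage matrix of odor-percept descriptors.

    ``sparsity`` is the fraction of zero entries (panelists use only a
    handful of the 146 descriptors per odorant); nonzero entries are
    drawn from a right-skewed Beta on the 0-100 scale.  Every
    descriptor column is guaranteed at least one nonzero entry, since
    thresholding is undefined on an all-zero column; sparsity=1 is
    therefore rejected.
    """
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0,1): all-zero columns are unusable")
    rng = _rng(seed, _STREAM_PERCEPTS)
    mask = rng.random((n_chemicals, n_descriptors)) >= sparsity
    # guarantee >= 1 nonzero per descriptor column
    empty = ~mask.any(axis=0)
    if empty.any():
        rows = rng.integers(0, n_chemicals, size=int(empty.sum()))
        mask[rows, np.flatnonzero(empty)] = True
    usage = np.zeros((n_chemicals, n_descriptors))
    usage[mask] = 100.0 * rng.beta(1.5, 4.0, size=int(mask.sum()))
    wd = len(str(n_descriptors))
    wn = len(str(n_chemicals))
    return pd.DataFrame(
        usage,
        index=[f"C{i:0{wn}d}" for i in range(n_chemicals)],
        columns=[f"D{i:0{wd}d}" for i in range(n_descriptors)],
    )


def generate_dose_response(
    ec50: float,
    hill: float,
    top: float,
    bottom: float,
    doses: Sequence[float],
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> DoseResponse:
    """Replicate luminescence responses around a four-parameter Hill curve.

    mean(dose) = bottom + (top - bottom) / (1 + (ec50/dose)**hill);
    replicates add iid Gaussian noise of sd ``replicate_sd``.
    """
    doses = np.asarray(doses, dtype=float)
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = _rng(seed, _STREAM_DOSE)
    mean = bottom + (top - bottom) / (1.0 + (ec50 / doses) ** hill)
    responses = mean[:, None] + rng.standard_normal((len(doses), n_replicates)) * replicate_sd
    return DoseResponse(
        doses=doses,
        responses=responses,
        truth={"ec50": ec50, "hill": hill, "top": top, "bottom": bottom},
    )


def generate_trap_counts(
    true_pi: float, n_insects: int = 20, n_trials: int = 10, seed: int = 0
) -> list[TrapTrial]:
    """Two-choice trap counts with a planted preference index.

    Per trial: treated ~ Binomial(n_insects, (1 + true_pi)/2) and
    control = n_insects - treated (full capture assumed: the preference
    index uses only trapped insects, so non-responders are out of
    model).
    """
    if not -1 <= true_pi <= 1:
        raise ValueError("true_pi must be in [-1,1]")
    rng = _rng(seed, _STREAM_TRAPS)
    p = (1.0 + true_pi) / 2.0
    treated = rng.binomial(n_insects, p, size=n_trials)
    return [
        TrapTrial(int(t), int(n_insects - t), n_released=n_insects) for t in treated
    ]


def make_dataset(
    config: SyntheticConfig,
    percept_sparsity: Optional[float] = None,
    percept_descriptors: int = 146,
    binary_top_fraction: Optional[float] = None,
) -> SyntheticDataset:
    """Full planted dataset: descriptors, response, optional extras.

    ``binary_top_fraction`` additionally produces binary active labels
    (top fraction of the response distribution), the mode used when the
    model is trained as a classifier rather than a regressor.
    """
    X = generate_descriptor_matrix(config)
    y = generate_repellency_response(X, config)
    percepts = None
    if percept_sparsity is not None:
        percepts = generate_percept_usage(
            config.n_chemicals,
            n_descriptors=percept_descriptors,
            sparsity=percept_sparsity,
            seed=config.seed,
        )
        percepts.index = X.chem_ids
    labels = None
    if binary_top_fraction is not None:
        from .evaluation import binarize_activity

        labels, _ = binarize_activity(y, top_fraction=binary_top_fraction)
    return SyntheticDataset(
        descriptors=X,
        response=y,
        informative_feature_ids=_informative_names(config),
        percepts=percepts,
        labels=labels,
        truth={
            "effect_sizes": list(map(float, config.effect_sizes)),
            "noise_sd": config.noise_sd,
            "nuisance_correlation": config.nuisance_correlation,
            "planted_r2": planted_r2(config),
            "seed": config.seed,
        },
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write descriptors/response as CSV and truth as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "descriptors": out / "descriptors.csv",
        "response": out / "response.csv",
        "truth": out / "truth.json",
    }
    dataset.descriptors.to_csv(paths["descriptors"])
    resp = pd.DataFrame(
        {"chem_id": dataset.descriptors.chem_ids, "repellency": dataset.response}
    )
    if dataset.labels is not None:
        resp["active"] = dataset.labels
    resp.to_csv(paths["response"], index=False)
    truth = dict(dataset.truth)
    truth["informative_feature_ids"] = dataset.informative_feature_ids
    paths["truth"].write_text(json.dumps(truth, indent=1))
    if dataset.percepts is not None:
        paths["percepts"] = out / "percepts.csv"
        dataset.percepts.to_csv(paths["percepts"], index_label="chem_id")
    return paths
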