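"""Behavioral and in-vitro summary statistics.

The wet-lab side of the screen produces three kinds of numbers, all
consumed here as plain counts/traces:

* two-choice fly trap assays → Preference Index
  PI = (treated - control) / (treated + control), in [-1, 1];
* one-choice mosquito landing assays → Repellency Coefficient
  RC = (mean cumulative landings on solvent control - mean cumulative
  landings on treated netting) / mean cumulative landings on solvent
  control, from cumulative counts at the 2, 3, 4, 5 minute timepoints
  (a trial's summary is the mean over those timepoints; a
  final-timepoint mode is available);
* aequorin luminescence dose-response traces → four-parameter Hill fits
  (EC50, Hill coefficient, top, bottom) and the thapsigargin
  store-depletion contrast.

Undefined statistics (0/0 cases) surface as explicit flags or errors,
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TrapTrial",
    "LandingSeries",
    "HillFit",
    "preference_index",
    "repellency_coefficient",
    "paired_solvent_check",
    "fit_hill",
    "hill_curve",
    "concentration_to_percent_vv",
    "store_depletion_contrast",
    "load_imagej_summary",
    "DEFAULT_TIMEPOINTS_MIN",
]

DEFAULT_TIMEPOINTS_MIN = (2.0, 3.0, 4.0, 5.0)


@dataclass
class TrapTrial:
    """Two-choice trap assay outcome: insects caught in each trap."""

    treated_count: int
    control_count: int
    n_released: Optional[int] = None

    def __post_init__(self) -> None:
        if self.treated_count < 0 or self.control_count < 0:
            raise ValueError("counts must be >= 0")
        if (
            self.n_released is not None
            and self.treated_count + self.control_count > self.n_released
        ):
            raise ValueError("trapped insects exceed number released")


@dataclass
class LandingSeries:
    """Cumulative landing counts over time for one trial/condition."""

    timepoints_min: Sequence[float]
    cumulative_counts: Sequence[float]
    condition: str = "treatment"  # {"solvent", "treatment"}
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        c = np.asarray(self.cumulative_counts, dtype=float)
        if len(t) != len(c):
            raise ValueError("timepoints and counts differ in length")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative counts must be non-decreasing in time")
        self.timepoints_min = t
        self.cumulative_counts = c

    def summary(self, timepoints: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
                mode: str = "mean") -> float:
        """Trial summary over the stated timepoints (mean or final)."""
        t = np.asarray(timepoints, dtype=float)
        idx = []
        for tp in t:
            hits = np.flatnonzero(np.isclose(self.timepoints_min, tp))
            if len(hits) == 0:
                raise ValueError(f"trial lacks timepoint {tp} min")
            idx.append(hits[0])
        counts = self.cumulative_counts[idx]
        if mode == "mean":
            return float(counts.mean())
        if mode == "final":
            return float(counts[-1])
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class HillFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    residual_ss: float
    converged: bool
    degenerate: bool = False


def preference_index(trial: TrapTrial) -> float:
    """PI = (treated - control) / (treated + control), in [-1, 1].

    Both traps empty leaves the index undefined — an error, not 0.
    """
    total = trial.treated_count + trial.control_count
    if total == 0:
        raise ValueError("preference index undefined: both trap counts are zero")
    return (trial.treated_count - trial.control_count) / total


def repellency_coefficient(
    solvent: Sequence[LandingSeries],
    treated: Sequence[LandingSeries],
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
    mode: str = "mean",
) -> float:
    """RC = (solvent mean - treated mean) / solvent mean.

    Each trial contributes the mean of its cumulative counts over the
    2-5 minute timepoints; trial summaries are averaged per condition.
    RC <= 1, with 1 reached only when no mosquito lands on the treated
    netting; a negative value (attraction) is permitted.  A zero
    solvent mean leaves the coefficient undefined (error).
    """
    if not solvent or not treated:
        raise ValueError("both conditions need at least one trial")
    mean_solvent = float(np.mean([s.summary(timepoints, mode) for s in solvent]))
    mean_treated = float(np.mean([s.summary(timepoints, mode) for s in treated]))
    if mean_solvent == 0:
        raise ValueError("repellency coefficient undefined: solvent mean is zero")
    return (mean_solvent - mean_treated) / mean_solvent


def paired_solvent_check(
    before: LandingSeries,
    after: LandingSeries,
    tolerance: float = 0.5,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
) -> bool:
    """Solvent-control consistency gate for the one-choice assay.

    A solvent-alone control is run before and after the test material;
    a relative change in the mean cumulative count beyond ``tolerance``
    flags the cage's behavior as unacceptable.  Returns True when ok.
    """
    b = before.summary(timepoints)
    a = after.summary(timepoints)
    denom = max(abs(b), abs(a))
    if denom == 0:
        return True  # no landings either time: nothing changed
    return abs(a - b) / denom <= tolerance


# ---------------------------------------------------------------------------
# Hill / EC50 fitting
# ---------------------------------------------------------------------------


def hill_curve(dose, ec50, hill, top, bottom):
    """Four-parameter logistic: bottom + (top-bottom)/(1+(ec50/dose)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def _hill_log(dose, log_ec50, hill, top, bottom):
    # fit in log-EC50 space: keeps EC50 positive and conditions the problem
    return hill_curve(dose, np.exp(log_ec50), hill, top, bottom)


def fit_hill(
    doses: Sequence[float],
    responses,
    fix_bottom: Optional[float] = None,
) -> HillFit:
    """Nonlinear least-squares four-parameter Hill fit.

    ``responses`` is a replicate matrix (n_doses × n_replicates) or a
    flat vector matching ``doses``.  Initialization is multi-start from
    the data quartiles (EC50 candidates at the dose quartiles, several
    slopes, asymptotes from the response extremes); the best converged
    start by residual sum of squares wins.  ``fix_bottom`` pins the
    lower asymptote (three-parameter mode).  A flat response yields a
    degenerate flag (top == bottom), never a spurious EC50.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    resp = np.asarray(responses, dtype=float)
    if resp.ndim == 2:
        x = np.repeat(doses, resp.shape[1])
        y = resp.ravel()
    else:
        if len(resp) != len(doses):
            raise ValueError("response vector length must match doses")
        x, y = doses, resp

    span = float(y.max() - y.min())
    if span == 0:
        return HillFit(
            ec50=float("nan"), hill=0.0, top=float(y[0]), bottom=float(y[0]),
            residual_ss=0.0, converged=True, degenerate=True,
        )

    log_d = np.log(doses)
    ec50_starts = np.exp(np.quantile(log_d, [0.25, 0.5, 0.75]))
    hill_starts = (0.5, 1.0, 2.0, 4.0, -1.0)
    top0, bot0 = float(y.max()), float(y.min())

    best = None
    for e0 in ec50_starts:
        for h0 in hill_starts:
            try:
                if fix_bottom is None:
                    p0 = [np.log(e0), h0, top0, bot0]
                    popt, _ = curve_fit(_hill_log, x, y, p0=p0, maxfev=10000)
                    log_e, h, top, bottom = popt
                else:
                    def model(dose, log_ec50, hill, top):
                        return _hill_log(dose, log_ec50, hill, top, fix_bottom)

                    p0 = [np.log(e0), h0, top0]
                    popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10000)
                    log_e, h, top = popt
                    bottom = fix_bottom
            except RuntimeError:
                continue
            ss = float(np.sum((y - hill_curve(x, np.exp(log_e), h, top, bottom)) ** 2))
            if best is None or ss < best[0]:
                best = (ss, np.exp(log_e), h, top, bottom)
    if best is None:
        raise RuntimeError(
            "Hill fit failed to converge from any start "
            f"(doses {doses.min():g}-{doses.max():g}, span {span:g})"
        )
    ss, ec50, hill, top, bottom = best
    if top < bottom:
        # canonical orientation: top >= bottom, mirrored by the slope sign
        top, bottom, hill = bottom, top, -hill
    return HillFit(
        ec50=float(ec50), hill=float(hill), top=float(top), bottom=float(bottom),
        residual_ss=ss, converged=True,
    )


def concentration_to_percent_vv(
    conc_mM: float, molar_mass: float, density: float
) -> float:
    """Millimolar concentration → % volume/volume.

    (conc_mM mmol/L × molar_mass g/mol → mg solute per L; divided by
    density mg/mL → mL solute per L; ×100/1000 → mL per 100 mL.)
    For DEET (molar mass 191.3 g/mol, density 0.998 g/mL) 56.6 mM is
    about 1% v/v.
    """
    if molar_mass <= 0 or density <= 0:
        raise ValueError("molar mass and density must be > 0")
    return conc_mM * molar_mass / (1e6 * density) * 100.0


def store_depletion_contrast(
    control_transients,
    depleted_transients,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Contrast Ca²⁺ transients with vs without store depletion.

    Inputs map stimulus concentration → replicate peak responses for
    untreated cells and for cells pre-treated with a SERCA antagonist
    (thapsigargin) that empties intracellular stores.  Returns, per
    matched concentration, the mean difference (control - depleted),
    the ratio of mean peaks (depleted / control), and a percentile
    bootstrap 95% interval on the difference.
    """
    shared = sorted(set(control_transients) & set(depleted_transients))
    if not shared:
        raise ValueError("no matched stimulus concentrations")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in shared:
        c = np.asarray(control_transients[conc], dtype=float)
        d = np.asarray(depleted_transients[conc], dtype=float)
        diff = float(c.mean() - d.mean())
        ratio = float(d.mean() / c.mean()) if c.mean() != 0 else float("nan")
        boot = np.empty(n_boot)
        for b in range(n_boot):
            boot[b] = (
                rng.choice(c, size=len(c)).mean() - rng.choice(d, size=len(d)).mean()
            )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            {
                "concentration": conc,
                "mean_difference": diff,
                "peak_ratio": ratio,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows).set_index("concentration")


def load_imagej_summary(
    path,
    frame_interval_min: float,
    condition: str = "treatment",
    trial_id: Optional[str] = None,
    count_column: str = "Count",
) -> LandingSeries:
    """Read a particle-counting summary CSV into a LandingSeries.

    The automated counting step tabulates per-frame particle counts
    (one row per frame, a ``Count`` column); frame index times
    ``frame_interval_min`` gives the timepoint.  Counts are running
    maxima of the per-frame counts, making the series cumulative
    (an insect that landed stays counted).
    """
    df = pd.read_csv(path)
    if count_column not in df.columns:
        raise ValueError(f"{path}: no {count_column!r} column")
    counts = df[count_column].to_numpy(dtype=float)
    cumulative = np.maximum.accumulate(counts)
    times = (np.arange(len(counts)) + 1) * frame_interval_min
    return LandingSeries(
        timepoints_min=times,
        cumulative_counts=cumulative,
        condition=condition,
        trial_id=trial_id,
    )
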