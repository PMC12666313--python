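"""Dose-response metrics for organoid drug screens.

Two readouts are computed per concentration from end-point fluorescence:

* viability — treated signal relative to the vehicle negative controls,
* GR value — growth-rate inhibition, ``GR = 2**(log2(x/x0)/log2(x_ctrl/x0)) - 1``,
  which normalizes the drug effect to the untreated growth rate.  GR spans
  1 (no effect) through 0 (complete cytostasis) to -1 (complete kill).

Curves are summarized without sigmoid fitting: the area under the raw curve
over the log10-concentration range (AUC / GR_AUC, rescaled so a constant
curve maps to its own value) and the first half-maximal crossing (IC50 /
GR50, by log-linear interpolation).  Summary metrics are min-max normalized
per drug across a cohort so that differently dosed regimens share a [0, 1]
scale, and a screen is called *sensitive* when the normalized GR_AUC falls
strictly below the configured cutoff (default 0.63).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateControlError,
    DegenerateRangeError,
    DomainError,
    GridError,
    InsufficientDataError,
    NoGrowthError,
)
from .plate_model import ScreenConfig, WellRecord

logger = logging.getLogger(__name__)

#: multipliers used to encode censored half-max concentrations
RIGHT_CENSOR_FACTOR = 10.0
LEFT_CENSOR_FACTOR = 0.1

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class DoseResponseCurve:
    """Replicate-aggregated viability and GR values on one drug's grid."""

    pdo_id: str
    drug: str
    concentrations: np.ndarray
    viability: np.ndarray
    gr: np.ndarray
    n_replicates_aggregated: int

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.gr = np.asarray(self.gr, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise GridError("concentrations must be strictly increasing")
        if not len(self.concentrations) == len(self.viability) == len(self.gr):
            raise GridError("curve arrays must share a length")


@dataclass
class SensitivityMetrics:
    """Per PDO x drug summary of the dose-response curve.

    ``gr50``/``ic50`` carry censoring flags: 'none' for an observed crossing,
    'right' when the curve never reaches the half-max level (sentinel
    10 * c_max), 'left' when it is already below at the lowest dose
    (sentinel c_min / 10).  Normalized fields are filled in cohort context by
    :func:`normalize_metrics`.
    """

    pdo_id: str
    drug: str
    gr_auc: float
    auc: float
    gr50: float
    ic50: float
    gr50_censoring: str = "none"
    ic50_censoring: str = "none"
    norm_gr_auc: float | None = None
    norm_auc: float | None = None
    norm_gr50: float | None = None
    norm_ic50: float | None = None
    sensitivity_class: str | None = None


def normalize_viability(treated: Sequence[float], neg_ctrl: Sequence[float]) -> float:
    """Mean treated intensity over mean negative-control intensity."""
    treated = np.asarray(treated, dtype=float)
    neg_ctrl = np.asarray(neg_ctrl, dtype=float)
    if treated.size == 0 or neg_ctrl.size == 0:
        raise InsufficientDataError("need at least one treated and one control intensity")
    ctrl_mean = neg_ctrl.mean()
    if ctrl_mean <= 0:
        raise DegenerateControlError(f"non-positive control mean {ctrl_mean}")
    return float(treated.mean() / ctrl_mean)


def compute_gr(x_c: float, x0: float, x_ctrl: float) -> float:
    """Growth-rate inhibition value for one treated signal.

    x_c is the treated day-5 signal, x0 the day-0 baseline and x_ctrl the
    untreated day-5 signal. Requires growing controls (x_ctrl > x0).
    """
    if x0 <= 0 or x_c <= 0:
        raise DomainError(f"signals must be positive (x_c={x_c}, x0={x0})")
    if x_ctrl <= x0:
        raise NoGrowthError(f"negative controls did not grow (x_ctrl={x_ctrl} <= x0={x0})")
    return float(2.0 ** (math.log2(x_c / x0) / math.log2(x_ctrl / x0)) - 1.0)


def curve_area(values: Sequence[float], concentrations: Sequence[float]) -> float:
    """Trapezoidal area under the raw curve in log10-concentration space,
    rescaled by the log-range so a constant curve returns its own value."""
    values = np.asarray(values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need at least two curve points")
    if values.size != conc.size:
        raise GridError("values and concentrations must share a length")
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise GridError("concentrations must be positive and strictly increasing")
    logc = np.log10(conc)
    return float(np.trapezoid(values, logc) / (logc[-1] - logc[0]))


def half_max_concentration(
    values: Sequence[float],
    concentrations: Sequence[float],
    level: float = 0.5,
) -> tuple[float, str]:
    """First crossing of `level`, scanning low to high concentration.

    Interpolates linearly in (log10 c, value) space on the nonfitted curve.
    Returns (concentration, censoring) where censoring is 'none', 'right'
    (curve never reaches the level; sentinel 10 * c_max) or 'left' (already
    below the level at c_min; sentinel c_min / 10).
    """
    values = np.asarray(values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need at least two curve points")
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise GridError("concentrations must be positive and strictly increasing")
    if values[0] < level:
        return float(conc[0] * LEFT_CENSOR_FACTOR), "left"
    logc = np.log10(conc)
    for i in range(values.size):
        if values[i] <= level:
            if values[i] == level or i == 0:
                return float(conc[i]), "none"
            frac = (values[i - 1] - level) / (values[i - 1] - values[i])
            return float(10.0 ** (logc[i - 1] + frac * (logc[i] - logc[i - 1]))), "none"
    return float(conc[-1] * RIGHT_CENSOR_FACTOR), "right"


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Map values to [0, 1] by the cohort minimum and maximum."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need at least two values to normalize")
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise DegenerateRangeError("all values equal; min-max normalization undefined")
    return (values - lo) / (hi - lo)


def classify_sensitivity(norm_gr_auc: float, cutoff: float = 0.63) -> str:
    """Sensitive iff the normalized GR_AUC is strictly below the cutoff."""
    if not 0.0 <= norm_gr_auc <= 1.0:
        raise DomainError(f"normalized GR_AUC {norm_gr_auc} outside [0, 1]")
    return SENSITIVE if norm_gr_auc < cutoff else RESISTANT


def _mean_intensity(wells: list[WellRecord]) -> float:
    return float(np.mean([w.intensity for w in wells]))


def build_curves(
    wells: Sequence[WellRecord],
    cfg: ScreenConfig,
    pdo_id: str,
    included_bio_reps: dict[str, set[int]] | None = None,
) -> list[DoseResponseCurve]:
    """Aggregate wells of one PDO screen into per-drug dose-response curves.

    Technical replicates are averaged per concentration within each
    biological replicate; the per-replicate viability and GR curves are then
    averaged without weighting.  `included_bio_reps` optionally restricts
    aggregation per drug to QC-passed biological replicates.
    """
    baseline = [w for w in wells if w.role == "baseline"]
    if not baseline:
        raise InsufficientDataError(f"{pdo_id}: no day-0 baseline wells")
    x0 = _mean_intensity(baseline)

    day5 = [w for w in wells if w.timepoint != 0]
    curves: list[DoseResponseCurve] = []
    for drug in cfg.drugs:
        dw = [w for w in day5 if w.role == "treated" and w.drug == drug]
        if not dw:
            logger.warning("%s: no wells for drug %s; skipping", pdo_id, drug)
            continue
        grid = cfg.concentration_grids[drug]
        bio_reps = sorted({w.bio_rep for w in dw})
        if included_bio_reps is not None and drug in included_bio_reps:
            bio_reps = [b for b in bio_reps if b in included_bio_reps[drug]]
            if not bio_reps:
                logger.warning("%s: all biological replicates excluded for %s", pdo_id, drug)
                continue
        via_reps, gr_reps = [], []
        for bio in bio_reps:
            neg = [
                w for w in day5 if w.role == "negative_control" and w.bio_rep == bio
            ]
            if not neg:
                raise InsufficientDataError(
                    f"{pdo_id}: no negative controls for bio_rep {bio}"
                )
            x_ctrl = _mean_intensity(neg)
            via, gr = [], []
            for c in grid:
                cw = [
                    w
                    for w in dw
                    if w.bio_rep == bio and np.isclose(w.concentration, c, rtol=1e-9, atol=0.0)
                ]
                if not cw:
                    raise InsufficientDataError(
                        f"{pdo_id}: {drug} bio_rep {bio} missing concentration {c}"
                    )
                x_c = _mean_intensity(cw)
                via.append(x_c / x_ctrl)
                gr.append(compute_gr(x_c, x0, x_ctrl))
            via_reps.append(via)
            gr_reps.append(gr)
        curves.append(
            DoseResponseCurve(
                pdo_id=pdo_id,
                drug=drug,
                concentrations=grid,
                viability=np.mean(via_reps, axis=0),
                gr=np.mean(gr_reps, axis=0),
                n_replicates_aggregated=len(bio_reps),
            )
        )
    return curves


def summarize_curve(curve: DoseResponseCurve) -> SensitivityMetrics:
    """Raw (un-normalized) summary metrics for one dose-response curve."""
    gr50, gr50_cens = half_max_concentration(curve.gr, curve.concentrations)
    ic50, ic50_cens = half_max_concentration(curve.viability, curve.concentrations)
    return SensitivityMetrics(
        pdo_id=curve.pdo_id,
        drug=curve.drug,
        gr_auc=curve_area(curve.gr, curve.concentrations),
        auc=curve_area(curve.viability, curve.concentrations),
        gr50=gr50,
        ic50=ic50,
        gr50_censoring=gr50_cens,
        ic50_censoring=ic50_cens,
    )


def score_screen(
    wells: Sequence[WellRecord],
    cfg: ScreenConfig,
    pdo_id: str,
    included_bio_reps: dict[str, set[int]] | None = None,
) -> list[SensitivityMetrics]:
    """Raw sensitivity metrics for every screened drug of one PDO.

    Normalized fields stay unset; fill them with :func:`normalize_metrics`
    once the whole cohort is scored.
    """
    return [
        summarize_curve(c)
        for c in build_curves(wells, cfg, pdo_id, included_bio_reps=included_bio_reps)
    ]


def normalize_metrics(
    metrics: Sequence[SensitivityMetrics], cfg: ScreenConfig
) -> list[SensitivityMetrics]:
    """Min-max normalize each metric per drug across the cohort and classify.

    Censored GR50/IC50 enter normalization at their sentinel values, keeping
    the transform total. Returns new SensitivityMetrics objects.
    """
    out: list[SensitivityMetrics] = []
    by_drug: dict[str, list[SensitivityMetrics]] = {}
    for m in metrics:
        by_drug.setdefault(m.drug, []).append(m)
    for drug, group in by_drug.items():
        fields = {
            "norm_gr_auc": [m.gr_auc for m in group],
            "norm_auc": [m.auc for m in group],
            "norm_gr50": [m.gr50 for m in group],
            "norm_ic50": [m.ic50 for m in group],
        }
        normed: dict[str, np.ndarray] = {}
        for name, vals in fields.items():
            try:
                normed[name] = minmax_normalize(vals)
            except (DegenerateRangeError, InsufficientDataError):
                logger.warning("%s: %s has degenerate range; left unnormalized", drug, name)
                normed[name] = np.full(len(vals), np.nan)
        for i, m in enumerate(group):
            norm_gr_auc = float(normed["norm_gr_auc"][i])
            out.append(
                replace(
                    m,
                    norm_gr_auc=norm_gr_auc,
                    norm_auc=float(normed["norm_auc"][i]),
                    norm_gr50=float(normed["norm_gr50"][i]),
                    norm_ic50=float(normed["norm_ic50"][i]),
                    sensitivity_class=(
                        classify_sensitivity(norm_gr_auc, cfg.sensitivity_cutoff)
                        if np.isfinite(norm_gr_auc)
                        else None
                    ),
                )
            )
    return out
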