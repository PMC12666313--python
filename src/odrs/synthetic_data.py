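"""Synthetic screens, cohorts and outcomes with the structure the pipeline assumes.

The generator emulates a 384-well organoid screening campaign: per drug a
10-point logarithmic concentration range in technical triplicate, vehicle
negative controls, staurosporine positive controls (GR -0.9), a separate
day-0 baseline plate, and biological duplicates on separate plates.  The
drug effect follows a Hill curve on the GR scale,

    GR_true(c) = e_inf + (1 - e_inf) / (1 + (c / ec50)**hill),

and intensities follow exponential growth: untreated wells complete
``growth`` doublings over the 5-day assay, treated wells grow at the
GR-implied relative rate, so that the analysis-side GR computation recovers
GR_true exactly in the absence of noise.  Noise is multiplicative
log-normal at a configurable coefficient of variation (default 0.08).

Cohort-level outputs couple a latent per-patient sensitivity s — the
analytic normalized GR_AUC of the focal regimen — to lesion percent change
(linear link plus Gaussian noise) and to PFS/OS (exponential
proportional-hazards with a configurable log hazard ratio per 0.1 units of
s, independent exponential censoring).  Establishment cohorts draw
covariates from fixed marginal frequencies and success from a logistic
model.

One global seed expands into per-component substreams via
``numpy.random.SeedSequence.spawn`` (order: plates, clinical, survival,
establishment), so partial re-runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_model import ScreenConfig, WellRecord
from .response_metrics import curve_area

FOCAL_REGIMEN = "5-FU+oxaliplatin"

#: staurosporine positive-control GR value
POSITIVE_CONTROL_GR = -0.9

N_CONTROL_WELLS = 16
BASE_INTENSITY = 1000.0

_ROWS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class HillParams:
    """Hill curve on the GR scale for one PDO x drug."""

    e_inf: float  # floor GR value
    ec50: float  # µM
    hill: float  # slope

    def __post_init__(self) -> None:
        if not -1.0 < self.e_inf <= 1.0:
            raise ValidationError("e_inf must lie in (-1, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValidationError("ec50 and hill must be positive")

    def gr(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.e_inf + (1.0 - self.e_inf) / (1.0 + (conc / self.ec50) ** self.hill)


@dataclass
class DrugResponseTruth:
    """Ground-truth response of one PDO line across the panel."""

    pdo_id: str
    growth: float  # doublings of untreated cells over the assay
    params: dict[str, HillParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.growth <= 0:
            raise ValidationError("growth must be positive")

    def analytic_gr_auc(self, drug: str, grid: Sequence[float]) -> float:
        """GR_AUC of the noise-free truth curve on the screening grid."""
        return curve_area(self.params[drug].gr(grid), grid)


@dataclass
class CohortTruth:
    """Latent links between sensitivity and clinical outcome."""

    response_intercept: float = -45.0  # % change at s = 0
    response_slope: float = 80.0  # % change per unit s
    response_sd: float = 35.0  # lesion-level noise, % points
    log_hr_pfs_per_0p1: float = math.log(1.35)
    log_hr_os_per_0p1: float = math.log(1.27)
    median_pfs_at_mid: float = 8.0  # months, at s = 0.5
    median_os_at_mid: float = 24.0
    censor_mean_months: float = 60.0

    def __post_init__(self) -> None:
        if self.response_sd < 0 or self.censor_mean_months <= 0:
            raise ValidationError("noise scales must be positive")


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in _ROWS for c in range(1, 25)]


def _noisy(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean; exact at cv = 0."""
    values = np.asarray(values, dtype=float)
    if cv == 0:
        return values.copy()
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return values * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=values.shape)


def _growth_signal(x0: float, gr: float, growth: float) -> float:
    """Day-5 intensity of cells with GR value `gr`: the exact inverse of the
    GR formula, x = x0 * 2**(log2(1 + gr) * growth)."""
    return x0 * 2.0 ** (math.log2(1.0 + gr) * growth)


def random_truth(pdo_id: str, cfg: ScreenConfig, rng: np.random.Generator) -> DrugResponseTruth:
    """Draw plausible Hill parameters for every drug of the panel."""
    params = {}
    for drug in cfg.drugs:
        grid = cfg.concentration_grids[drug]
        lo, hi = math.log10(grid[0]), math.log10(grid[-1])
        params[drug] = HillParams(
            e_inf=float(rng.uniform(-0.6, 0.4)),
            ec50=float(10 ** rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))),
            hill=float(rng.uniform(0.8, 3.0)),
        )
    return DrugResponseTruth(pdo_id=pdo_id, growth=float(rng.uniform(1.5, 3.0)), params=params)


def generate_plate_set(
    truth: DrugResponseTruth,
    cfg: ScreenConfig,
    noise_cv: float = 0.08,
    seed: int | np.random.Generator = 0,
) -> list[WellRecord]:
    """Day-0 baseline plate plus one day-5 plate per biological replicate."""
    if noise_cv < 0:
        raise ValidationError("noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wells: list[WellRecord] = []
    names = _well_names()

    # day-0 baseline plate
    base = _noisy(rng, np.full(N_CONTROL_WELLS, BASE_INTENSITY), noise_cv)
    for i in range(N_CONTROL_WELLS):
        wells.append(
            WellRecord(
                plate_id=f"{truth.pdo_id}-D0",
                well=names[i],
                role="baseline",
                drug="",
                concentration=0.0,
                tech_rep=i % cfg.n_technical + 1,
                bio_rep=1,
                timepoint=0,
                intensity=float(base[i]),
            )
        )

    x_ctrl = _growth_signal(BASE_INTENSITY, 1.0, truth.growth)
    x_pos = _growth_signal(BASE_INTENSITY, POSITIVE_CONTROL_GR, truth.growth)
    for bio in range(1, cfg.n_biological + 1):
        plate_id = f"{truth.pdo_id}-B{bio}"
        pos = 0
        for drug in cfg.drugs:
            grid = cfg.concentration_grids[drug]
            gr_curve = truth.params[drug].gr(grid)
            for c, gr in zip(grid, gr_curve):
                x_c = _growth_signal(BASE_INTENSITY, float(gr), truth.growth)
                sig = _noisy(rng, np.full(cfg.n_technical, x_c), noise_cv)
                for tech in range(1, cfg.n_technical + 1):
                    wells.append(
                        WellRecord(
                            plate_id=plate_id,
                            well=names[pos],
                            role="treated",
                            drug=drug,
                            concentration=float(c),
                            tech_rep=tech,
                            bio_rep=bio,
                            timepoint=5,
                            intensity=float(sig[tech - 1]),
                        )
                    )
                    pos += 1
        neg = _noisy(rng, np.full(N_CONTROL_WELLS, x_ctrl), noise_cv)
        posc = _noisy(rng, np.full(N_CONTROL_WELLS, x_pos), noise_cv)
        for role, sig in (("negative_control", neg), ("positive_control", posc)):
            for i in range(N_CONTROL_WELLS):
                wells.append(
                    WellRecord(
                        plate_id=plate_id,
                        well=names[pos],
                        role=role,
                        drug="",
                        concentration=0.0,
                        tech_rep=i % cfg.n_technical + 1,
                        bio_rep=bio,
                        timepoint=5,
                        intensity=float(sig[i]),
                    )
                )
                pos += 1
    return wells


def _lesion_rows(
    patient_id: str, best_change: dict[str, float], rng: np.random.Generator
) -> list[dict]:
    """Serial diameters for one biopsied lesion and two extra target lesions.

    The best (minimum) percent change over follow-ups equals the intended
    value by construction: shrinking lesions pass through a halfway scan
    before reaching it, growing lesions grow monotonically to it.
    """
    rows = []
    for lesion, change in best_change.items():
        baseline = float(rng.uniform(15.0, 60.0))
        first = change / 2.0 if change < 0 else change
        trajectory = {0: baseline, 1: baseline * (1 + first / 100.0), 2: baseline * (1 + change / 100.0)}
        for t, diam in trajectory.items():
            rows.append(
                {
                    "patient_id": patient_id,
                    "lesion_id": f"{patient_id}-{lesion}",
                    "is_biopsied": int(lesion == "L1"),
                    "is_target": 1,
                    "timepoint": t,
                    "diameter_mm": max(float(diam), 0.0),
                    "new_lesions": 0,
                }
            )
    return rows


def generate_screen_cohort(
    n_pdos: int,
    cohort_truth: CohortTruth | None = None,
    cfg: ScreenConfig | None = None,
    noise_cv: float = 0.08,
    seed: int = 0,
) -> dict:
    """Full synthetic study: plates per PDO, clinical lesion table, PFS/OS
    tables, and the ground-truth record needed for recovery tests.

    The latent sensitivity s of a patient is the analytic normalized GR_AUC
    of the focal fluoropyrimidine + oxaliplatin regimen, min-max scaled
    across the cohort.
    """
    if n_pdos < 5:
        raise ValidationError("need at least five PDOs for a cohort")
    cohort_truth = cohort_truth or CohortTruth()
    cfg = cfg or ScreenConfig()
    ss = np.random.SeedSequence(seed)
    rng_plates, rng_clin, rng_surv, _ = [np.random.default_rng(s) for s in ss.spawn(4)]

    pdo_ids = [f"PDO{i + 1:03d}" for i in range(n_pdos)]
    truths = {p: random_truth(p, cfg, rng_plates) for p in pdo_ids}
    plates = {
        p: generate_plate_set(truths[p], cfg, noise_cv=noise_cv, seed=rng_plates)
        for p in pdo_ids
    }

    grid = cfg.concentration_grids[FOCAL_REGIMEN]
    raw_auc = np.array([truths[p].analytic_gr_auc(FOCAL_REGIMEN, grid) for p in pdo_ids])
    s = (raw_auc - raw_auc.min()) / (raw_auc.max() - raw_auc.min())

    clin_rows: list[dict] = []
    surv_rows: list[dict] = []
    for i, p in enumerate(pdo_ids):
        mean_change = cohort_truth.response_intercept + cohort_truth.response_slope * s[i]
        changes = {
            "L1": float(mean_change + rng_clin.normal(0, cohort_truth.response_sd)),
            "L2": float(mean_change + rng_clin.normal(0, cohort_truth.response_sd)),
            "L3": float(mean_change + rng_clin.normal(0, cohort_truth.response_sd)),
        }
        changes = {k: max(v, -100.0) for k, v in changes.items()}
        clin_rows.extend(_lesion_rows(p, changes, rng_clin))

        for endpoint, log_hr, med in (
            ("pfs", cohort_truth.log_hr_pfs_per_0p1, cohort_truth.median_pfs_at_mid),
            ("os", cohort_truth.log_hr_os_per_0p1, cohort_truth.median_os_at_mid),
        ):
            lam0 = math.log(2.0) / med / math.exp(log_hr * 0.5 / 0.1)
            lam = lam0 * math.exp(log_hr * s[i] / 0.1)
            t_event = rng_surv.exponential(1.0 / lam)
            t_cens = rng_surv.exponential(cohort_truth.censor_mean_months)
            surv_rows.append(
                {
                    "patient_id": p,
                    "endpoint": endpoint,
                    "time_months": float(max(min(t_event, t_cens), 1e-3)),
                    "event": int(t_event <= t_cens),
                    "true_s": float(s[i]),
                }
            )

    return {
        "pdo_ids": pdo_ids,
        "truths": truths,
        "plates": plates,
        "clinical": pd.DataFrame(clin_rows),
        "survival": pd.DataFrame(surv_rows),
        "latent_sensitivity": dict(zip(pdo_ids, s.astype(float))),
        "analytic_gr_auc": dict(zip(pdo_ids, raw_auc.astype(float))),
        "cohort_truth": cohort_truth,
    }


DEFAULT_ESTABLISHMENT_COEFS = {
    "intercept": -2.1,
    "male": 0.8,
    "ldh_elevated": 0.9,
    "academic": 0.8,
    "period_P2": 0.8,
    "period_P3": 1.6,
}

#: knots (days from first study biopsy) separating culture-protocol periods
DEFAULT_PERIOD_KNOTS = (600.0, 1200.0)


def generate_establishment_cohort(
    n: int,
    coefficients: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table for the establishment model, success via a logistic link.

    Covariates are drawn from fixed marginal frequencies typical of a
    metastatic colorectal cancer cohort; only the terms present in
    `coefficients` influence success.
    """
    if n < 50:
        raise ValidationError("need n >= 50 for a usable establishment cohort")
    coefs = dict(DEFAULT_ESTABLISHMENT_COEFS if coefficients is None else coefficients)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])

    sex = rng.choice(["male", "female"], size=n, p=[0.6, 0.4])
    ldh = rng.random(n) < 0.45
    hospital = rng.choice(["academic", "nonacademic"], size=n, p=[0.5, 0.5])
    biopsy_day = rng.uniform(0.0, 1800.0, size=n)
    period = np.select(
        [biopsy_day < DEFAULT_PERIOD_KNOTS[0], biopsy_day < DEFAULT_PERIOD_KNOTS[1]],
        ["P1", "P2"],
        default="P3",
    )
    eta = (
        coefs.get("intercept", 0.0)
        + coefs.get("male", 0.0) * (sex == "male")
        + coefs.get("ldh_elevated", 0.0) * ldh
        + coefs.get("academic", 0.0) * (hospital == "academic")
        + coefs.get("period_P2", 0.0) * (period == "P2")
        + coefs.get("period_P3", 0.0) * (period == "P3")
    )
    success = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "success": success.astype(int),
            "age": np.round(rng.normal(63.0, 10.0, size=n), 1),
            "sex": sex,
            "location": rng.choice(["rectum", "left", "right"], size=n, p=[0.45, 0.3, 0.25]),
            "differentiation": rng.choice(
                ["good", "poor", "unknown"], size=n, p=[0.6, 0.2, 0.2]
            ),
            "time_to_metastases": rng.choice(
                ["synchronous", "metachronous"], size=n, p=[0.6, 0.4]
            ),
            "ldh_elevated": ldh.astype(int),
            "prior_treatment": rng.choice(
                ["none", "adjuvant", "palliative"], size=n, p=[0.3, 0.2, 0.5]
            ),
            "mutation": rng.choice(["KRAS", "BRAF", "WT"], size=n, p=[0.45, 0.12, 0.43]),
            "biopsy_day": np.round(biopsy_day, 1),
            "hospital": hospital,
        }
    )
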