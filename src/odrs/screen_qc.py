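"""Quality gates for plate-based drug screens.

Two gates are applied before any dose-response aggregation:

* the Z'-factor of each assay plate, ``1 - 3*(sd_pos + sd_neg)/|mean_pos -
  mean_neg|``; plates below 0.3 are excluded, and
* concordance of biological replicates, measured by summing the absolute
  GR difference over all concentrations of a drug curve; pairs whose sum
  exceeds 1.7 are flagged for re-run and excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import GridError, InsufficientDataError, UndefinedTestError
from .plate_model import ScreenConfig, WellRecord
from .response_metrics import compute_gr

INCLUDE = "include"
EXCLUDE_PLATE = "exclude_plate"
RERUN_REPLICATES = "rerun_replicates"


@dataclass(frozen=True)
class QCReport:
    """Outcome of one quality gate; `drug` is empty for plate-level gates."""

    pdo_id: str
    drug: str
    plate_id: str
    z_prime: float | None
    z_pass: bool | None
    replicate_deviation: float | None
    deviation_pass: bool | None
    decision: str


def z_factor(pos_ctrl: Sequence[float], neg_ctrl: Sequence[float]) -> float:
    """Z'-factor of a plate from its positive and negative control wells.

    Uses sample (n-1) standard deviations. At most 1, reached only when both
    control groups have zero spread.
    """
    pos = np.asarray(pos_ctrl, dtype=float)
    neg = np.asarray(neg_ctrl, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError("need at least two wells per control group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise UndefinedTestError("control means coincide; Z'-factor undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def replicate_deviation(gr_a: Sequence[float], gr_b: Sequence[float]) -> float:
    """Sum over concentrations of |GR_a - GR_b| between two replicate curves."""
    a = np.asarray(gr_a, dtype=float)
    b = np.asarray(gr_b, dtype=float)
    if a.shape != b.shape:
        raise GridError("replicate curves must share the concentration grid")
    return float(np.abs(a - b).sum())


def _bio_rep_gr_curve(
    wells: Sequence[WellRecord], drug: str, bio: int, grid: np.ndarray, x0: float
) -> np.ndarray:
    day5 = [w for w in wells if w.timepoint != 0]
    neg = [w for w in day5 if w.role == "negative_control" and w.bio_rep == bio]
    if not neg:
        raise InsufficientDataError(f"no negative controls for bio_rep {bio}")
    x_ctrl = float(np.mean([w.intensity for w in neg]))
    gr = []
    for c in grid:
        cw = [
            w
            for w in day5
            if w.role == "treated"
            and w.drug == drug
            and w.bio_rep == bio
            and np.isclose(w.concentration, c, rtol=1e-9, atol=0.0)
        ]
        if not cw:
            raise InsufficientDataError(f"{drug} bio_rep {bio} missing concentration {c}")
        gr.append(compute_gr(float(np.mean([w.intensity for w in cw])), x0, x_ctrl))
    return np.asarray(gr)


def qc_gate(
    wells: Sequence[WellRecord], cfg: ScreenConfig, pdo_id: str
) -> tuple[list[QCReport], dict[str, set[int]]]:
    """Apply both quality gates to one PDO's plate set.

    Returns the QC reports plus, per drug, the set of biological replicates
    that survive for aggregation.  Plates failing Z' are excluded wholesale;
    a failing replicate pair excludes both members for that drug.
    """
    reports: list[QCReport] = []
    day5 = [w for w in wells if w.timepoint != 0]
    baseline = [w for w in wells if w.role == "baseline"]
    if not baseline:
        raise InsufficientDataError(f"{pdo_id}: no baseline wells")
    x0 = float(np.mean([w.intensity for w in baseline]))

    excluded_plates: set[str] = set()
    for plate_id in sorted({w.plate_id for w in day5}):
        pw = [w for w in day5 if w.plate_id == plate_id]
        pos = [w.intensity for w in pw if w.role == "positive_control"]
        neg = [w.intensity for w in pw if w.role == "negative_control"]
        zp = z_factor(pos, neg)
        z_pass = zp >= cfg.z_prime_min
        if not z_pass:
            excluded_plates.add(plate_id)
        reports.append(
            QCReport(
                pdo_id=pdo_id,
                drug="",
                plate_id=plate_id,
                z_prime=zp,
                z_pass=z_pass,
                replicate_deviation=None,
                deviation_pass=None,
                decision=INCLUDE if z_pass else EXCLUDE_PLATE,
            )
        )

    surviving = [w for w in wells if w.plate_id not in excluded_plates]
    day5_ok = [w for w in surviving if w.timepoint != 0]
    included: dict[str, set[int]] = {}
    for drug in cfg.drugs:
        bio_reps = sorted(
            {w.bio_rep for w in day5_ok if w.role == "treated" and w.drug == drug}
        )
        if not bio_reps:
            included[drug] = set()
            continue
        keep = set(bio_reps)
        if len(bio_reps) >= 2:
            grid = cfg.concentration_grids[drug]
            curves = {
                b: _bio_rep_gr_curve(surviving, drug, b, grid, x0) for b in bio_reps
            }
            # gate on the worst pair; both members of a failing pair drop out
            for a, b in combinations(bio_reps, 2):
                dev = replicate_deviation(curves[a], curves[b])
                dev_pass = dev <= cfg.deviation_max
                if not dev_pass:
                    keep.discard(a)
                    keep.discard(b)
                plate_ids = sorted(
                    {
                        w.plate_id
                        for w in day5_ok
                        if w.drug == drug and w.bio_rep in (a, b)
                    }
                )
                reports.append(
                    QCReport(
                        pdo_id=pdo_id,
                        drug=drug,
                        plate_id="+".join(plate_ids),
                        z_prime=None,
                        z_pass=None,
                        replicate_deviation=dev,
                        deviation_pass=dev_pass,
                        decision=INCLUDE if dev_pass else RERUN_REPLICATES,
                    )
                )
        included[drug] = keep
    return reports, included
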