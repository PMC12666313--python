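"""Patient-level response endpoints from lesion measurements.

Lesion diameters from serial CT scans are reduced to a best percent change —
separately for the biopsied index lesion and for the sum of all target
lesions — then categorized per RECIST 1.1 (CR/PR/SD/PD) and dichotomized
into decrease vs. increase.  Zero change counts as *increase* (absence of
shrinkage) and is flagged for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError, FormatError, InsufficientDataError, ValidationError

DECREASE = "decrease"
INCREASE = "increase"

CLINICAL_COLUMNS = (
    "patient_id",
    "lesion_id",
    "is_biopsied",
    "is_target",
    "timepoint",
    "diameter_mm",
    "new_lesions",
)


@dataclass(frozen=True)
class LesionMeasurement:
    patient_id: str
    lesion_id: str
    is_biopsied: bool
    is_target: bool
    timepoint: int  # scan index, 0 = baseline
    diameter: float  # longest diameter, mm

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValidationError(f"negative diameter for lesion {self.lesion_id}")


@dataclass(frozen=True)
class PatientResponse:
    patient_id: str
    pct_change_biopsied: float
    pct_change_targets: float
    recist: str
    dichotomized_biopsied: str
    dichotomized_targets: str
    new_lesions: bool
    zero_change_flag: bool  # exact 0% mapped to "increase"; audit marker


def percent_change(baseline_sum: float, followup_sum: float) -> float:
    """Percent change of a diameter (sum) relative to baseline."""
    if baseline_sum <= 0:
        raise DomainError("baseline diameter sum must be positive")
    return 100.0 * (followup_sum - baseline_sum) / baseline_sum


def best_response(changes: Sequence[float]) -> float:
    """Best (most negative) percent change across follow-up scans."""
    if len(changes) == 0:
        raise InsufficientDataError("no follow-up measurements")
    return float(min(changes))


def recist_category(
    best_change: float,
    increase_from_nadir: float,
    absolute_increase: float,
    new_lesions: bool,
) -> str:
    """RECIST 1.1 category from target-lesion summaries.

    PD requires new lesions or a >=20% increase from nadir that is also
    >=5 mm absolute; CR a disappearance (-100%); PR a >=30% decrease;
    SD otherwise.
    """
    if new_lesions or (increase_from_nadir >= 20.0 and absolute_increase >= 5.0):
        return "PD"
    if best_change <= -100.0:
        return "CR"
    if best_change <= -30.0:
        return "PR"
    return "SD"


def dichotomize_response(best_change: float) -> str:
    """Decrease iff the best percent change is strictly negative."""
    return DECREASE if best_change < 0 else INCREASE


def load_clinical_table(path_or_buffer) -> pd.DataFrame:
    """Read the clinical lesion TSV; `new_lesions` column is optional."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    required = set(CLINICAL_COLUMNS) - {"new_lesions"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing column(s) {sorted(missing)}")
    unknown = set(df.columns) - set(CLINICAL_COLUMNS)
    if unknown:
        raise FormatError(f"clinical table has unknown column(s) {sorted(unknown)}")
    if "new_lesions" not in df.columns:
        df["new_lesions"] = False
    if (df["diameter_mm"] < 0).any():
        row = int(df.index[df["diameter_mm"] < 0][0]) + 1
        raise ValidationError(f"row {row}: negative diameter")
    return df


def _series_changes(measure: pd.DataFrame) -> tuple[float, float, float]:
    """(best %, worst-from-nadir %, worst-from-nadir absolute mm) for a
    per-timepoint diameter-sum series indexed by scan."""
    sums = measure.groupby("timepoint")["diameter_mm"].sum().sort_index()
    if 0 not in sums.index:
        raise InsufficientDataError("no baseline (timepoint 0) measurement")
    baseline = float(sums.loc[0])
    follow = sums.loc[sums.index > 0]
    if follow.empty:
        raise InsufficientDataError("no follow-up measurements")
    changes = [percent_change(baseline, float(v)) for v in follow]
    best = best_response(changes)
    # progression is judged against the nadir (smallest sum incl. baseline)
    nadir = baseline
    worst_pct, worst_abs = float("-inf"), float("-inf")
    for v in follow:
        v = float(v)
        if nadir > 0:
            worst_pct = max(worst_pct, percent_change(nadir, v))
        worst_abs = max(worst_abs, v - nadir)
        nadir = min(nadir, v)
    return best, worst_pct, worst_abs


def derive_patient_responses(df: pd.DataFrame) -> list[PatientResponse]:
    """Compute per-patient response endpoints from a clinical lesion table."""
    out: list[PatientResponse] = []
    for pid, pdf in df.groupby("patient_id", sort=True):
        biopsied = pdf[pdf["is_biopsied"].astype(bool)]
        targets = pdf[pdf["is_target"].astype(bool)]
        if biopsied.empty or targets.empty:
            raise InsufficientDataError(f"{pid}: need a biopsied and >=1 target lesion")
        best_biop, _, _ = _series_changes(biopsied)
        best_tgt, inc_nadir, abs_inc = _series_changes(targets)
        new = bool(pdf["new_lesions"].astype(bool).any())
        out.append(
            PatientResponse(
                patient_id=str(pid),
                pct_change_biopsied=best_biop,
                pct_change_targets=best_tgt,
                recist=recist_category(best_tgt, inc_nadir, abs_inc, new),
                dichotomized_biopsied=dichotomize_response(best_biop),
                dichotomized_targets=dichotomize_response(best_tgt),
                new_lesions=new,
                zero_change_flag=(best_biop == 0.0 or best_tgt == 0.0),
            )
        )
    return out


def responses_frame(responses: Sequence[PatientResponse]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in responses])
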