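"""Data model and I/O for 384-well drug-screen plates.

A screen of one PDO (patient-derived organoid) line consists of day-5 assay
plates carrying drug-treated wells, vehicle negative controls and
staurosporine positive controls, plus a separate day-0 baseline plate of
untreated organoids used to anchor growth-rate (GR) calculations.  Plates are
exchanged as plain CSV tables with one row per well.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import FormatError, ValidationError

ROLES = ("treated", "negative_control", "positive_control", "baseline")

#: canonical CSV header, in order
PLATE_COLUMNS = (
    "plate_id",
    "well",
    "role",
    "drug",
    "concentration_uM",
    "tech_rep",
    "bio_rep",
    "timepoint_day",
    "intensity",
)

_WELL_RE = re.compile(r"^[A-P]([1-9]|1[0-9]|2[0-4])$")

#: default seven-regimen panel mirroring standard-of-care colorectal drugs
DEFAULT_DRUGS = (
    "5-FU",
    "oxaliplatin",
    "SN-38",
    "5-FU+oxaliplatin",
    "5-FU+SN-38",
    "trifluridine/tipiracil",
    "panitumumab",
)


@dataclass(frozen=True)
class WellRecord:
    """One well of a 384-well plate at a single readout."""

    plate_id: str
    well: str  # "A1".."P24"
    role: str  # one of ROLES
    drug: str  # empty for controls/baseline
    concentration: float  # µM; 0 for controls
    tech_rep: int  # 1..3
    bio_rep: int  # 1..4
    timepoint: int  # day 0 or day 5
    intensity: float  # fluorescence, arbitrary units

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} in well {self.well}")
        if not _WELL_RE.match(self.well):
            raise ValidationError(f"well address {self.well!r} not on a 384-well grid")
        if self.intensity < 0:
            raise ValidationError(f"negative intensity {self.intensity} in well {self.well}")
        if self.role == "baseline" and self.timepoint != 0:
            raise ValidationError(f"baseline well {self.well} must be at day 0")
        if self.role == "treated" and self.concentration <= 0:
            raise ValidationError(f"treated well {self.well} needs concentration > 0")
        if self.role in ("negative_control", "positive_control", "baseline") and self.drug:
            raise ValidationError(f"control well {self.well} must have empty drug")


def _default_grids(drugs: Sequence[str]) -> dict[str, np.ndarray]:
    # 10-point logarithmic range over four decades, synthetic stand-in for
    # panel-specific ranges
    return {d: np.logspace(-3, 1, 10) for d in drugs}


@dataclass
class ScreenConfig:
    """Panel layout and analysis thresholds for one screening campaign."""

    drugs: tuple[str, ...] = DEFAULT_DRUGS
    n_concentrations: int = 10
    concentration_grids: dict[str, np.ndarray] = field(default_factory=dict)
    n_technical: int = 3
    n_biological: int = 2
    z_prime_min: float = 0.3
    deviation_max: float = 1.7
    sensitivity_cutoff: float = 0.63

    def __post_init__(self) -> None:
        if not self.concentration_grids:
            self.concentration_grids = _default_grids(self.drugs)
        for drug, grid in self.concentration_grids.items():
            grid = np.asarray(grid, dtype=float)
            self.concentration_grids[drug] = grid
            if len(grid) != self.n_concentrations:
                raise ValidationError(
                    f"grid for {drug} has {len(grid)} points, expected {self.n_concentrations}"
                )
            if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
                raise ValidationError(f"grid for {drug} must be strictly increasing and positive")
        if not self.z_prime_min < 1:
            raise ValidationError("z_prime_min must be < 1")
        if not 0 < self.sensitivity_cutoff < 1:
            raise ValidationError("sensitivity_cutoff must lie in (0, 1)")
        if self.deviation_max <= 0:
            raise ValidationError("deviation_max must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScreenConfig":
        kwargs = dict(raw)
        if "drugs" in kwargs:
            kwargs["drugs"] = tuple(kwargs["drugs"])
        if "concentration_grids" in kwargs:
            kwargs["concentration_grids"] = {
                d: np.asarray(g, dtype=float) for d, g in kwargs["concentration_grids"].items()
            }
        return cls(**kwargs)


def load_plate_table(path_or_buffer) -> list[WellRecord]:
    """Read a canonical plate CSV into WellRecords.

    Raises FormatError on a header mismatch and ValidationError (with the
    offending 1-based data row number) on invariant violations.
    """
    if hasattr(path_or_buffer, "read"):
        fh = path_or_buffer
        close = False
    else:
        fh = open(path_or_buffer, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty plate table") from None
        missing = set(PLATE_COLUMNS) - set(header)
        unknown = set(header) - set(PLATE_COLUMNS)
        if missing or unknown:
            parts = []
            if missing:
                parts.append(f"missing column(s) {sorted(missing)}")
            if unknown:
                parts.append(f"unknown column(s) {sorted(unknown)}")
            raise FormatError("; ".join(parts))
        idx = {c: header.index(c) for c in PLATE_COLUMNS}
        records = []
        for rownum, row in enumerate(reader, start=1):
            if not row:
                continue
            try:
                records.append(
                    WellRecord(
                        plate_id=row[idx["plate_id"]],
                        well=row[idx["well"]],
                        role=row[idx["role"]],
                        drug=row[idx["drug"]],
                        concentration=float(row[idx["concentration_uM"]]),
                        tech_rep=int(row[idx["tech_rep"]]),
                        bio_rep=int(row[idx["bio_rep"]]),
                        timepoint=int(row[idx["timepoint_day"]]),
                        intensity=float(row[idx["intensity"]]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
        return records
    finally:
        if close:
            fh.close()


def _format_float(x: float) -> str:
    # repr round-trips doubles exactly, keeping write∘read the identity
    return repr(float(x))


def write_plate_table(records: Iterable[WellRecord], path_or_buffer) -> None:
    """Write WellRecords in the canonical CSV dialect (inverse of load)."""
    if hasattr(path_or_buffer, "write"):
        fh = path_or_buffer
        close = False
    else:
        fh = open(path_or_buffer, "w", newline="", encoding="utf-8")
        close = True
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PLATE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.plate_id,
                    r.well,
                    r.role,
                    r.drug,
                    _format_float(r.concentration),
                    r.tech_rep,
                    r.bio_rep,
                    r.timepoint,
                    _format_float(r.intensity),
                ]
            )
    finally:
        if close:
            fh.close()


def dumps_plate_table(records: Iterable[WellRecord]) -> str:
    buf = io.StringIO()
    write_plate_table(records, buf)
    return buf.getvalue()


@dataclass(frozen=True)
class LayoutViolation:
    """One violated layout rule; violations are data, not exceptions."""

    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {self.detail}"


def validate_layout(wells: Sequence[WellRecord], cfg: ScreenConfig) -> list[LayoutViolation]:
    """Check a screen's plate set against the configured layout contract.

    Returns one descriptor per violated rule; an empty list means the layout
    conforms. Removing wells can only add violations, never remove one.
    """
    violations: list[LayoutViolation] = []
    day5 = [w for w in wells if w.timepoint != 0]
    if not any(w.role == "baseline" for w in wells):
        violations.append(LayoutViolation("missing_baseline", "no day-0 baseline wells"))
    if not any(w.role == "negative_control" for w in day5):
        violations.append(
            LayoutViolation("missing_negative_control", "no day-5 negative-control wells")
        )
    if not any(w.role == "positive_control" for w in day5):
        violations.append(
            LayoutViolation("missing_positive_control", "no day-5 positive-control wells")
        )

    treated = [w for w in day5 if w.role == "treated"]
    by_drug: dict[str, list[WellRecord]] = {}
    for w in treated:
        by_drug.setdefault(w.drug, []).append(w)

    for drug, dw in sorted(by_drug.items()):
        grid = cfg.concentration_grids.get(drug)
        if grid is None:
            violations.append(LayoutViolation("unknown_drug", f"{drug} not in configured panel"))
            continue
        present = sorted({w.concentration for w in dw})
        missing = [
            float(c)
            for c in grid
            if not any(np.isclose(c, p, rtol=1e-9, atol=0.0) for p in present)
        ]
        if missing:
            violations.append(
                LayoutViolation(
                    "missing_concentrations",
                    f"{drug}: grid concentrations {missing} absent",
                )
            )
        extra = [
            float(p)
            for p in present
            if not any(np.isclose(p, c, rtol=1e-9, atol=0.0) for c in grid)
        ]
        if extra:
            violations.append(
                LayoutViolation("off_grid_concentrations", f"{drug}: {extra} not on grid")
            )
        # replicate counts per concentration within each biological replicate
        for bio in sorted({w.bio_rep for w in dw}):
            for c in grid:
                n = sum(
                    1
                    for w in dw
                    if w.bio_rep == bio and np.isclose(w.concentration, c, rtol=1e-9, atol=0.0)
                )
                if 0 < n != cfg.n_technical:
                    violations.append(
                        LayoutViolation(
                            "wrong_replicate_count",
                            f"{drug} bio_rep {bio} at {c} µM: {n} technical "
                            f"replicates, expected {cfg.n_technical}",
                        )
                    )
    return violations
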