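"""Domain types, validation and CSV I/O for PCNL patient cohorts.

A cohort is a list of :class:`PatientRecord`. Each record carries the
demographics, anthropometrics, stone burden, serial hematocrits and
transfusion volumes needed by the blood-loss estimator and the
transfusion audit.

Hematocrits are stored internally as *fractions* in (0, 1). Clinical CSV
files carry them in percent by default; :func:`read_cohort` converts on
the way in and :func:`write_cohort` converts back on the way out. The
fraction convention is what makes the red-cell-mass arithmetic
(``RBC volume = EBV × Hct``) dimensionally consistent once transfused
product volumes enter the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import CohortValidationError, SchemaError

__all__ = [
    "Sex",
    "StoneType",
    "HematocritSeries",
    "PatientRecord",
    "TIMEPOINTS",
    "POSTOP_TIMEPOINTS",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

#: Sampling schedule: one pre-operative draw, then 12/24/36/72 h post-op.
TIMEPOINTS = ("pre_op", "h12", "h24", "h36", "h72")
POSTOP_TIMEPOINTS = ("h12", "h24", "h36", "h72")

_HCT_COLUMNS = {
    "pre_op": "hct_preop",
    "h12": "hct_12h",
    "h24": "hct_24h",
    "h36": "hct_36h",
    "h72": "hct_72h",
}

MANDATORY_COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "stone_burden_mm2",
    "stone_type",
    "hct_preop",
    "hct_12h",
    "hct_24h",
    "hct_36h",
    "hct_72h",
    "crossmatched_ml",
    "transfused_intraop_ml",
    "transfused_postop_ml",
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class StoneType(str, Enum):
    STAGHORN = "staghorn"
    NON_STAGHORN = "non_staghorn"
    UNKNOWN = "unknown"


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(
            f"{name} must be a hematocrit fraction in (0, 1), got {value!r}"
        )


@dataclass(frozen=True)
class HematocritSeries:
    """Serial hematocrits as fractions: pre-op plus 12/24/36/72 h post-op.

    The pre-op draw is mandatory and at least one post-op draw must be
    present. The 72-h draw is the default endpoint of the blood-loss
    chain; the intermediate draws are carried for trajectory QC only.
    """

    pre_op: float
    h12: Optional[float] = None
    h24: Optional[float] = None
    h36: Optional[float] = None
    h72: Optional[float] = None

    def __post_init__(self) -> None:
        _check_fraction("pre_op hematocrit", self.pre_op)
        postop = [getattr(self, tp) for tp in POSTOP_TIMEPOINTS]
        if all(v is None for v in postop):
            raise ValueError("at least one post-operative hematocrit is required")
        for tp in POSTOP_TIMEPOINTS:
            v = getattr(self, tp)
            if v is not None:
                _check_fraction(f"{tp} hematocrit", v)

    def get(self, timepoint: str) -> Optional[float]:
        if timepoint not in TIMEPOINTS:
            raise KeyError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
        return getattr(self, timepoint)

    def has(self, timepoint: str) -> bool:
        return self.get(timepoint) is not None


@dataclass(frozen=True)
class PatientRecord:
    """One patient of a PCNL cohort.

    ``stone_burden_mm2`` is the planar stone size, length × width on
    pre-operative imaging. ``product_hct`` is the hematocrit of the
    transfused product as a fraction; the default 1.0 treats transfused
    volumes as pure red-cell volume (whole-product accounting), and can
    be lowered for packed-cell accounting.
    """

    patient_id: str
    sex: Sex
    age: float
    height_cm: float
    weight_kg: float
    stone_burden_mm2: float
    hct: HematocritSeries
    crossmatched_ml: float = 0.0
    transfused_intraop_ml: float = 0.0
    transfused_postop_ml: float = 0.0
    product_hct: float = 1.0
    stone_type: StoneType = StoneType.UNKNOWN

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError(f"height must be positive, got {self.height_cm!r}")
        if self.weight_kg <= 0:
            raise ValueError(f"weight must be positive, got {self.weight_kg!r}")
        if self.stone_burden_mm2 < 0:
            raise ValueError(f"stone burden must be >= 0, got {self.stone_burden_mm2!r}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18 (adult cohort), got {self.age!r}")
        if self.crossmatched_ml < 0:
            raise ValueError("cross-matched volume must be >= 0")
        if self.transfused_intraop_ml < 0 or self.transfused_postop_ml < 0:
            raise ValueError("transfused volumes must be >= 0")
        if not (0.0 < self.product_hct <= 1.0):
            raise ValueError(f"product hematocrit must be in (0, 1], got {self.product_hct!r}")

    @property
    def transfused_total_ml(self) -> float:
        return self.transfused_intraop_ml + self.transfused_postop_ml

    @property
    def transfused_rbc_ml(self) -> float:
        """Red-cell volume transfused: product volume × product hematocrit."""
        return self.transfused_total_ml * self.product_hct


def _parse_sex(raw) -> Sex:
    token = str(raw).strip().lower()
    if token in ("m", "male"):
        return Sex.MALE
    if token in ("f", "female"):
        return Sex.FEMALE
    raise ValueError(f"unrecognized sex {raw!r} (expected M/F)")


def _parse_stone_type(raw) -> StoneType:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return StoneType.UNKNOWN
    token = str(raw).strip().lower()
    for st in StoneType:
        if token == st.value:
            return st
    raise ValueError(f"unrecognized stone type {raw!r}")


def _parse_hct(raw, column: str, hct_unit: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    value = float(raw)
    if hct_unit == "percent":
        if not (0.0 < value < 100.0):
            raise ValueError(f"{column}={value!r} outside (0, 100) percent")
        return value / 100.0
    if not (0.0 < value < 1.0):
        raise ValueError(f"{column}={value!r} outside (0, 1) fraction")
    return value


def read_cohort(path, hct_unit: str = "percent") -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with one row per patient (schema: ``MANDATORY_COLUMNS``
        plus optional ``product_hct``).
    hct_unit
        ``"percent"`` (clinical convention, default) or ``"fraction"``.

    Raises
    ------
    SchemaError
        A mandatory column is missing.
    CohortValidationError
        One or more rows violate record invariants; the exception lists
        every offending row with its index and patient id.
    """
    if hct_unit not in ("percent", "fraction"):
        raise ValueError(f"hct_unit must be 'percent' or 'fraction', got {hct_unit!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    records: list[PatientRecord] = []
    diagnostics: list[str] = []
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            hcts = {
                tp: _parse_hct(row[col], col, hct_unit)
                for tp, col in _HCT_COLUMNS.items()
            }
            if hcts["pre_op"] is None:
                raise ValueError("pre-operative hematocrit is mandatory")
            series = HematocritSeries(
                pre_op=hcts["pre_op"],
                h12=hcts["h12"],
                h24=hcts["h24"],
                h36=hcts["h36"],
                h72=hcts["h72"],
            )
            product_hct = 1.0
            if "product_hct" in df.columns and not pd.isna(row["product_hct"]):
                product_hct = float(row["product_hct"])
            records.append(
                PatientRecord(
                    patient_id=pid,
                    sex=_parse_sex(row["sex"]),
                    age=float(row["age"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    stone_burden_mm2=float(row["stone_burden_mm2"]),
                    stone_type=_parse_stone_type(row["stone_type"]),
                    hct=series,
                    crossmatched_ml=float(row["crossmatched_ml"]),
                    transfused_intraop_ml=float(row["transfused_intraop_ml"]),
                    transfused_postop_ml=float(row["transfused_postop_ml"]),
                    product_hct=product_hct,
                )
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(f"row {idx} (patient_id={pid}): {exc}")
    if diagnostics:
        raise CohortValidationError(diagnostics)
    return records


def cohort_to_frame(records: Iterable[PatientRecord], hct_unit: str = "percent") -> pd.DataFrame:
    """Tabulate records in the CSV schema (hematocrits in the given unit)."""
    scale = 100.0 if hct_unit == "percent" else 1.0
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": "M" if r.sex is Sex.MALE else "F",
            "age": r.age,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "stone_burden_mm2": r.stone_burden_mm2,
            "stone_type": r.stone_type.value,
        }
        for tp, col in _HCT_COLUMNS.items():
            v = r.hct.get(tp)
            row[col] = v * scale if v is not None else None
        row.update(
            crossmatched_ml=r.crossmatched_ml,
            transfused_intraop_ml=r.transfused_intraop_ml,
            transfused_postop_ml=r.transfused_postop_ml,
            product_hct=r.product_hct,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[PatientRecord], path, hct_unit: str = "percent") -> None:
    """Write a cohort CSV; inverse of :func:`read_cohort` to 1e-9 on numerics."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty cohort")
    df = cohort_to_frame(records, hct_unit=hct_unit)
    df.to_csv(path, index=False)  # default float repr round-trips exactly
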