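"""Hematocrit-based perioperative blood-loss estimation.

The chain runs from anthropometrics to a hemodilution-corrected total
blood loss (TBL), all in mL:

    BSA  = 0.0235 × height_cm^0.42246 × weight_kg^0.51456        [m²]
    EBV  = BSA × 2430 (female) | 2530 (male)                     [mL]
    uncompensated RBC loss = EBV × (Hct_pre − Hct_final)
    compensated  RBC loss = transfused red-cell volume
    total RBC loss = uncompensated + compensated
    TBL  = total RBC loss / mean(Hct_pre, Hct_final)

Hematocrits are fractions throughout. The pre-operative draw is the
"initial" hematocrit; the 72-h post-operative draw is the default
"final" one (the 12/24/36-h draws do not enter TBL). A rising
hematocrit yields a negative uncompensated loss, which is propagated,
not clamped: downstream audit code decides whether to floor at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cohort import PatientRecord, Sex
from .errors import DomainError, EstimationError

__all__ = [
    "BSA_COEF",
    "BSA_HEIGHT_EXP",
    "BSA_WEIGHT_EXP",
    "EBV_PER_M2",
    "BloodLossEstimate",
    "body_surface_area",
    "estimated_blood_volume",
    "rbc_loss",
    "total_blood_loss",
    "estimate_patient",
    "estimate_cohort",
]

BSA_COEF = 0.0235
BSA_HEIGHT_EXP = 0.42246
BSA_WEIGHT_EXP = 0.51456

#: Estimated blood volume per m² of body surface area, by sex (mL/m²).
EBV_PER_M2 = {Sex.FEMALE: 2430.0, Sex.MALE: 2530.0}


@dataclass(frozen=True)
class BloodLossEstimate:
    """Full estimation chain for one patient (volumes in mL, BSA in m²)."""

    patient_id: str
    bsa_m2: float
    ebv_ml: float
    hct_initial: float
    hct_final: float
    initial_rbc_ml: float
    final_rbc_ml: float
    uncompensated_rbc_loss_ml: float
    compensated_rbc_loss_ml: float
    total_rbc_loss_ml: float
    total_blood_loss_ml: float

    @property
    def hct_drop(self) -> float:
        """Pre-to-final hematocrit drop as a fraction (may be negative)."""
        return self.hct_initial - self.hct_final


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²) from height (cm) and weight (kg)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError(
            f"height and weight must be positive, got ({height_cm!r}, {weight_kg!r})"
        )
    return BSA_COEF * height_cm**BSA_HEIGHT_EXP * weight_kg**BSA_WEIGHT_EXP


def estimated_blood_volume(sex: Sex, bsa_m2: float) -> float:
    """Sex-adjusted estimated blood volume (mL) from body surface area."""
    if bsa_m2 <= 0:
        raise DomainError(f"body surface area must be positive, got {bsa_m2!r}")
    return EBV_PER_M2[Sex(sex)] * bsa_m2


def _check_hct(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise DomainError(f"{name} must be a fraction in (0, 1), got {value!r}")


def rbc_loss(
    ebv_ml: float,
    hct_initial: float,
    hct_final: float,
    transfused_rbc_ml: float = 0.0,
) -> tuple[float, float, float]:
    """Red-cell losses (uncompensated, compensated, total), all in mL.

    Uncompensated loss is the red-cell volume implied by the hematocrit
    shift; compensated loss is the red-cell volume put back by
    transfusion. A hematocrit rise gives a negative uncompensated loss.
    """
    _check_hct("initial hematocrit", hct_initial)
    _check_hct("final hematocrit", hct_final)
    if transfused_rbc_ml < 0:
        raise DomainError(f"transfused RBC volume must be >= 0, got {transfused_rbc_ml!r}")
    uncompensated = ebv_ml * (hct_initial - hct_final)
    compensated = transfused_rbc_ml
    return uncompensated, compensated, uncompensated + compensated


def total_blood_loss(total_rbc_loss_ml: float, hct_initial: float, hct_final: float) -> float:
    """Whole-blood-equivalent loss: RBC loss over the mean perioperative hematocrit."""
    _check_hct("initial hematocrit", hct_initial)
    _check_hct("final hematocrit", hct_final)
    return total_rbc_loss_ml / (0.5 * (hct_initial + hct_final))


def estimate_patient(record: PatientRecord, final_timepoint: str = "h72") -> BloodLossEstimate:
    """Run the whole chain for one validated patient record.

    Raises :class:`EstimationError` when the final-timepoint hematocrit
    is missing (complete-case design: such patients are excluded, not
    imputed).
    """
    hct_final = record.hct.get(final_timepoint)
    if hct_final is None:
        raise EstimationError(
            f"patient {record.patient_id}: missing {final_timepoint} hematocrit"
        )
    hct_initial = record.hct.pre_op
    bsa = body_surface_area(record.height_cm, record.weight_kg)
    ebv = estimated_blood_volume(record.sex, bsa)
    uncomp, comp, total_rbc = rbc_loss(ebv, hct_initial, hct_final, record.transfused_rbc_ml)
    tbl = total_blood_loss(total_rbc, hct_initial, hct_final)
    return BloodLossEstimate(
        patient_id=record.patient_id,
        bsa_m2=bsa,
        ebv_ml=ebv,
        hct_initial=hct_initial,
        hct_final=hct_final,
        initial_rbc_ml=ebv * hct_initial,
        final_rbc_ml=ebv * hct_final,
        uncompensated_rbc_loss_ml=uncomp,
        compensated_rbc_loss_ml=comp,
        total_rbc_loss_ml=total_rbc,
        total_blood_loss_ml=tbl,
    )


def estimate_cohort(
    records: Iterable[PatientRecord], final_timepoint: str = "h72"
) -> tuple[list[tuple[PatientRecord, BloodLossEstimate]], list[str]]:
    """Estimate every estimable patient; return (pairs, excluded patient ids)."""
    pairs: list[tuple[PatientRecord, BloodLossEstimate]] = []
    excluded: list[str] = []
    for record in records:
        try:
            pairs.append((record, estimate_patient(record, final_timepoint)))
        except EstimationError:
            excluded.append(record.patient_id)
    return pairs, excluded
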