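"""Cohort-level transfusion-practice audit.

Three metrics of blood-bank utilization:

* the per-patient transfusion *pattern* (none / intra-operative only /
  post-operative only / both);
* the cross-match-to-transfusion (CT) ratio — all cross-matched volume
  over all transfused volume, including patients cross-matched but
  never transfused (over-ordering inflates it; values near 1 indicate
  efficient ordering);
* per-patient transfusion *adequacy* against estimated total blood
  loss: a transfused volume deviating from TBL by more than the
  threshold (default 15%) is under- or over-transfusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .blood_loss import BloodLossEstimate
from .cohort import PatientRecord
from .errors import DomainError, UndefinedRatioError

__all__ = [
    "TransfusionPattern",
    "Adequacy",
    "TransfusionAudit",
    "classify_pattern",
    "ct_ratio",
    "classify_adequacy",
    "audit_cohort",
]

DEFAULT_ADEQUACY_THRESHOLD = 0.15


class TransfusionPattern(str, Enum):
    NONE = "none"
    INTRA_ONLY = "intra_only"
    POST_ONLY = "post_only"
    BOTH = "both"


class Adequacy(str, Enum):
    UNDER = "under"
    ADEQUATE = "adequate"
    OVER = "over"


def classify_pattern(record: PatientRecord) -> TransfusionPattern:
    """Transfusion pattern from the intra-op and post-op volume fields."""
    intra = record.transfused_intraop_ml > 0
    post = record.transfused_postop_ml > 0
    if intra and post:
        return TransfusionPattern.BOTH
    if intra:
        return TransfusionPattern.INTRA_ONLY
    if post:
        return TransfusionPattern.POST_ONLY
    return TransfusionPattern.NONE


def ct_ratio(crossmatched_total: float, transfused_total: float) -> float:
    """Cross-match-to-transfusion ratio (unitless; mL or units, consistently)."""
    if transfused_total <= 0:
        raise UndefinedRatioError("no transfusions; CT ratio undefined")
    return crossmatched_total / transfused_total


def classify_adequacy(
    tbl_ml: float,
    transfused_ml: float,
    threshold: float = DEFAULT_ADEQUACY_THRESHOLD,
) -> Adequacy:
    """Classify a transfusion against estimated blood loss.

    ``over`` when the transfused volume exceeds TBL by more than
    ``threshold`` × TBL, ``under`` when it falls short by more than
    that, else ``adequate``. A zero-TBL patient is adequate untransfused
    and over-transfused otherwise.
    """
    if tbl_ml < 0 or transfused_ml < 0:
        raise DomainError(
            f"TBL and transfused volume must be >= 0, got ({tbl_ml!r}, {transfused_ml!r})"
        )
    if tbl_ml == 0:
        return Adequacy.ADEQUATE if transfused_ml == 0 else Adequacy.OVER
    delta = (transfused_ml - tbl_ml) / tbl_ml
    if delta > threshold:
        return Adequacy.OVER
    if delta < -threshold:
        return Adequacy.UNDER
    return Adequacy.ADEQUATE


@dataclass(frozen=True)
class TransfusionAudit:
    """Per-patient classes plus cohort-level utilization metrics.

    ``ct_ratio`` is ``None`` for an all-untransfused cohort (undefined).
    ``adequacy_counts_transfused`` restricts to transfused patients;
    ``adequacy_counts_cohort`` covers everyone.
    """

    per_patient: pd.DataFrame  # patient_id, pattern, adequacy, tbl_ml, transfused_ml
    n: int
    n_transfused: int
    transfusion_rate: float
    pattern_proportions: Mapping[TransfusionPattern, float]
    ct_ratio: Optional[float]
    total_crossmatched_ml: float
    total_transfused_ml: float
    mean_crossmatched_ml: float
    mean_transfused_ml_among_transfused: Optional[float]
    adequacy_counts_transfused: Mapping[Adequacy, int]
    adequacy_counts_cohort: Mapping[Adequacy, int]

    @property
    def transfusion_rate_percent(self) -> float:
        """Perioperative transfusion rate in percent, 1-decimal rounding."""
        return round(100.0 * self.transfusion_rate, 1)


def audit_cohort(
    pairs: Sequence[tuple[PatientRecord, BloodLossEstimate]],
    threshold: float = DEFAULT_ADEQUACY_THRESHOLD,
) -> TransfusionAudit:
    """Audit a cohort of (record, estimate) pairs.

    Adequacy is classified against TBL floored at zero: a net
    hemoconcentration (negative estimated loss) needs no transfusion,
    so an untransfused such patient is adequate and a transfused one is
    over-transfused. The raw (possibly negative) TBL is preserved in
    the per-patient table.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot audit an empty cohort")

    rows = []
    for record, est in pairs:
        pattern = classify_pattern(record)
        adequacy = classify_adequacy(
            max(est.total_blood_loss_ml, 0.0), record.transfused_total_ml, threshold
        )
        rows.append(
            {
                "patient_id": record.patient_id,
                "pattern": pattern.value,
                "adequacy": adequacy.value,
                "tbl_ml": est.total_blood_loss_ml,
                "crossmatched_ml": record.crossmatched_ml,
                "transfused_ml": record.transfused_total_ml,
            }
        )
    per_patient = pd.DataFrame(rows)

    n = len(pairs)
    pattern_counts = {p: 0 for p in TransfusionPattern}
    for value in per_patient["pattern"]:
        pattern_counts[TransfusionPattern(value)] += 1
    pattern_proportions = {p: c / n for p, c in pattern_counts.items()}
    n_transfused = n - pattern_counts[TransfusionPattern.NONE]

    total_crossmatched = float(per_patient["crossmatched_ml"].sum())
    total_transfused = float(per_patient["transfused_ml"].sum())
    ratio = None
    if total_transfused > 0:
        ratio = ct_ratio(total_crossmatched, total_transfused)

    transfused_mask = per_patient["transfused_ml"] > 0
    mean_transfused = (
        float(per_patient.loc[transfused_mask, "transfused_ml"].mean())
        if n_transfused
        else None
    )

    counts_cohort = {a: 0 for a in Adequacy}
    counts_transfused = {a: 0 for a in Adequacy}
    for _, row in per_patient.iterrows():
        adequacy = Adequacy(row["adequacy"])
        counts_cohort[adequacy] += 1
        if row["transfused_ml"] > 0:
            counts_transfused[adequacy] += 1

    return TransfusionAudit(
        per_patient=per_patient,
        n=n,
        n_transfused=n_transfused,
        transfusion_rate=n_transfused / n,
        pattern_proportions=pattern_proportions,
        ct_ratio=ratio,
        total_crossmatched_ml=total_crossmatched,
        total_transfused_ml=total_transfused,
        mean_crossmatched_ml=float(per_patient["crossmatched_ml"].mean()),
        mean_transfused_ml_among_transfused=mean_transfused,
        adequacy_counts_transfused=counts_transfused,
        adequacy_counts_cohort=counts_cohort,
    )
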