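"""Human-readable report assembly.

Renders the pipeline's results as Markdown blocks: cohort summary,
blood-loss summary, bivariate screening table, fitted model and
transfusion audit. Volumes print to 2 decimals, percentages to 1,
coefficients to 3; all numbers are recomputable from the input CSV
plus configuration.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blood_loss import BloodLossEstimate, estimate_cohort
from .cohort import PatientRecord, Sex, StoneType
from .errors import UndefinedCorrelationError
from .regression import (
    RegressionModel,
    ScreeningResult,
    bivariate_screen,
    fit_stepwise,
    published_model,
)
from .transfusion import Adequacy, TransfusionAudit, TransfusionPattern, audit_cohort

__all__ = [
    "estimates_frame",
    "screening_frame",
    "cohort_summary_block",
    "blood_loss_block",
    "screening_block",
    "model_block",
    "audit_block",
    "build_report",
]


def estimates_frame(
    pairs: Sequence[tuple[PatientRecord, BloodLossEstimate]]
) -> pd.DataFrame:
    """Tidy per-patient estimate table keyed by patient_id."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r, _ in pairs],
            "bsa_m2": [e.bsa_m2 for _, e in pairs],
            "ebv_ml": [e.ebv_ml for _, e in pairs],
            "initial_rbc_ml": [e.initial_rbc_ml for _, e in pairs],
            "final_rbc_ml": [e.final_rbc_ml for _, e in pairs],
            "uncompensated_rbc_loss_ml": [e.uncompensated_rbc_loss_ml for _, e in pairs],
            "compensated_rbc_loss_ml": [e.compensated_rbc_loss_ml for _, e in pairs],
            "total_rbc_loss_ml": [e.total_rbc_loss_ml for _, e in pairs],
            "tbl_ml": [e.total_blood_loss_ml for _, e in pairs],
            "hct_drop_pp": [100.0 * e.hct_drop for _, e in pairs],
        }
    )


def screening_frame(
    pairs: Sequence[tuple[PatientRecord, BloodLossEstimate]],
    extra: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Candidate-predictor frame from records (+ optional extra columns).

    Record-derived candidates: stone burden, baseline hematocrit
    (percent), age, BMI. Extra candidates (creatinine, counts, ...)
    may be merged in on patient_id.
    """
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r, _ in pairs],
            "stone_burden_mm2": [r.stone_burden_mm2 for r, _ in pairs],
            "baseline_hct_percent": [100.0 * r.hct.pre_op for r, _ in pairs],
            "age": [r.age for r, _ in pairs],
            "bmi": [r.weight_kg / (r.height_cm / 100.0) ** 2 for r, _ in pairs],
            "tbl_ml": [e.total_blood_loss_ml for _, e in pairs],
        }
    )
    if extra is not None:
        df = df.merge(extra, on="patient_id", how="left")
    return df.drop(columns=["patient_id"])


def _fmt_pct(x: float) -> str:
    return f"{100.0 * x:.1f}%"


def cohort_summary_block(records: Sequence[PatientRecord]) -> str:
    n = len(records)
    n_male = sum(1 for r in records if r.sex is Sex.MALE)
    ages = np.array([r.age for r in records])
    burden = np.array([r.stone_burden_mm2 for r in records])
    n_staghorn = sum(1 for r in records if r.stone_type is StoneType.STAGHORN)
    lines = [
        "## Cohort summary",
        "",
        f"- Patients: {n} ({n_male} male / {n - n_male} female)",
        f"- Age: {ages.mean():.2f} ± {ages.std(ddof=1):.2f} years",
        f"- Stone burden: median {np.median(burden):.2f} mm² "
        f"(IQR {np.percentile(burden, 25):.2f}–{np.percentile(burden, 75):.2f})",
        f"- Staghorn calculi: {_fmt_pct(n_staghorn / n)}",
    ]
    return "\n".join(lines)


def blood_loss_block(pairs) -> str:
    tbl = np.array([e.total_blood_loss_ml for _, e in pairs])
    drop = np.array([100.0 * e.hct_drop for _, e in pairs])
    lines = [
        "## Blood loss",
        "",
        f"- Total blood loss: mean {tbl.mean():.2f} ± {tbl.std(ddof=1):.2f} mL, "
        f"median {np.median(tbl):.2f} mL "
        f"(95% range {np.percentile(tbl, 2.5):.2f}–{np.percentile(tbl, 97.5):.2f} mL)",
        f"- Hematocrit drop: mean {drop.mean():.2f} ± {drop.std(ddof=1):.2f} percentage points",
    ]
    return "\n".join(lines)


def screening_block(results: Sequence[ScreeningResult]) -> str:
    lines = [
        "## Bivariate screening vs total blood loss",
        "",
        "| Variable | Method | r | p | enters (p < 0.25) |",
        "|---|---|---|---|---|",
    ]
    for res in results:
        lines.append(
            f"| {res.variable} | {res.method} | {res.r:.3f} | {res.p:.3f} | "
            f"{'yes' if res.passes_entry else 'no'} |"
        )
    return "\n".join(lines)


def model_block(model: RegressionModel) -> str:
    lines = ["## Fitted predictive model", "", f"`{model.equation()}`", ""]
    if model.coefficients:
        lines += ["| Term | Estimate | p |", "|---|---|---|"]
        lines.append(f"| intercept | {model.intercept:.3f} | — |")
        for name, beta in model.coefficients.items():
            p = model.pvalues.get(name) if model.pvalues else None
            lines.append(f"| {name} | {beta:.3f} | {p:.3f} |" if p is not None else f"| {name} | {beta:.3f} | — |")
        if model.r_squared is not None:
            lines.append("")
            lines.append(f"R² = {model.r_squared:.3f} (n = {model.n})")
    else:
        lines.append("No candidate survived stepwise selection (intercept-only model).")
    if model.excluded:
        lines.append("")
        lines.append(f"Candidates not selected: {', '.join(model.excluded)}")
    lines += [
        "",
        "Published reference model: "
        f"`{published_model().equation()}` (baseline hematocrit in percent)",
    ]
    return "\n".join(lines)


def audit_block(audit: TransfusionAudit) -> str:
    props = audit.pattern_proportions
    lines = [
        "## Transfusion audit",
        "",
        "| Pattern | Proportion |",
        "|---|---|",
        f"| No transfusion | {_fmt_pct(props[TransfusionPattern.NONE])} |",
        f"| Intra-operative only | {_fmt_pct(props[TransfusionPattern.INTRA_ONLY])} |",
        f"| Post-operative only | {_fmt_pct(props[TransfusionPattern.POST_ONLY])} |",
        f"| Both intra & post | {_fmt_pct(props[TransfusionPattern.BOTH])} |",
        "",
        f"- Perioperative transfusion rate: {audit.transfusion_rate_percent}% "
        f"({audit.n_transfused}/{audit.n})",
        f"- Mean cross-matched volume: {audit.mean_crossmatched_ml:.2f} mL",
    ]
    if audit.mean_transfused_ml_among_transfused is not None:
        lines.append(
            f"- Mean transfused volume (transfused patients): "
            f"{audit.mean_transfused_ml_among_transfused:.2f} mL"
        )
    if audit.ct_ratio is not None:
        lines.append(f"- Cross-match-to-transfusion ratio: {audit.ct_ratio:.2f}")
    else:
        lines.append("- Cross-match-to-transfusion ratio: undefined (no transfusions)")
    ct = audit.adequacy_counts_transfused
    cc = audit.adequacy_counts_cohort
    lines += [
        "",
        "| Adequacy | Transfused patients | Whole cohort |",
        "|---|---|---|",
        f"| Under-transfused | {ct[Adequacy.UNDER]} | {cc[Adequacy.UNDER]} |",
        f"| Adequate | {ct[Adequacy.ADEQUATE]} | {cc[Adequacy.ADEQUATE]} |",
        f"| Over-transfused | {ct[Adequacy.OVER]} | {cc[Adequacy.OVER]} |",
    ]
    return "\n".join(lines)


def build_report(
    records: Sequence[PatientRecord],
    final_timepoint: str = "h72",
    adequacy_threshold: float = 0.15,
    extra_candidates: Optional[pd.DataFrame] = None,
) -> str:
    """Assemble the full Markdown report from a validated cohort."""
    pairs, excluded = estimate_cohort(records, final_timepoint)
    if not pairs:
        raise ValueError("no estimable patients in cohort")
    blocks = [
        "# PCNL blood-loss pipeline report",
        cohort_summary_block(records),
        blood_loss_block(pairs),
    ]
    frame = screening_frame(pairs, extra_candidates)
    try:
        screen = bivariate_screen(frame)
        blocks.append(screening_block(screen))
        survivors = [s.variable for s in screen if s.passes_entry]
        if survivors:
            model = fit_stepwise(frame, candidates=survivors)
            blocks.append(model_block(model))
        else:
            blocks.append(
                "## Fitted predictive model\n\nNo candidate passed the p < 0.25 screen."
            )
    except UndefinedCorrelationError as exc:
        blocks.append(f"## Bivariate screening\n\nScreening failed: {exc}")
    blocks.append(audit_block(audit_cohort(pairs, adequacy_threshold)))
    if excluded:
        blocks.append(
            "## Exclusions\n\nPatients without the final-timepoint hematocrit "
            f"(excluded from estimation): {', '.join(excluded)}"
        )
    return "\n\n".join(blocks) + "\n"
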