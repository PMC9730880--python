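"""Tumor growth rates and hyperprogression classification.

A lesion's growth rate assumes exponential volume growth with volume
proportional to the cube of the RECIST long diameter:

    TG = 3 * ln(D2 / D1) / (t2 - t1)      [per day]

computed over the reference period (pre-baseline -> baseline) and the
experimental period (baseline -> follow-up).  A hyperprogressive lesion
(HPL) shows single-lesion RECIST progression at follow-up together with at
least a doubling of the growth rate after treatment start.  Patient status
is nPD (not progressing), PD-nHPD (progressing, no HPL) or PD-HPD
(progressing with >= 1 HPL).

Single-lesion RECIST progression adapts the RECIST 1.1 sum rule to one
diameter: >= 20% relative and >= 5 mm absolute increase from baseline to
follow-up.  Patient-level progression applies the same rule to the sum of
all segmented lesion diameters, or fires on new lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "LesionMeasurements",
    "GrowthAssessment",
    "PatientStatus",
    "growth_rate",
    "recist_lesion_pd",
    "classify_hpl",
    "patient_status",
    "validate_timepoints",
    "cohort_rates",
    "classify_cohort",
    "measurements_from_row",
]

DAYS_PER_MONTH = 30.44

# Acquisition windows (days relative to treatment start) for the three scans:
# pre-baseline 3 +/- 2 months before baseline, baseline up to 3 months before
# treatment, follow-up 3 +/- 1.5 months after treatment start.
PRE_TO_BASE_WINDOW_DAYS = (30, 152)
BASELINE_WINDOW_DAYS = (-91, 0)
FOLLOWUP_WINDOW_DAYS = (46, 137)


@dataclass
class LesionMeasurements:
    """Long diameters (mm) and scan times (days from treatment start)."""

    lesion_id: str
    patient_id: str
    d_pre_mm: float
    d_base_mm: float
    d_fu_mm: float
    t_pre: float
    t_base: float
    t_fu: float

    def __post_init__(self) -> None:
        if min(self.d_pre_mm, self.d_base_mm, self.d_fu_mm) <= 0:
            raise ValueError(f"lesion {self.lesion_id!r}: diameters must be > 0")
        if not (self.t_pre < self.t_base <= 0 < self.t_fu):
            raise ValueError(
                f"lesion {self.lesion_id!r}: need t_pre < t_base <= 0 < t_fu, "
                f"got ({self.t_pre}, {self.t_base}, {self.t_fu})")


@dataclass
class GrowthAssessment:
    """Per-lesion growth rates and hyperprogression flags."""

    lesion_id: str
    patient_id: str
    tg_ref: float
    tg_exp: float
    tgr_ratio: float | None  # None when tg_ref <= 0 (ratio undefined)
    recist_pd: bool
    hpl: bool
    ref_nonpositive: bool = False  # flagged for sensitivity analysis
    window_violations: list[str] = field(default_factory=list)


@dataclass
class PatientStatus:
    patient_id: str
    status: str  # nPD | PD-nHPD | PD-HPD
    n_lesions: int
    n_hpl: int
    new_lesions_flag: bool


def growth_rate(d1_mm: float, d2_mm: float, t1_days: float, t2_days: float) -> float:
    """Exponential volume growth rate (per day) from two long diameters."""
    if d1_mm <= 0 or d2_mm <= 0:
        raise ValueError("diameters must be positive")
    if t2_days <= t1_days:
        raise ValueError(f"need t2 > t1, got t1={t1_days}, t2={t2_days}")
    return 3.0 * math.log(d2_mm / d1_mm) / (t2_days - t1_days)


def recist_lesion_pd(d_base_mm: float, d_fu_mm: float) -> bool:
    """Single-lesion progression: >= 20% and >= 5 mm diameter increase."""
    if d_base_mm <= 0 or d_fu_mm <= 0:
        raise ValueError("diameters must be positive")
    delta = d_fu_mm - d_base_mm
    return delta / d_base_mm >= 0.20 and delta >= 5.0


def classify_hpl(m: LesionMeasurements) -> GrowthAssessment:
    """Classify one lesion as hyperprogressive or not.

    HPL requires single-lesion RECIST progression, positive post-treatment
    growth, and TG doubling.  A non-positive reference rate (lesion stable or
    shrinking before treatment) with positive post-treatment growth counts as
    doubling — any growth exceeds twice a non-positive rate — and is flagged.
    """
    tg_ref = growth_rate(m.d_pre_mm, m.d_base_mm, m.t_pre, m.t_base)
    tg_exp = growth_rate(m.d_base_mm, m.d_fu_mm, m.t_base, m.t_fu)
    pd_flag = recist_lesion_pd(m.d_base_mm, m.d_fu_mm)
    ratio = tg_exp / tg_ref if tg_ref > 0 else None
    doubling = tg_exp > 0 and (tg_ref <= 0 or tg_exp >= 2.0 * tg_ref)
    return GrowthAssessment(
        lesion_id=m.lesion_id,
        patient_id=m.patient_id,
        tg_ref=tg_ref,
        tg_exp=tg_exp,
        tgr_ratio=ratio,
        recist_pd=pd_flag,
        hpl=pd_flag and doubling,
        ref_nonpositive=tg_ref <= 0,
        window_violations=validate_timepoints(m),
    )


def validate_timepoints(m: LesionMeasurements) -> list[str]:
    """Advisory check of the scan-time windows; returns violation messages."""
    out = []
    gap = m.t_base - m.t_pre
    if not PRE_TO_BASE_WINDOW_DAYS[0] <= gap <= PRE_TO_BASE_WINDOW_DAYS[1]:
        out.append(f"pre-baseline: baseline gap {gap:g} d outside "
                   f"{PRE_TO_BASE_WINDOW_DAYS}")
    if not BASELINE_WINDOW_DAYS[0] <= m.t_base <= BASELINE_WINDOW_DAYS[1]:
        out.append(f"baseline: t={m.t_base:g} d outside {BASELINE_WINDOW_DAYS}")
    if not FOLLOWUP_WINDOW_DAYS[0] <= m.t_fu <= FOLLOWUP_WINDOW_DAYS[1]:
        out.append(f"follow-up: t={m.t_fu:g} d outside {FOLLOWUP_WINDOW_DAYS}")
    return out


def patient_status(assessments: list[GrowthAssessment],
                   measurements: list[LesionMeasurements],
                   new_lesions_flag: bool = False) -> PatientStatus:
    """Patient-level status from all of the patient's lesions.

    Patient PD: >= 20% and >= 5 mm increase of the summed long diameters
    (baseline -> follow-up) over all segmented lesions, or new lesions.
    """
    if not assessments:
        raise ValueError("patient has no lesions")
    pid = assessments[0].patient_id
    sum_base = sum(m.d_base_mm for m in measurements)
    sum_fu = sum(m.d_fu_mm for m in measurements)
    delta = sum_fu - sum_base
    pd_flag = (delta / sum_base >= 0.20 and delta >= 5.0) or new_lesions_flag
    n_hpl = sum(a.hpl for a in assessments)
    if pd_flag and n_hpl >= 1:
        status = "PD-HPD"
    elif pd_flag:
        status = "PD-nHPD"
    else:
        status = "nPD"
    return PatientStatus(pid, status, len(assessments), n_hpl, new_lesions_flag)


# ---------------------------------------------------------------------------
# Cohort-level plumbing over the lesions.csv schema


def measurements_from_row(row: pd.Series) -> LesionMeasurements:
    """Build LesionMeasurements from a lesions-table row.

    Prefers explicit day offsets (``t_*_days``); falls back to ISO dates
    relative to a ``treatment_start`` column.
    """
    if "t_pre_days" in row.index and pd.notna(row["t_pre_days"]):
        t = (float(row["t_pre_days"]), float(row["t_base_days"]),
             float(row["t_fu_days"]))
    else:
        start = pd.Timestamp(row["treatment_start"])
        t = tuple((pd.Timestamp(row[c]) - start).days for c in
                  ("date_prebaseline", "date_baseline", "date_followup"))
    return LesionMeasurements(
        lesion_id=str(row["lesion_id"]), patient_id=str(row["patient_id"]),
        d_pre_mm=float(row["d_prebaseline_mm"]),
        d_base_mm=float(row["d_baseline_mm"]),
        d_fu_mm=float(row["d_followup_mm"]),
        t_pre=t[0], t_base=t[1], t_fu=t[2])


def classify_cohort(lesions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every lesion and every patient of a lesions table.

    Returns ``(assessments, statuses)`` data frames.
    """
    assessments, per_patient = [], {}
    for _, row in lesions.iterrows():
        m = measurements_from_row(row)
        a = classify_hpl(m)
        assessments.append(a)
        per_patient.setdefault(m.patient_id, ([], [], False))
        per_patient[m.patient_id][0].append(a)
        per_patient[m.patient_id][1].append(m)
        if bool(row.get("new_lesions_flag", False)):
            per_patient[m.patient_id] = (per_patient[m.patient_id][0],
                                         per_patient[m.patient_id][1], True)
    statuses = [patient_status(a, ms, flag)
                for a, ms, flag in per_patient.values()]
    adf = pd.DataFrame([{
        "lesion_id": a.lesion_id, "patient_id": a.patient_id,
        "tg_ref": a.tg_ref, "tg_exp": a.tg_exp,
        "tgr_ratio": a.tgr_ratio, "recist_pd": a.recist_pd, "hpl": a.hpl,
        "ref_nonpositive": a.ref_nonpositive,
        "window_violations": "; ".join(a.window_violations),
    } for a in assessments])
    sdf = pd.DataFrame([{
        "patient_id": s.patient_id, "status": s.status,
        "n_lesions": s.n_lesions, "n_hpl": s.n_hpl,
        "new_lesions_flag": s.new_lesions_flag,
    } for s in statuses])
    return adf, sdf


def cohort_rates(assessments: pd.DataFrame, statuses: pd.DataFrame) -> dict:
    """Lesion- and patient-level progression/hyperprogression rates (%)."""
    if len(assessments) == 0 or len(statuses) == 0:
        raise ValueError("empty cohort")
    n_lesions = len(assessments)
    n_pd = int(assessments["recist_pd"].sum())
    n_hpl = int(assessments["hpl"].sum())
    n_patients = len(statuses)
    pd_statuses = statuses["status"].isin(["PD-nHPD", "PD-HPD"])
    n_pd_patients = int(pd_statuses.sum())
    n_pdhpd = int((statuses["status"] == "PD-HPD").sum())
    return {
        "n_lesions": n_lesions,
        "n_pd_lesions": n_pd,
        "n_hpl_lesions": n_hpl,
        "lesion_pd_rate_pct": 100.0 * n_pd / n_lesions,
        "hpl_rate_overall_pct": 100.0 * n_hpl / n_lesions,
        "hpl_rate_among_pd_pct": 100.0 * n_hpl / n_pd if n_pd else 0.0,
        "n_patients": n_patients,
        "n_pd_patients": n_pd_patients,
        "n_pd_hpd_patients": n_pdhpd,
        "patient_pd_rate_pct": 100.0 * n_pd_patients / n_patients,
        "pd_hpd_among_pd_pct": (100.0 * n_pdhpd / n_pd_patients
                                if n_pd_patients else 0.0),
        "pd_hpd_overall_pct": 100.0 * n_pdhpd / n_patients,
    }
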