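"""Cohort construction from longitudinal patient records.

Study entry is the later of the CAD diagnosis date and the first
primary-care note inside the study window; exit is the last primary-care
note in the window.  Eligibility requires primary-care notes on at least
two distinct dates, at least 365 days of follow-up after entry, and
non-missing demographics (sex, median income by zip code).

Outcome definitions: *statin use* is at least one start/renew prescription
action dated within [entry, exit]; *persistence* additionally requires a
start/renew within the final 365 days of follow-up with no explicit
discontinuation on or after that record's date (a same-day discontinuation
counts against persistence).  All date arithmetic is in whole calendar
days — "one year" and "twelve months" both mean 365 days.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_BIN_EDGES, AGE_BIN_LABELS
from .records import PatientRecord

__all__ = [
    "derive_entry_exit",
    "classify_statin_use",
    "classify_persistence",
    "derive_covariates",
    "build_analysis_rows",
    "apply_eligibility",
]

FOLLOWUP_DAYS = 365
PERSISTENCE_WINDOW_DAYS = 365

EXCLUSION_REASONS = ("missing_demographics", "too_few_notes",
                     "insufficient_followup")


class ContractViolation(RuntimeError):
    """An operation was called outside its stated precondition."""


def derive_entry_exit(record: PatientRecord, window) -> tuple[dt.date, dt.date] | None:
    """(entry, exit) dates, or None when the patient has no primary-care
    note within the study window (ineligible, not an error)."""
    start, end = window
    notes = [d for d in record.pcp_note_dates if start <= d <= end]
    if not notes:
        return None
    entry = max(record.cad_diagnosis_date, min(notes))
    return entry, max(notes)


def classify_statin_use(record: PatientRecord, entry: dt.date, exit_: dt.date) -> bool:
    return any(action in ("start", "renew") and entry <= date <= exit_
               for date, action in record.statin_prescriptions)


def classify_persistence(record: PatientRecord, entry: dt.date, exit_: dt.date) -> bool:
    """True when some start/renew lies within 365 days of exit and no
    discontinuation follows it (same-date discontinuation counts as
    following).  Only defined for statin users."""
    if not classify_statin_use(record, entry, exit_):
        raise ContractViolation("classify_persistence requires a statin user")
    window_start = exit_ - dt.timedelta(days=PERSISTENCE_WINDOW_DAYS)
    discontinues = [d for d, a in record.statin_prescriptions
                    if a == "discontinue" and d <= exit_]
    last_disc = max(discontinues) if discontinues else None
    for date, action in record.statin_prescriptions:
        if action in ("start", "renew") and window_start <= date <= exit_:
            if last_disc is None or date > last_disc:
                return True
    return False


def _age_group(age_years: int) -> str:
    idx = int(np.digitize(age_years, AGE_BIN_EDGES[1:], right=False))
    return AGE_BIN_LABELS[idx]


def derive_covariates(record: PatientRecord, entry: dt.date, exit_: dt.date,
                      window) -> dict:
    """Table-1 covariates for one patient.

    Smoking status and baseline BMI come from the latest record strictly
    before entry (else missing); maximum LDL-C is the highest value recorded
    strictly before exit (else missing); cardiology evaluation is any
    cardiology note within the study window.
    """
    start, end = window
    age = math.floor((entry - record.birth_date).days / 365.25)
    pre_smoking = [(d, v) for d, v in record.smoking_records if d < entry]
    pre_bmi = [(d, v) for d, v in record.bmi_records if d < entry]
    ldl_vals = [v for d, v in record.ldl_records if d < exit_]
    return {
        "age_at_entry": age,
        "age_group": _age_group(age),
        "ever_smoker": max(pre_smoking)[1] if pre_smoking else None,
        "baseline_bmi": max(pre_bmi)[1] if pre_bmi else None,
        "max_ldl": max(ldl_vals) if ldl_vals else None,
        "cardiology_evaluated": any(start <= d <= end
                                    for d in record.cardiology_note_dates),
        "diabetes": record.diabetes,
        "family_history_cad": record.family_history_cad,
        "cabg": record.cabg,
        "mi": record.mi,
        "income": record.income,
        "race": record.race,
        "government_insurance": record.government_insurance,
        "english_language": record.english_language,
    }


def build_analysis_rows(records: list[PatientRecord], window) -> pd.DataFrame:
    """One analysis row per patient: entry/exit, eligibility bookkeeping,
    outcomes and covariates.  Rows for ineligible patients are retained
    (with their exclusion reason) for :func:`apply_eligibility`."""
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "sex": rec.sex,
                     "provider_id": rec.provider_id}
        ee = derive_entry_exit(rec, window)
        if ee is None:
            row.update(entry_date=pd.NaT, exit_date=pd.NaT,
                       n_pcp_note_dates=0, followup_days=-1,
                       statin_use=None, persistent=None,
                       adverse_reaction=None, income=rec.income)
            rows.append(row)
            continue
        entry, exit_ = ee
        start, end = window
        n_notes = len({d for d in rec.pcp_note_dates if start <= d <= end})
        use = classify_statin_use(rec, entry, exit_)
        row.update(
            entry_date=pd.Timestamp(entry), exit_date=pd.Timestamp(exit_),
            n_pcp_note_dates=n_notes,
            followup_days=(exit_ - entry).days,
            statin_use=use,
            persistent=classify_persistence(rec, entry, exit_) if use else None,
            adverse_reaction=rec.adverse_reaction if use else None,
        )
        row.update(derive_covariates(rec, entry, exit_, window))
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("statin_use", "persistent", "adverse_reaction", "ever_smoker"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    for col in ("max_ldl", "baseline_bmi", "income"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def apply_eligibility(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Filter analysis rows to the study population and tally exclusions.

    Exclusion reasons, one per excluded row, by precedence:
    missing demographics (sex or income) > too few primary-care notes
    (< 2 distinct dates) > insufficient follow-up (< 365 days).
    """
    if len(rows) == 0:
        return rows.copy(), {r: 0 for r in EXCLUSION_REASONS}
    missing_demo = rows["sex"].isna() | rows["income"].isna()
    too_few = rows["n_pcp_note_dates"] < 2
    short_fu = rows["followup_days"] < FOLLOWUP_DAYS
    reason = np.select(
        [missing_demo, too_few, short_fu],
        ["missing_demographics", "too_few_notes", "insufficient_followup"],
        default="none")
    tally = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    retained = rows[reason == "none"].copy()
    retained["eligible"] = True
    return retained, tally


def write_exclusions(tally: dict, path) -> None:
    Path(path).write_text(json.dumps(
        {"excluded": tally, "total_excluded": sum(tally.values())}, indent=2))
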