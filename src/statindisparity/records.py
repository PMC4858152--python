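"""Patient-level longitudinal record type and its delimited-text round trip.

A cohort is stored as four CSV files:

``patients.csv``
    one row per patient: demographics, diagnosis flags, the adverse-reaction
    flag (blank for non-users), and the CAD diagnosis date.
``encounters.csv``
    ``patient_id,date,clinic`` with clinic in {primary_care, cardiology}.
``prescriptions.csv``
    ``patient_id,date,action`` with action in {start, renew, discontinue}.
``measurements.csv``
    ``patient_id,date,kind,value`` with kind in {ldl, bmi, smoking};
    smoking values are 0/1.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

PRESCRIPTION_ACTIONS = ("start", "renew", "discontinue")


@dataclass
class PatientRecord:
    patient_id: int
    sex: str
    birth_date: dt.date
    provider_id: int
    cad_diagnosis_date: dt.date
    pcp_note_dates: list = field(default_factory=list)
    cardiology_note_dates: list = field(default_factory=list)
    statin_prescriptions: list = field(default_factory=list)  # (date, action)
    smoking_records: list = field(default_factory=list)       # (date, bool)
    bmi_records: list = field(default_factory=list)           # (date, float)
    ldl_records: list = field(default_factory=list)           # (date, float)
    diabetes: bool = False
    family_history_cad: bool = False
    cabg: bool = False
    mi: bool = False
    adverse_reaction: bool | None = None
    income: float | None = None
    race: str = "White"
    government_insurance: bool = False
    english_language: bool = True

    def __post_init__(self):
        self.statin_prescriptions = sorted(
            self.statin_prescriptions,
            key=lambda p: (p[0], PRESCRIPTION_ACTIONS.index(p[1])))


def write_cohort_csv(records: list[PatientRecord], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients = pd.DataFrame([
        {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "birth_date": r.birth_date.isoformat(),
            "provider_id": r.provider_id,
            "cad_diagnosis_date": r.cad_diagnosis_date.isoformat(),
            "diabetes": int(r.diabetes),
            "family_history_cad": int(r.family_history_cad),
            "cabg": int(r.cabg),
            "mi": int(r.mi),
            "adverse_reaction": "" if r.adverse_reaction is None else int(r.adverse_reaction),
            "income": "" if r.income is None else r.income,
            "race": r.race,
            "government_insurance": int(r.government_insurance),
            "english_language": int(r.english_language),
        }
        for r in records
    ])
    patients.to_csv(outdir / "patients.csv", index=False)

    enc_rows, rx_rows, meas_rows = [], [], []
    for r in records:
        enc_rows.extend((r.patient_id, d.isoformat(), "primary_care")
                        for d in r.pcp_note_dates)
        enc_rows.extend((r.patient_id, d.isoformat(), "cardiology")
                        for d in r.cardiology_note_dates)
        rx_rows.extend((r.patient_id, d.isoformat(), a)
                       for d, a in r.statin_prescriptions)
        meas_rows.extend((r.patient_id, d.isoformat(), "smoking", int(v))
                         for d, v in r.smoking_records)
        meas_rows.extend((r.patient_id, d.isoformat(), "bmi", v)
                         for d, v in r.bmi_records)
        meas_rows.extend((r.patient_id, d.isoformat(), "ldl", v)
                         for d, v in r.ldl_records)
    pd.DataFrame(enc_rows, columns=["patient_id", "date", "clinic"]).to_csv(
        outdir / "encounters.csv", index=False)
    pd.DataFrame(rx_rows, columns=["patient_id", "date", "action"]).to_csv(
        outdir / "prescriptions.csv", index=False)
    pd.DataFrame(meas_rows, columns=["patient_id", "date", "kind", "value"]).to_csv(
        outdir / "measurements.csv", index=False)


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def read_cohort_csv(indir) -> list[PatientRecord]:
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv",
                           dtype={"adverse_reaction": "Int64"})
    encounters = pd.read_csv(indir / "encounters.csv")
    prescriptions = pd.read_csv(indir / "prescriptions.csv")
    measurements = pd.read_csv(indir / "measurements.csv")

    def grouped(df):
        return {pid: g for pid, g in df.groupby("patient_id")} if len(df) else {}

    enc_by, rx_by, meas_by = grouped(encounters), grouped(prescriptions), grouped(measurements)

    records = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        enc = enc_by.get(pid)
        pcp, cardio = [], []
        if enc is not None:
            for d, clinic in zip(enc["date"], enc["clinic"]):
                (pcp if clinic == "primary_care" else cardio).append(_parse_date(d))
        rx = rx_by.get(pid)
        prescriptions_list = ([(_parse_date(d), a) for d, a in zip(rx["date"], rx["action"])]
                              if rx is not None else [])
        meas = meas_by.get(pid)
        smoking, bmi, ldl = [], [], []
        if meas is not None:
            for d, kind, v in zip(meas["date"], meas["kind"], meas["value"]):
                date = _parse_date(d)
                if kind == "smoking":
                    smoking.append((date, bool(int(v))))
                elif kind == "bmi":
                    bmi.append((date, float(v)))
                else:
                    ldl.append((date, float(v)))
        adverse = row.adverse_reaction
        records.append(PatientRecord(
            patient_id=pid,
            sex=row.sex,
            birth_date=_parse_date(row.birth_date),
            provider_id=row.provider_id,
            cad_diagnosis_date=_parse_date(row.cad_diagnosis_date),
            pcp_note_dates=sorted(pcp),
            cardiology_note_dates=sorted(cardio),
            statin_prescriptions=prescriptions_list,
            smoking_records=sorted(smoking),
            bmi_records=sorted(bmi),
            ldl_records=sorted(ldl),
            diabetes=bool(row.diabetes),
            family_history_cad=bool(row.family_history_cad),
            cabg=bool(row.cabg),
            mi=bool(row.mi),
            adverse_reaction=None if pd.isna(adverse) else bool(adverse),
            income=None if pd.isna(row.income) else float(row.income),
            race=row.race,
            government_insurance=bool(row.government_insurance),
            english_language=bool(row.english_language),
        ))
    return records
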