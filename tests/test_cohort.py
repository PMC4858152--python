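"""Entry/exit derivation, eligibility filtering, outcome classification and
covariate derivation, including the exact round trip against the
generator's drawn outcomes."""

import datetime as dt

import pandas as pd
import pytest

from statindisparity import apply_eligibility, build_analysis_rows
from statindisparity.cohort import (ContractViolation, classify_persistence,
                                    classify_statin_use, derive_covariates,
                                    derive_entry_exit)
from statindisparity.records import PatientRecord

WINDOW = (dt.date(2000, 1, 1), dt.date(2011, 12, 31))
D = dt.date


def make_record(pcp=None, cad_dx=D(1998, 5, 1), rx=(), cardio=(),
                smoking=(), bmi=(), ldl=(), **kw) -> PatientRecord:
    defaults = dict(patient_id=0, sex="male", birth_date=D(1940, 1, 1),
                    provider_id=0, income=50.0)
    defaults.update(kw)
    return PatientRecord(cad_diagnosis_date=cad_dx,
                         pcp_note_dates=sorted(pcp or []),
                         cardiology_note_dates=list(cardio),
                         statin_prescriptions=list(rx),
                         smoking_records=list(smoking),
                         bmi_records=list(bmi),
                         ldl_records=list(ldl),
                         **defaults)


# ------------------------- entry / exit ------------------------------- #

@pytest.mark.parametrize("cad_dx, notes, expected_entry, expected_exit", [
    # entry is the later of CAD diagnosis and first in-window note
    (D(1998, 5, 1), [D(2000, 3, 15), D(2005, 6, 30)],
     D(2000, 3, 15), D(2005, 6, 30)),
    (D(2003, 2, 1), [D(2000, 6, 1), D(2002, 1, 1), D(2006, 3, 1)],
     D(2003, 2, 1), D(2006, 3, 1)),
])
def test_entry_exit_definition(cad_dx, notes, expected_entry, expected_exit):
    entry, exit_ = derive_entry_exit(make_record(pcp=notes, cad_dx=cad_dx), WINDOW)
    assert (entry, exit_) == (expected_entry, expected_exit)


def test_no_in_window_notes_marks_ineligible_not_error():
    rec = make_record(pcp=[D(1997, 1, 1)])
    assert derive_entry_exit(rec, WINDOW) is None
    rows = build_analysis_rows([rec], WINDOW)
    _, tally = apply_eligibility(rows)
    assert tally["too_few_notes"] == 1


def test_single_note_date_is_ineligible():
    rows = build_analysis_rows([make_record(pcp=[D(2004, 1, 1)])], WINDOW)
    retained, tally = apply_eligibility(rows)
    assert len(retained) == 0 and tally["too_few_notes"] == 1


# ------------------------- eligibility -------------------------------- #

def _eligibility_row(followup, income=50.0, n_notes=5, sex="male"):
    return {"sex": sex, "income": income, "n_pcp_note_dates": n_notes,
            "followup_days": followup}


def test_followup_boundary_364_excluded_365_retained():
    rows = pd.DataFrame([_eligibility_row(364), _eligibility_row(365)])
    retained, tally = apply_eligibility(rows)
    assert len(retained) == 1
    assert retained.iloc[0]["followup_days"] == 365
    assert tally["insufficient_followup"] == 1


def test_exclusion_precedence_and_tally_sums():
    rows = pd.DataFrame([
        _eligibility_row(100, income=None, n_notes=1),  # missing demographics wins
        _eligibility_row(500, n_notes=1),                # too few notes
        _eligibility_row(100),                           # short follow-up
        _eligibility_row(400),
    ])
    retained, tally = apply_eligibility(rows)
    assert tally == {"missing_demographics": 1, "too_few_notes": 1,
                     "insufficient_followup": 1}
    assert sum(tally.values()) == len(rows) - len(retained)


def test_empty_input_gives_empty_output_zero_tally():
    retained, tally = apply_eligibility(pd.DataFrame())
    assert len(retained) == 0 and sum(tally.values()) == 0


# ------------------------- outcomes ----------------------------------- #

ENTRY, EXIT = D(2002, 1, 1), D(2006, 1, 1)


@pytest.mark.parametrize("rx, expected", [
    ([(ENTRY + dt.timedelta(days=10), "start")], True),
    ([(ENTRY - dt.timedelta(days=100), "start")], False),  # before entry only
    ([], False),
    ([(ENTRY + dt.timedelta(days=5), "discontinue")], False),  # not a supply
])
def test_statin_use_classification(rx, expected):
    assert classify_statin_use(make_record(rx=rx), ENTRY, EXIT) is expected


@pytest.mark.parametrize("rx, expected", [
    # renew six months before exit, never discontinued -> persistent
    ([(ENTRY, "start"), (EXIT - dt.timedelta(days=182), "renew")], True),
    # last record 13 months before exit -> lapsed
    ([(ENTRY, "start"), (EXIT - dt.timedelta(days=395), "renew")], False),
    # recent renew but later explicit discontinuation -> not persistent
    ([(ENTRY, "start"), (EXIT - dt.timedelta(days=90), "renew"),
      (EXIT - dt.timedelta(days=30), "discontinue")], False),
    # same-day renew and discontinue resolve as discontinued
    ([(ENTRY, "start"), (EXIT - dt.timedelta(days=90), "renew"),
      (EXIT - dt.timedelta(days=90), "discontinue")], False),
    # discontinuation followed by a later restart -> persistent again
    ([(ENTRY, "start"), (EXIT - dt.timedelta(days=200), "discontinue"),
      (EXIT - dt.timedelta(days=100), "start")], True),
    # boundary: record exactly 365 days before exit counts
    ([(EXIT - dt.timedelta(days=365), "start")], True),
])
def test_persistence_classification(rx, expected):
    assert classify_persistence(make_record(rx=rx), ENTRY, EXIT) is expected


def test_persistence_on_non_user_is_contract_violation():
    with pytest.raises(ContractViolation):
        classify_persistence(make_record(), ENTRY, EXIT)


# ------------------------- covariates --------------------------------- #

def test_max_ldl_is_maximum_before_exit():
    rec = make_record(ldl=[(D(2003, 1, 1), 110.0), (D(2004, 1, 1), 160.0),
                           (D(2005, 1, 1), 130.0), (EXIT, 200.0)])
    cov = derive_covariates(rec, ENTRY, EXIT, WINDOW)
    assert cov["max_ldl"] == 160.0  # the exit-day value is not "before exit"


def test_missing_baseline_bmi_when_no_pre_entry_record():
    rec = make_record(bmi=[(ENTRY + dt.timedelta(days=30), 28.0)])
    cov = derive_covariates(rec, ENTRY, EXIT, WINDOW)
    assert cov["baseline_bmi"] is None


def test_smoking_from_latest_pre_entry_record():
    rec = make_record(smoking=[(D(2000, 1, 5), True), (D(2001, 6, 1), False)])
    cov = derive_covariates(rec, ENTRY, EXIT, WINDOW)
    assert cov["ever_smoker"] is False


def test_cardiology_evaluation_flag():
    rec = make_record(cardio=[D(2004, 5, 1)])
    assert derive_covariates(rec, ENTRY, EXIT, WINDOW)["cardiology_evaluated"]
    assert not derive_covariates(make_record(), ENTRY, EXIT, WINDOW)[
        "cardiology_evaluated"]


def test_age_at_entry_floor():
    rec = make_record(birth_date=D(1940, 6, 15))
    cov = derive_covariates(rec, ENTRY, EXIT, WINDOW)
    assert cov["age_at_entry"] == 61
    assert cov["age_group"] == "55-64"


# ------------------------- round trip --------------------------------- #

def test_derived_outcomes_match_generator_truth_exactly(small_config,
                                                        small_cohort,
                                                        small_frame):
    """The builder's statin-use and persistence classifications reproduce
    the generator's drawn outcomes on 100% of rows, and persistence
    implies use everywhere."""
    rows = build_analysis_rows(small_cohort, small_config.study_window)
    retained, tally = apply_eligibility(rows)
    assert sum(tally.values()) == 0
    merged = retained.set_index("patient_id")
    truth = small_frame.set_index("patient_id")
    assert (merged["statin_use"].astype(bool)
            == truth["statin_use"].astype(bool)).all()
    users = truth["statin_use"].astype(bool)
    assert (merged.loc[users, "persistent"].astype(bool)
            == truth.loc[users, "persistent"].astype(bool)).all()
    assert merged.loc[~users, "persistent"].isna().all()
    # persistence implies use
    both = merged["persistent"].fillna(False).astype(bool)
    assert (merged.loc[both, "statin_use"].astype(bool)).all()
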