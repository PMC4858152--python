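"""Synthetic longitudinal CAD cohort generator.

Two entry points share one population model:

* :func:`generate_analysis_frame` draws the patient-level covariates and the
  true initiation/persistence outcomes and returns the analysis table
  directly (fast; used for large simulation experiments).
* :func:`generate_cohort` additionally constructs encounter, prescription and
  measurement histories such that the cohort-builder's derived
  classifications reproduce the drawn outcomes exactly.

Covariates are drawn independently within sex from per-sex marginals (the
joint distribution of the source population is unknown; independence within
sex is the declared simplification).  Ages follow a per-sex normal truncated
to [18, 100].  Outcomes follow logistic models on sex, age group and the
binary covariates plus a provider-level normal random intercept shared by
both outcomes.  Missingness in smoking / max LDL / baseline BMI is missing
at random given sex and age.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import (AGE_BIN_EDGES, AGE_BIN_LABELS, MODEL_BINARY_COVARIATES,
                     CohortConfig)
from .records import PatientRecord

__all__ = [
    "generate_analysis_frame",
    "generate_cohort",
    "config_full_mediation",
    "config_direct_effect_only",
    "make_eligibility_fixture",
]

AGE_MIN, AGE_MAX = 18.0, 100.0

#: log-odds-style tilts of the missingness probability (MAR in age and sex).
_MISS_AGE_SLOPE = 0.04
_MISS_FEMALE_SHIFT = 0.3


def age_bin_index(age_years) -> np.ndarray:
    """Index of the standard age group for integer or fractional ages."""
    return np.digitize(np.asarray(age_years, dtype=float),
                       AGE_BIN_EDGES[1:], right=False)


def linear_predictor(coefs: dict, female, age_idx, binaries: dict,
                     adverse=None) -> np.ndarray:
    """Log-odds of an outcome under a coefficient dictionary."""
    female = np.asarray(female)
    lp = np.full(female.shape, float(coefs["intercept"]))
    lp += coefs.get("female", 0.0) * female
    offsets = np.asarray(coefs.get("age_group", np.zeros(len(AGE_BIN_LABELS))),
                         dtype=float)
    lp += offsets[np.asarray(age_idx)]
    for name, x in binaries.items():
        lp += coefs.get(name, 0.0) * np.asarray(x)
    if adverse is not None:
        lp += coefs.get("adverse_reaction", 0.0) * np.asarray(adverse)
    return lp


def _per_sex(values_by_sex: dict, female: np.ndarray, key=None) -> np.ndarray:
    male_v = values_by_sex["male"] if key is None else values_by_sex["male"][key]
    female_v = values_by_sex["female"] if key is None else values_by_sex["female"][key]
    return np.where(female, female_v, male_v)


def _draw_population(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Vectorized draw of one population; returns raw arrays including the
    hidden continuous age and provider effects."""
    n = config.n_patients
    female = rng.random(n) < config.frac_female
    provider_id = rng.integers(0, config.n_providers, n)
    provider_effects = rng.normal(0.0, config.provider_random_effect_sd,
                                  config.n_providers)
    u_age = rng.random(n)
    age = np.empty(n)
    for sex, mask in (("male", ~female), ("female", female)):
        p = config.age_params_by_sex[sex]
        a = (AGE_MIN - p["mean"]) / p["sd"]
        b = (AGE_MAX - p["mean"]) / p["sd"]
        age[mask] = truncnorm.ppf(u_age[mask], a, b, loc=p["mean"], scale=p["sd"])
    age_idx = age_bin_index(np.floor(age))

    binaries = {}
    for cov in sorted(config.covariate_prevalences_by_sex):
        p = _per_sex(config.covariate_prevalences_by_sex[cov], female)
        binaries[cov] = rng.random(n) < p

    aux = config.auxiliary_params_by_sex
    income = np.maximum(
        _per_sex(aux["income"], female, "mean")
        + _per_sex(aux["income"], female, "sd") * rng.standard_normal(n), 5.0)
    max_ldl = np.clip(
        _per_sex(aux["max_ldl"], female, "mean")
        + _per_sex(aux["max_ldl"], female, "sd") * rng.standard_normal(n),
        30.0, 400.0)
    bmi = np.clip(
        _per_sex(aux["baseline_bmi"], female, "mean")
        + _per_sex(aux["baseline_bmi"], female, "sd") * rng.standard_normal(n),
        12.0, 70.0)
    race_levels = sorted(aux["race_probs"]["male"])
    race_cum = {sex: np.cumsum([aux["race_probs"][sex][lvl] for lvl in race_levels])
                for sex in ("male", "female")}
    u_race = rng.random(n)
    race_idx = np.where(female,
                        np.searchsorted(race_cum["female"], u_race),
                        np.searchsorted(race_cum["male"], u_race))
    race = np.array(race_levels, dtype=object)[np.minimum(race_idx, len(race_levels) - 1)]
    gov = rng.random(n) < _per_sex(aux["government_insurance"], female)
    english = rng.random(n) < _per_sex(aux["english_language"], female)

    model_binaries = {c: binaries[c] for c in MODEL_BINARY_COVARIATES
                      if c in binaries}
    u = provider_effects[provider_id]
    lp_init = linear_predictor(config.initiation_coefficients, female,
                               age_idx, model_binaries) + u
    statin_use = rng.random(n) < expit(lp_init)
    adverse_all = rng.random(n) < _per_sex(
        config.adverse_reaction_prevalence_by_sex, female)
    adverse = np.where(statin_use, adverse_all, False)
    lp_pers = linear_predictor(config.persistence_coefficients, female,
                               age_idx, model_binaries, adverse=adverse) + u
    persistent_all = rng.random(n) < expit(lp_pers)
    persistent = statin_use & persistent_all

    missing = {}
    tilt = np.exp(_MISS_AGE_SLOPE * (age - 70.0) + _MISS_FEMALE_SHIFT * female)
    tilt /= tilt.mean()
    for var in ("smoking", "max_ldl", "baseline_bmi"):
        rate = config.missingness_rates.get(var, 0.0)
        p_miss = np.clip(rate * tilt, 0.0, 0.95)
        missing[var] = rng.random(n) < p_miss

    return {
        "female": female, "provider_id": provider_id, "age": age,
        "age_idx": age_idx, "binaries": binaries, "income": income,
        "max_ldl": max_ldl, "bmi": bmi, "race": race, "gov": gov,
        "english": english, "statin_use": statin_use, "adverse": adverse,
        "persistent": persistent, "missing": missing,
    }


def _population_frame(config: CohortConfig, pop: dict) -> pd.DataFrame:
    n = config.n_patients
    female = pop["female"]
    labels = np.array(AGE_BIN_LABELS, dtype=object)
    smoking_true = pop["binaries"]["smoking"]
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "sex": np.where(female, "female", "male"),
        "provider_id": pop["provider_id"],
        "age_at_entry": np.floor(pop["age"]).astype(int),
        "age_group": labels[pop["age_idx"]],
        "ever_smoker": pd.array(smoking_true, dtype="boolean"),
        "cardiology_evaluated": pop["binaries"]["cardiology_evaluated"],
        "diabetes": pop["binaries"]["diabetes"],
        "family_history_cad": pop["binaries"]["family_history_cad"],
        "cabg": pop["binaries"].get("cabg", np.zeros(n, bool)),
        "mi": pop["binaries"].get("mi", np.zeros(n, bool)),
        "income": pop["income"],
        "race": pop["race"],
        "government_insurance": pop["gov"],
        "english_language": pop["english"],
        "max_ldl": pop["max_ldl"].copy(),
        "baseline_bmi": pop["bmi"].copy(),
        "statin_use": pop["statin_use"],
        "adverse_reaction": pd.array(pop["adverse"], dtype="boolean"),
        "persistent": pd.array(pop["persistent"], dtype="boolean"),
        # hidden truth (pre-missingness) for validation of imputation etc.
        "true_ever_smoker": smoking_true,
        "true_max_ldl": pop["max_ldl"],
        "true_baseline_bmi": pop["bmi"],
    })
    df.loc[pop["missing"]["smoking"], "ever_smoker"] = pd.NA
    df.loc[pop["missing"]["max_ldl"], "max_ldl"] = np.nan
    df.loc[pop["missing"]["baseline_bmi"], "baseline_bmi"] = np.nan
    df.loc[~pop["statin_use"], "adverse_reaction"] = pd.NA
    df.loc[~pop["statin_use"], "persistent"] = pd.NA
    return df


def generate_analysis_frame(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort and return its analysis table directly (no event
    histories).  Byte-for-byte reproducible for identical ``(config, seed)``."""
    config.validate()
    pop_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    pop = _draw_population(config, np.random.default_rng(pop_ss))
    return _population_frame(config, pop)


# --------------------------------------------------------------------- #
# event-history construction
# --------------------------------------------------------------------- #

def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate full longitudinal records.

    Histories are constructed so that the cohort builder's derived entry,
    exit, statin-use and persistence classifications reproduce the drawn
    values: every patient has primary-care notes on >= 2 distinct dates with
    >= 365 days of follow-up; persistent users carry a start/renew within
    12 months of exit and no later discontinuation; non-persistent
    initiators either lapse (last record > 12 months before exit) or
    explicitly discontinue, 50/50, so both failure modes of the classifier
    are exercised.
    """
    config.validate()
    pop_ss, hist_ss = np.random.SeedSequence(config.seed).spawn(2)
    pop = _draw_population(config, np.random.default_rng(pop_ss))
    rng = np.random.default_rng(hist_ss)
    start, end = config.study_window
    window_days = (end - start).days

    records = []
    for i in range(config.n_patients):
        entry_off = int(rng.integers(0, window_days - 365 + 1))
        fu = int(rng.integers(365, window_days - entry_off + 1))
        entry = start + dt.timedelta(days=entry_off)
        exit_ = entry + dt.timedelta(days=fu)

        # entry is max(CAD diagnosis, first PCP note): realize both orderings
        pcp = {exit_}
        if rng.random() < 0.5 or entry_off == 0:
            cad_dx = entry - dt.timedelta(days=int(rng.integers(0, 3651)))
            pcp.add(entry)
        else:
            cad_dx = entry
            first_note_off = int(rng.integers(0, entry_off))
            pcp.add(start + dt.timedelta(days=first_note_off))
        for _ in range(int(rng.integers(0, 4))):
            pcp.add(entry + dt.timedelta(days=int(rng.integers(0, fu + 1))))

        cardio = []
        if pop["binaries"]["cardiology_evaluated"][i]:
            for _ in range(1 + int(rng.integers(0, 2))):
                cardio.append(entry + dt.timedelta(days=int(rng.integers(0, fu + 1))))

        rx = []
        if pop["statin_use"][i]:
            start_off = int(rng.integers(0, min(fu, 365) + 1))
            if pop["persistent"][i]:
                rx.append((entry + dt.timedelta(days=start_off), "start"))
                renew_off = fu - int(rng.integers(0, 365))
                if renew_off > start_off:
                    rx.append((entry + dt.timedelta(days=renew_off), "renew"))
            elif rng.random() < 0.5 and fu >= 366:
                # lapse: all medication records > 12 months before exit
                start_off = int(rng.integers(0, fu - 366 + 1))
                rx.append((entry + dt.timedelta(days=start_off), "start"))
                last_off = int(rng.integers(start_off, fu - 366 + 1))
                if last_off > start_off:
                    rx.append((entry + dt.timedelta(days=last_off), "renew"))
            else:
                # explicit discontinuation after the last medication record
                renew_off = fu - int(rng.integers(30, 366))
                start_off = int(rng.integers(0, max(renew_off, 0) + 1))
                disc_off = int(rng.integers(renew_off, fu + 1))
                rx.append((entry + dt.timedelta(days=start_off), "start"))
                if renew_off > start_off:
                    rx.append((entry + dt.timedelta(days=renew_off), "renew"))
                rx.append((entry + dt.timedelta(days=disc_off), "discontinue"))
        elif rng.random() < 0.1 and entry_off > 30:
            # some never-users have a pre-entry prescription only
            rx.append((entry - dt.timedelta(days=int(rng.integers(1, min(entry_off, 3650) + 1))),
                       "start"))

        smoking_recs, bmi_recs, ldl_recs = [], [], []
        if not pop["missing"]["smoking"][i]:
            smoking_recs.append((entry - dt.timedelta(days=int(rng.integers(1, 366))),
                                 bool(pop["binaries"]["smoking"][i])))
        if not pop["missing"]["baseline_bmi"][i]:
            bmi_recs.append((entry - dt.timedelta(days=int(rng.integers(1, 366))),
                             round(float(pop["bmi"][i]), 1)))
        if not pop["missing"]["max_ldl"][i]:
            peak = round(float(pop["max_ldl"][i]), 1)
            n_ldl = 1 + int(rng.integers(0, 3))
            offs = rng.integers(-365, fu, n_ldl)  # dates strictly before exit
            vals = [peak] + [round(peak * float(rng.uniform(0.5, 1.0)), 1)
                             for _ in range(n_ldl - 1)]
            ldl_recs = [(entry + dt.timedelta(days=int(o)), v)
                        for o, v in zip(offs, vals)]

        birth = entry - dt.timedelta(days=int(round(pop["age"][i] * 365.25)))
        records.append(PatientRecord(
            patient_id=i,
            sex="female" if pop["female"][i] else "male",
            birth_date=birth,
            provider_id=int(pop["provider_id"][i]),
            cad_diagnosis_date=cad_dx,
            pcp_note_dates=sorted(pcp),
            cardiology_note_dates=sorted(cardio),
            statin_prescriptions=rx,
            smoking_records=smoking_recs,
            bmi_records=bmi_recs,
            ldl_records=sorted(ldl_recs),
            diabetes=bool(pop["binaries"]["diabetes"][i]),
            family_history_cad=bool(pop["binaries"]["family_history_cad"][i]),
            cabg=bool(pop["binaries"].get("cabg", np.zeros(1, bool))[i]),
            mi=bool(pop["binaries"].get("mi", np.zeros(1, bool))[i]),
            adverse_reaction=bool(pop["adverse"][i]) if pop["statin_use"][i] else None,
            income=round(float(pop["income"][i]), 3),
            race=str(pop["race"][i]),
            government_insurance=bool(pop["gov"][i]),
            english_language=bool(pop["english"][i]),
        ))
    return records


# --------------------------------------------------------------------- #
# experiment presets and fixtures
# --------------------------------------------------------------------- #

def _equalize(by_sex: dict) -> dict:
    mean = (by_sex["male"] + by_sex["female"]) / 2
    return {"male": mean, "female": mean}


def config_full_mediation(**overrides) -> CohortConfig:
    """Sex affects the outcomes only through the standardized covariates
    (age group, smoking, cardiology evaluation, adverse reactions): no
    direct sex coefficient, and covariates outside the standardized set have
    identical distributions across sexes.  The true joint explained
    fraction is 100% for both outcomes."""
    base = CohortConfig().validate()
    prev = {k: dict(v) for k, v in base.covariate_prevalences_by_sex.items()}
    for cov in ("diabetes", "family_history_cad", "cabg", "mi"):
        prev[cov] = _equalize(prev[cov])
    init = dict(base.initiation_coefficients, female=0.0)
    pers = dict(base.persistence_coefficients, female=0.0)
    cfg = base.replace(covariate_prevalences_by_sex=prev,
                       initiation_coefficients=init,
                       persistence_coefficients=pers)
    return cfg.replace(**overrides) if overrides else cfg


def config_direct_effect_only(**overrides) -> CohortConfig:
    """A pure direct sex effect: identical covariate distributions across
    sexes, so every explained fraction is truly zero."""
    base = CohortConfig().validate()
    prev = {k: _equalize(dict(v)) for k, v in base.covariate_prevalences_by_sex.items()}
    age = {"male": {"mean": 70.0, "sd": 12.0}, "female": {"mean": 70.0, "sd": 12.0}}
    init = dict(base.initiation_coefficients, female=-0.35)
    pers = dict(base.persistence_coefficients, female=-0.30)
    cfg = base.replace(covariate_prevalences_by_sex=prev,
                       age_params_by_sex=age,
                       adverse_reaction_prevalence_by_sex=_equalize(
                           dict(base.adverse_reaction_prevalence_by_sex)),
                       initiation_coefficients=init,
                       persistence_coefficients=pers)
    return cfg.replace(**overrides) if overrides else cfg


def config_convergence_experiment(**overrides) -> CohortConfig:
    """Configuration for estimator-vs-enumeration convergence experiments: a
    pronounced initiation disparity (larger direct sex effect and covariate
    effects) so that explained fractions are estimated with small Monte
    Carlo error at large n, and no missingness (the enumeration describes
    complete data)."""
    base = CohortConfig().validate()
    init = dict(base.initiation_coefficients, female=-0.5, smoking=0.30,
                cardiology_evaluated=1.0)
    cfg = base.replace(
        initiation_coefficients=init,
        missingness_rates={"smoking": 0.0, "max_ldl": 0.0, "baseline_bmi": 0.0})
    return cfg.replace(**overrides) if overrides else cfg


def make_eligibility_fixture(n_total: int, n_missing_demographics: int,
                             seed: int = 0) -> pd.DataFrame:
    """Analysis-row fixture for the exclusion filter: ``n_total`` otherwise
    eligible rows of which exactly ``n_missing_demographics`` lack the
    demographic data (median income) required for inclusion."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "patient_id": np.arange(n_total),
        "sex": np.where(rng.random(n_total) < 0.37, "female", "male"),
        "income": rng.normal(70.0, 25.0, n_total).clip(min=5.0),
        "n_pcp_note_dates": rng.integers(2, 30, n_total),
        "followup_days": rng.integers(365, 4000, n_total),
    })
    drop = rng.choice(n_total, size=n_missing_demographics, replace=False)
    df.loc[drop, "income"] = np.nan
    return df
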