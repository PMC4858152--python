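"""Cohort generator configuration.

The defaults describe a two-hospital primary-care population of adults with
coronary artery disease followed 2000-2011: roughly 63% men, women about
4.5 years older on average, sex-differential prevalences of smoking and
cardiology evaluation, and statin initiation / persistence generated from
logistic models on those covariates with a shared provider random effect.
"""

from __future__ import annotations

import copy
import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Left edges of the age groups used for standardization; the last group is
#: open-ended (85+).  Ages below 18 never occur (adult cohort).
AGE_BIN_EDGES = (18, 45, 55, 65, 75, 85)
AGE_BIN_LABELS = ("18-44", "45-54", "55-64", "65-74", "75-84", "85+")

#: Binary covariates that enter the outcome models, in canonical order.
MODEL_BINARY_COVARIATES = (
    "smoking",
    "cardiology_evaluated",
    "diabetes",
    "family_history_cad",
)

#: Covariates drawn per sex but outside the outcome models by default.
EXTRA_BINARY_COVARIATES = ("cabg", "mi")

SEXES = ("male", "female")


class ConfigError(ValueError):
    """Invalid cohort configuration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _default_age_params() -> dict:
    return {
        "male": {"mean": 68.4, "sd": 11.8},
        "female": {"mean": 72.9, "sd": 12.1},
    }


def _default_prevalences() -> dict:
    return {
        "smoking": {"male": 0.656, "female": 0.498},
        "cardiology_evaluated": {"male": 0.645, "female": 0.575},
        "diabetes": {"male": 0.419, "female": 0.407},
        "family_history_cad": {"male": 0.149, "female": 0.151},
        "cabg": {"male": 0.170, "female": 0.101},
        "mi": {"male": 0.378, "female": 0.368},
    }


def _default_initiation_coefficients() -> dict:
    # Effect sizes chosen so that marginal initiation rates and odds ratios
    # resemble a secondary-prevention cohort (men ~87.7%, women ~81.9%).
    return {
        "intercept": 1.936,
        "female": -0.260,
        "age_group": [0.0, -0.315, -0.525, -0.735, -0.945, -1.155],
        "smoking": 0.135,
        "cardiology_evaluated": 0.930,
        "diabetes": 0.319,
        "family_history_cad": 0.315,
    }


def _default_persistence_coefficients() -> dict:
    # Persistence among initiators: men ~81.3%, women ~81.8%.
    return {
        "intercept": 1.644,
        "female": 0.126,
        "age_group": [0.0, -0.195, -0.325, -0.455, -0.585, -0.715],
        "smoking": 0.090,
        "cardiology_evaluated": 0.290,
        "diabetes": 0.152,
        "family_history_cad": 0.310,
        "adverse_reaction": -0.344,
    }


def _default_auxiliary() -> dict:
    """Distributions of covariates that do not drive the outcomes by default
    (they appear in the regression models as noise covariates)."""
    return {
        "income": {"male": {"mean": 73.4, "sd": 27.7},
                   "female": {"mean": 68.9, "sd": 27.4}},
        "max_ldl": {"male": {"mean": 127.4, "sd": 42.1},
                    "female": {"mean": 137.2, "sd": 46.6}},
        "baseline_bmi": {"male": {"mean": 29.6, "sd": 5.3},
                         "female": {"mean": 29.7, "sd": 6.7}},
        "race_probs": {
            "male": {"White": 0.856, "Black": 0.025, "Hispanic": 0.025,
                     "Asian": 0.014, "Other": 0.080},
            "female": {"White": 0.807, "Black": 0.052, "Hispanic": 0.036,
                       "Asian": 0.010, "Other": 0.095},
        },
        "government_insurance": {"male": 0.695, "female": 0.793},
        "english_language": {"male": 0.899, "female": 0.868},
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort.

    Proportions are in [0, 1]; ages in years; coefficients on the log-odds
    scale.  ``age_group`` coefficients are offsets for the six standard age
    bins (first bin is the reference).  The provider random effect is a
    normal log-odds intercept shared by the initiation and persistence
    models, inducing within-provider clustering.
    """

    n_patients: int = 24338
    frac_female: float = 0.37
    age_params_by_sex: dict = field(default_factory=_default_age_params)
    covariate_prevalences_by_sex: dict = field(default_factory=_default_prevalences)
    adverse_reaction_prevalence_by_sex: dict = field(
        default_factory=lambda: {"male": 0.217, "female": 0.271})
    initiation_coefficients: dict = field(default_factory=_default_initiation_coefficients)
    persistence_coefficients: dict = field(default_factory=_default_persistence_coefficients)
    n_providers: int = 200
    provider_random_effect_sd: float = 0.3
    missingness_rates: dict = field(
        default_factory=lambda: {"smoking": 0.084, "max_ldl": 0.090,
                                 "baseline_bmi": 0.144})
    study_window: tuple = (dt.date(2000, 1, 1), dt.date(2011, 12, 31))
    seed: int = 12345
    auxiliary_params_by_sex: dict = field(default_factory=_default_auxiliary)

    # ------------------------------------------------------------------ #

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1:
            raise ConfigError("n_patients", "must be >= 1")
        if self.n_providers < 1:
            raise ConfigError("n_providers", "must be >= 1")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ConfigError("frac_female", "must lie in [0, 1]")
        if self.provider_random_effect_sd < 0:
            raise ConfigError("provider_random_effect_sd", "must be >= 0")
        for sex in SEXES:
            params = self.age_params_by_sex.get(sex)
            if params is None or params.get("sd", -1) <= 0:
                raise ConfigError("age_params_by_sex",
                                  f"missing or non-positive SD for {sex!r}")
        for cov, by_sex in self.covariate_prevalences_by_sex.items():
            for sex in SEXES:
                p = by_sex.get(sex)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        "covariate_prevalences_by_sex",
                        f"prevalence of {cov!r} for {sex!r} must lie in [0, 1]")
        for sex in SEXES:
            p = self.adverse_reaction_prevalence_by_sex.get(sex)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError("adverse_reaction_prevalence_by_sex",
                                  f"proportion for {sex!r} must lie in [0, 1]")
        for name, coefs in (("initiation_coefficients", self.initiation_coefficients),
                            ("persistence_coefficients", self.persistence_coefficients)):
            if "intercept" not in coefs:
                raise ConfigError(name, "missing intercept")
            offsets = coefs.get("age_group", [0.0] * len(AGE_BIN_LABELS))
            if len(offsets) != len(AGE_BIN_LABELS):
                raise ConfigError(
                    name, f"age_group needs {len(AGE_BIN_LABELS)} offsets")
        for var, rate in self.missingness_rates.items():
            if var not in ("smoking", "max_ldl", "baseline_bmi"):
                raise ConfigError("missingness_rates", f"unknown variable {var!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("missingness_rates",
                                  f"rate for {var!r} must lie in [0, 1]")
        start, end = self.study_window
        if not start < end:
            raise ConfigError("study_window", "start must precede end")
        return self

    def replace(self, **changes: Any) -> "CohortConfig":
        """Deep-copying variant of :func:`dataclasses.replace`."""
        base = copy.deepcopy(dataclasses.asdict(self))
        base.update(changes)
        return CohortConfig(**base)

    # ----------------------------- serialization ---------------------- #

    def to_dict(self) -> dict:
        d = copy.deepcopy(dataclasses.asdict(self))
        start, end = self.study_window
        d["study_window"] = [start.isoformat(), end.isoformat()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = copy.deepcopy(d)
        if "study_window" in d:
            start, end = d["study_window"]
            if isinstance(start, str):
                start = dt.date.fromisoformat(start)
            if isinstance(end, str):
                end = dt.date.fromisoformat(end)
            d["study_window"] = (start, end)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
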