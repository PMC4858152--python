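"""Direct and two-level standardization of sex disparities.

The disparity in a binary event (statin initiation, or persistence) between
men and women is decomposed by re-weighting women's covariate distribution
to men's.  Writing ``w_m(s)`` for men's share of stratum ``s`` and ``r_w(s)``
for women's event rate within it, the adjusted probability for women is

    P_w_adj = sum_s w_m(s) * r_w(s)

and the decomposition identities are

    D_obs = P_m - P_w            (observed disparity)
    D_adj = P_m - P_w_adj        (adjusted disparity)
    explained = D_obs - D_adj
    fraction = explained / D_obs  (undefined when D_obs = 0)

Covariates defined only for statin users (reported adverse reactions) enter
through *two-level* standardization: within each stratum of the
everybody-covariates, women's rate is first re-weighted to men's
distribution of the users-only covariates in that stratum, and the
resulting stratum rates are then combined with men's first-level weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "DisparityResult",
    "standardize_strata",
    "stratum_weights",
    "direct_standardize",
    "two_level_standardize",
    "decomposition_suite",
    "default_plan",
    "fraction_statistic",
]


class SpecificationError(ValueError):
    """A covariate specification inconsistent with the requested analysis."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of a standardization covariate.

    Parameters
    ----------
    name
        Column name in the analysis table.
    level
        ``"all_subjects"`` for covariates defined for everyone,
        ``"statin_users_only"`` for covariates defined only among users
        (e.g. reported adverse reactions to statins).
    kind
        ``"binary"``, ``"categorical"``, or ``"binned_continuous"``.
    bins
        Strictly increasing interior cut points; required (and only allowed)
        for ``binned_continuous``.
    """

    name: str
    level: str = "all_subjects"
    kind: str = "binary"
    bins: tuple | None = None

    def __post_init__(self):
        if self.level not in ("all_subjects", "statin_users_only"):
            raise SpecificationError(f"unknown level {self.level!r}")
        if self.kind not in ("binary", "categorical", "binned_continuous"):
            raise SpecificationError(f"unknown kind {self.kind!r}")
        if self.kind == "binned_continuous":
            if not self.bins:
                raise SpecificationError(
                    f"{self.name}: binned_continuous requires >= 1 cut point")
            arr = np.asarray(self.bins, dtype=float)
            if not np.all(np.diff(arr) > 0):
                raise SpecificationError(
                    f"{self.name}: bins must be strictly increasing")
        elif self.bins is not None:
            raise SpecificationError(
                f"{self.name}: bins only valid for binned_continuous")


@dataclass
class DisparityResult:
    """One standardization run: observed and adjusted probabilities and the
    decomposition identities.  ``fraction`` is ``None`` when the observed
    disparity is exactly zero."""

    event: str
    covariates: tuple[str, ...]
    p_m: float
    p_w: float
    p_w_adj: float
    d_obs: float = field(init=False)
    d_adj: float = field(init=False)
    explained: float = field(init=False)
    fraction: float | None = field(init=False)
    dropped_strata: list = field(default_factory=list)
    n_men: int = 0
    n_women: int = 0
    population: str = "all"

    def __post_init__(self):
        self.d_obs = self.p_m - self.p_w
        self.d_adj = self.p_m - self.p_w_adj
        self.explained = self.d_obs - self.d_adj
        self.fraction = self.explained / self.d_obs if self.d_obs != 0 else None

    def as_dict(self) -> dict:
        return {
            "event": self.event,
            "population": self.population,
            "covariates": "+".join(self.covariates) if self.covariates else "(none)",
            "p_m": self.p_m,
            "p_w": self.p_w,
            "p_w_adj": self.p_w_adj,
            "d_obs": self.d_obs,
            "d_adj": self.d_adj,
            "explained": self.explained,
            "fraction": self.fraction,
            "fraction_pct": None if self.fraction is None else round(100 * self.fraction, 1),
            "n_dropped_strata": len(self.dropped_strata),
            "n_men": self.n_men,
            "n_women": self.n_women,
        }


# --------------------------------------------------------------------- #
# stratum encoding
# --------------------------------------------------------------------- #

def _discretize(values: pd.Series, spec: CovariateSpec) -> pd.Series:
    if spec.kind == "binned_continuous":
        edges = [-np.inf, *spec.bins, np.inf]
        return pd.cut(values.astype(float), bins=edges)
    return values


def _encode_strata(df: pd.DataFrame, specs: Sequence[CovariateSpec]):
    """Integer stratum codes for the cross-classification of ``specs``.

    Returns ``(codes, valid, n_strata, labels)``; rows with a missing value
    in any covariate have ``valid`` False and must be excluded by callers.
    """
    n = len(df)
    if not specs:
        return np.zeros(n, dtype=np.int64), np.ones(n, dtype=bool), 1, [()]
    per_cov_codes, per_cov_labels, sizes = [], [], []
    valid = np.ones(n, dtype=bool)
    for spec in specs:
        if spec.name not in df.columns:
            raise SpecificationError(f"unknown covariate {spec.name!r}")
        codes, uniques = pd.factorize(_discretize(df[spec.name], spec),
                                      use_na_sentinel=True)
        valid &= codes >= 0
        per_cov_codes.append(codes)
        per_cov_labels.append(list(uniques))
        sizes.append(max(len(uniques), 1))
    combined = np.zeros(n, dtype=np.int64)
    for codes, size in zip(per_cov_codes, sizes):
        combined = combined * size + np.where(codes >= 0, codes, 0)
    n_strata = int(np.prod(sizes))
    labels = _stratum_labels(per_cov_labels, sizes)
    return combined, valid, n_strata, labels


def _stratum_labels(per_cov_labels, sizes):
    labels = [()]
    for lvls, size in zip(per_cov_labels, sizes):
        padded = list(lvls) + [None] * (size - len(lvls))
        labels = [prev + (lvl,) for prev in labels for lvl in padded]
    return labels


# --------------------------------------------------------------------- #
# pure standardization arithmetic
# --------------------------------------------------------------------- #

def standardize_strata(men_weights, women_rates):
    """Combine men's stratum weights with women's stratum event rates.

    Strata with positive men's weight but an undefined (NaN) women's rate —
    no women observed there — are dropped from the reference distribution
    and the remaining men's weights renormalized.  Returns
    ``(p_w_adj, dropped_indices)``.
    """
    men_weights = np.asarray(men_weights, dtype=float)
    women_rates = np.asarray(women_rates, dtype=float)
    if men_weights.shape != women_rates.shape:
        raise ValueError("weight/rate arrays must align")
    active = men_weights > 0
    undefined = active & np.isnan(women_rates)
    keep = active & ~undefined
    total = men_weights[keep].sum()
    if total <= 0:
        raise ValueError("no stratum with both men's weight and a women's rate")
    p_w_adj = float(np.dot(men_weights[keep] / total, women_rates[keep]))
    return p_w_adj, list(np.nonzero(undefined)[0])


def stratum_weights(df: pd.DataFrame, covariates: Sequence[CovariateSpec],
                    sex: str, sex_col: str = "sex") -> pd.Series:
    """Empirical joint distribution of the covariate cross-classification
    within one sex.  Weights are nonnegative and sum to one."""
    group = df[df[sex_col] == sex]
    if len(group) == 0:
        raise ValueError(f"no rows for sex {sex!r}")
    codes, valid, n_strata, labels = _encode_strata(group, covariates)
    counts = np.bincount(codes[valid], minlength=n_strata).astype(float)
    if counts.sum() == 0:
        raise ValueError("all rows have missing covariate values")
    weights = counts / counts.sum()
    index = pd.MultiIndex.from_tuples(labels, names=[c.name for c in covariates]) \
        if covariates else pd.Index([()])
    return pd.Series(weights, index=index, name="weight")


def _counts_and_rates(codes, valid, n_strata, female, y):
    men = valid & ~female
    women = valid & female
    men_counts = np.bincount(codes[men], minlength=n_strata).astype(float)
    women_counts = np.bincount(codes[women], minlength=n_strata).astype(float)
    women_events = np.bincount(codes[women], weights=y[women], minlength=n_strata)
    with np.errstate(invalid="ignore"):
        women_rates = np.where(women_counts > 0, women_events / np.maximum(women_counts, 1), np.nan)
    return men_counts, women_counts, women_rates


# --------------------------------------------------------------------- #
# estimators
# --------------------------------------------------------------------- #

def _check_levels(specs: Iterable[CovariateSpec], level: str, where: str):
    for s in specs:
        if s.level != level:
            raise SpecificationError(
                f"covariate {s.name!r} has level {s.level!r}; {where} requires {level!r}")


def direct_standardize(df: pd.DataFrame, event: str,
                       covariates: Sequence[CovariateSpec],
                       sex_col: str = "sex",
                       population: str = "all") -> DisparityResult:
    """Single-level direct standardization of women's covariate distribution
    to men's.

    Rows with a missing event value are excluded (this is how persistence
    among users is analyzed: persistence is undefined for non-users).  Rows
    missing a standardization covariate are likewise excluded.
    """
    _check_levels(covariates, "all_subjects", "direct_standardize")
    sub = df[df[event].notna()]
    female = (sub[sex_col] == "female").to_numpy()
    y = sub[event].astype(bool).to_numpy().astype(float)
    codes, valid, n_strata, labels = _encode_strata(sub, covariates)
    men_counts, women_counts, women_rates = _counts_and_rates(
        codes, valid, n_strata, female, y)
    n_men, n_women = int(men_counts.sum()), int(women_counts.sum())
    if n_men == 0 or n_women == 0:
        raise ValueError("both sexes must be present")
    p_m = float(np.bincount(codes[valid & ~female], weights=y[valid & ~female],
                            minlength=n_strata).sum() / n_men)
    p_w = float(np.nansum(women_rates * women_counts) / n_women)
    p_w_adj, dropped = standardize_strata(men_counts / n_men, women_rates)
    return DisparityResult(
        event=event, covariates=tuple(c.name for c in covariates),
        p_m=p_m, p_w=p_w, p_w_adj=p_w_adj,
        dropped_strata=[labels[i] for i in dropped],
        n_men=n_men, n_women=n_women, population=population)


def two_level_standardize(df: pd.DataFrame, event: str,
                          level1: Sequence[CovariateSpec],
                          level2: Sequence[CovariateSpec],
                          sex_col: str = "sex",
                          population: str = "users",
                          use_col: str = "statin_use") -> DisparityResult:
    """Two-level standardization for covariates defined only on statin users.

    First level: covariates defined for every subject.  Second level: within
    each first-level stratum, women's event rate among users is re-weighted
    to men's distribution of the users-only covariates in that stratum.

    ``population="users"`` analyzes persistence among statin users.
    ``population="all"`` reports persistence against the whole cohort via the
    composition  P(persistent) = P(initiate) * P(persist | initiate): the
    users-only covariates adjust the persistence factor while the initiation
    factor retains women's observed rates.
    """
    _check_levels(level1, "all_subjects", "level 1")
    _check_levels(level2, "statin_users_only", "level 2")
    if not level2:
        if population == "users":
            users = df[df[use_col].fillna(False).astype(bool)]
            return direct_standardize(users, event, level1, sex_col,
                                      population="users")
        # whole-cohort base: the event is "initiated AND persisted"
        overall = (df[use_col].fillna(False).astype(bool)
                   & df[event].fillna(False).astype(bool))
        res = direct_standardize(df.assign(_overall_event=overall),
                                 "_overall_event", level1, sex_col,
                                 population="all")
        res.event = event
        return res

    covnames = tuple(c.name for c in level1) + tuple(c.name for c in level2)
    users = df[df[use_col].fillna(False).astype(bool)]
    fem_u = (users[sex_col] == "female").to_numpy()
    y_u = users[event].astype(bool).to_numpy().astype(float)
    codes1_u, valid1_u, K1, labels1 = _encode_strata(users, level1)
    codes2_u, valid2_u, K2, _ = _encode_strata(users, level2)
    valid_u = valid1_u & valid2_u & users[event].notna().to_numpy()
    joint = codes1_u * K2 + codes2_u

    men_u = valid_u & ~fem_u
    women_u = valid_u & fem_u
    men_joint = np.bincount(joint[men_u], minlength=K1 * K2).astype(float).reshape(K1, K2)
    women_joint = np.bincount(joint[women_u], minlength=K1 * K2).astype(float).reshape(K1, K2)
    women_joint_events = np.bincount(
        joint[women_u], weights=y_u[women_u], minlength=K1 * K2).reshape(K1, K2)
    with np.errstate(invalid="ignore"):
        women_rates = np.where(women_joint > 0,
                               women_joint_events / np.maximum(women_joint, 1), np.nan)

    dropped: list = []
    inner = np.full(K1, np.nan)
    for c in range(K1):
        w_m = men_joint[c]
        if w_m.sum() == 0:
            continue
        active = w_m > 0
        undefined = active & np.isnan(women_rates[c])
        keep = active & ~undefined
        dropped.extend((labels1[c], t) for t in np.nonzero(undefined)[0])
        if keep.sum() == 0 or women_joint[c].sum() == 0:
            inner[c] = np.nan  # no women users in this stratum at all
            continue
        inner[c] = np.dot(w_m[keep] / w_m[keep].sum(), women_rates[c][keep])

    if population == "users":
        men_l1 = men_joint.sum(axis=1)
        n_men, n_women = int(men_l1.sum()), int(women_joint.sum())
        p_m = float(np.bincount(codes1_u[men_u], weights=y_u[men_u],
                                minlength=K1).sum() / n_men)
        p_w = float(women_joint_events.sum() / n_women)
        p_w_adj, dropped1 = standardize_strata(men_l1 / men_l1.sum(), inner)
        dropped.extend(labels1[i] for i in dropped1)
        return DisparityResult(event=event, covariates=covnames,
                               p_m=p_m, p_w=p_w, p_w_adj=p_w_adj,
                               dropped_strata=dropped,
                               n_men=n_men, n_women=n_women, population="users")

    if population != "all":
        raise SpecificationError(f"unknown population {population!r}")

    # Whole-cohort base: men's level-1 weights over all patients; women's
    # initiation rate per stratum composed with the adjusted persistence rate.
    female_a = (df[sex_col] == "female").to_numpy()
    use_a = df[use_col].fillna(False).astype(bool).to_numpy().astype(float)
    overall_event = (df[use_col].fillna(False).astype(bool)
                     & df[event].fillna(False).astype(bool)).to_numpy().astype(float)
    codes1_a, valid1_a, K1a, labels1a = _encode_strata(df, level1)
    assert K1a == K1
    men_a = valid1_a & ~female_a
    women_a = valid1_a & female_a
    men_l1_all = np.bincount(codes1_a[men_a], minlength=K1).astype(float)
    women_l1_all = np.bincount(codes1_a[women_a], minlength=K1).astype(float)
    women_init = np.bincount(codes1_a[women_a], weights=use_a[women_a], minlength=K1)
    with np.errstate(invalid="ignore"):
        women_init_rate = np.where(women_l1_all > 0,
                                   women_init / np.maximum(women_l1_all, 1), np.nan)
    composed = women_init_rate * inner
    n_men, n_women = int(men_l1_all.sum()), int(women_l1_all.sum())
    p_m = float(overall_event[men_a].sum() / n_men)
    p_w = float(overall_event[women_a].sum() / n_women)
    p_w_adj, dropped1 = standardize_strata(men_l1_all / n_men, composed)
    dropped.extend(labels1a[i] for i in dropped1)
    return DisparityResult(event=event, covariates=covnames,
                           p_m=p_m, p_w=p_w, p_w_adj=p_w_adj,
                           dropped_strata=dropped,
                           n_men=n_men, n_women=n_women, population="all")


# --------------------------------------------------------------------- #
# decomposition plans
# --------------------------------------------------------------------- #

AGE_SPEC = CovariateSpec("age_group", kind="categorical")
SMOKING_SPEC = CovariateSpec("ever_smoker", kind="binary")
CARDIOLOGY_SPEC = CovariateSpec("cardiology_evaluated", kind="binary")
ADVERSE_SPEC = CovariateSpec("adverse_reaction", level="statin_users_only",
                             kind="binary")


@dataclass(frozen=True)
class DecompositionTask:
    name: str
    event: str
    level1: tuple[CovariateSpec, ...]
    level2: tuple[CovariateSpec, ...] = ()
    population: str = "all"


def default_plan() -> list[DecompositionTask]:
    """The decomposition plan of the study: for statin use, age group,
    smoking and cardiology evaluation singly and jointly; for persistence,
    those plus reported adverse reactions (two-level), reported both among
    users and against the whole cohort."""
    l1 = {"age_group": AGE_SPEC, "ever_smoker": SMOKING_SPEC,
          "cardiology_evaluated": CARDIOLOGY_SPEC}
    plan = []
    for name, spec in l1.items():
        plan.append(DecompositionTask(f"use:{name}", "statin_use", (spec,)))
    plan.append(DecompositionTask("use:joint", "statin_use", tuple(l1.values())))
    for pop in ("users", "all"):
        for name, spec in l1.items():
            plan.append(DecompositionTask(
                f"persistence[{pop}]:{name}", "persistent", (spec,), (), pop))
        plan.append(DecompositionTask(
            f"persistence[{pop}]:adverse_reaction", "persistent", (),
            (ADVERSE_SPEC,), pop))
        plan.append(DecompositionTask(
            f"persistence[{pop}]:joint", "persistent", tuple(l1.values()),
            (ADVERSE_SPEC,), pop))
    return plan


def run_task(df: pd.DataFrame, task: DecompositionTask) -> DisparityResult:
    composed = task.event == "persistent"  # undefined for non-users
    if task.level2 or task.population == "users" or composed:
        return two_level_standardize(df, task.event, task.level1, task.level2,
                                     population=task.population)
    return direct_standardize(df, task.event, task.level1,
                              population=task.population)


def decomposition_suite(df: pd.DataFrame,
                        plan: Sequence[DecompositionTask] | None = None
                        ) -> pd.DataFrame:
    """Run every task in ``plan`` (default: the study plan) and return a tidy
    table with one row per covariate set."""
    plan = list(plan) if plan is not None else default_plan()
    rows = []
    for task in plan:
        res = run_task(df, task)
        d = res.as_dict()
        d["set"] = task.name
        rows.append(d)
    out = pd.DataFrame(rows)
    return out[["set"] + [c for c in out.columns if c != "set"]]


def fraction_statistic(task: DecompositionTask) -> Callable[[pd.DataFrame], float]:
    """Statistic (for bootstrapping) returning the explained fraction of a
    decomposition task; NaN when the observed disparity vanishes."""
    def stat(df: pd.DataFrame) -> float:
        res = run_task(df, task)
        return np.nan if res.fraction is None else res.fraction
    return stat
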