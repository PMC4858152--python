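"""Exact population-level disparity decomposition for a generator config.

Enumerates the finite covariate strata implied by a :class:`CohortConfig`
(age group x all binary covariates), integrates the provider random effect
by Gauss-Hermite quadrature, and evaluates the same standardization
estimands the empirical estimators target.  Serves as the ground truth for
parameter-recovery and bootstrap-calibration experiments: no sampling is
involved anywhere.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .config import AGE_BIN_EDGES, AGE_BIN_LABELS, CohortConfig
from .synthetic import AGE_MAX, AGE_MIN, linear_predictor

__all__ = ["population_structure", "true_disparity", "generate_true_decomposition"]

_GH_NODES = 61

#: Covariates the enumeration can standardize on; all are discrete (age is
#: always handled through the standard six-bin grouping — continuous
#: covariates without a discretization rule are rejected).
STANDARDIZABLE = ("age_group", "ever_smoker", "cardiology_evaluated",
                  "diabetes", "family_history_cad", "cabg", "mi")

#: Analysis-table names whose generator-side marginals go by another key.
_GENERATOR_NAME = {"ever_smoker": "smoking"}


class OracleError(ValueError):
    pass


def _age_bin_probs(mean: float, sd: float) -> np.ndarray:
    edges = np.array([*AGE_BIN_EDGES, AGE_MAX], dtype=float)
    z = norm.cdf((edges - mean) / sd)
    probs = np.diff(z) / (norm.cdf((AGE_MAX - mean) / sd)
                          - norm.cdf((AGE_MIN - mean) / sd))
    return probs / probs.sum()


def _mixed_mean(lp: np.ndarray, sd: float, lp2: np.ndarray | None = None) -> np.ndarray:
    """E over u ~ N(0, sd) of expit(lp + u) [* expit(lp2 + u)]."""
    if sd == 0:
        out = expit(lp)
        return out * expit(lp2) if lp2 is not None else out
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    u = np.sqrt(2.0) * sd * x
    w = w / np.sqrt(np.pi)
    vals = expit(lp[..., None] + u)
    if lp2 is not None:
        vals = vals * expit(lp2[..., None] + u)
    return vals @ w


def population_structure(config: CohortConfig) -> dict:
    """Stratum grid, per-sex stratum weights, and exact event probabilities.

    Returns arrays over the full cross-classification S = 6 age groups x
    2^k binary covariates, per sex (index 0 = male, 1 = female):
    ``weights[sex, s]``, ``p_init[sex, s]``,
    ``p_joint[a][sex, s]`` = P(initiate AND persist | stratum, adverse = a).
    """
    config.validate()
    cov_names = sorted(config.covariate_prevalences_by_sex)
    sizes = [len(AGE_BIN_LABELS)] + [2] * len(cov_names)
    grid = np.indices(sizes).reshape(len(sizes), -1)
    age_idx = grid[0]
    levels = {name: grid[1 + i] for i, name in enumerate(cov_names)}
    n_strata = grid.shape[1]

    weights = np.zeros((2, n_strata))
    p_init = np.zeros((2, n_strata))
    p_joint = {0: np.zeros((2, n_strata)), 1: np.zeros((2, n_strata))}
    sd = config.provider_random_effect_sd
    for si, sex in enumerate(("male", "female")):
        ap = config.age_params_by_sex[sex]
        w = _age_bin_probs(ap["mean"], ap["sd"])[age_idx].astype(float)
        for name in cov_names:
            p = config.covariate_prevalences_by_sex[name][sex]
            w = w * np.where(levels[name] == 1, p, 1.0 - p)
        weights[si] = w
        female = np.full(n_strata, si == 1)
        lp_i = linear_predictor(config.initiation_coefficients, female,
                                age_idx, levels)
        p_init[si] = _mixed_mean(lp_i, sd)
        for a in (0, 1):
            lp_p = linear_predictor(config.persistence_coefficients, female,
                                    age_idx, levels,
                                    adverse=np.full(n_strata, a))
            p_joint[a][si] = _mixed_mean(lp_i, sd, lp_p)

    q_adv = np.array([config.adverse_reaction_prevalence_by_sex["male"],
                      config.adverse_reaction_prevalence_by_sex["female"]])
    return {
        "age_idx": age_idx, "levels": levels, "n_strata": n_strata,
        "weights": weights, "p_init": p_init, "p_joint": p_joint,
        "q_adverse": q_adv, "cov_names": cov_names,
    }


def _subset_codes(struct: dict, covariates: tuple[str, ...]) -> tuple[np.ndarray, int]:
    code = np.zeros(struct["n_strata"], dtype=np.int64)
    size = 1
    for name in covariates:
        if name not in STANDARDIZABLE:
            raise OracleError(
                f"covariate {name!r} has no discretization rule for enumeration")
        if name == "age_group":
            vals, k = struct["age_idx"], len(AGE_BIN_LABELS)
        else:
            key = _GENERATOR_NAME.get(name, name)
            if key not in struct["levels"]:
                raise OracleError(f"unknown covariate {name!r}")
            vals, k = struct["levels"][key], 2
        code = code * k + vals
        size *= k
    return code, size


def _aggregate(code, size, weights, values) -> tuple[np.ndarray, np.ndarray]:
    """Collapse full-stratum weights and weight-averaged values to a subset
    cross-classification."""
    w = np.bincount(code, weights=weights, minlength=size)
    wv = np.bincount(code, weights=weights * values, minlength=size)
    with np.errstate(invalid="ignore"):
        rates = np.where(w > 0, wv / np.where(w > 0, w, 1.0), np.nan)
    return w, rates


def true_disparity(config_or_struct, event: str,
                   covariates: tuple[str, ...] = (),
                   include_adverse: bool = False,
                   population: str = "all") -> dict:
    """Exact observed/adjusted probabilities and explained fraction for one
    standardization task under the generative model.

    ``event`` is ``"use"`` or ``"persistence"``; ``include_adverse`` adds
    reported adverse reactions as a users-only (second-level) covariate.
    Returns a dict with keys p_m, p_w, p_w_adj, d_obs, d_adj, explained,
    fraction (None when d_obs == 0).
    """
    struct = (config_or_struct if isinstance(config_or_struct, dict)
              else population_structure(config_or_struct))
    w = struct["weights"]
    p_init = struct["p_init"]
    p_joint = struct["p_joint"]
    q = struct["q_adverse"]
    code, size = _subset_codes(struct, covariates)

    if event == "use":
        if include_adverse:
            raise OracleError("adverse reactions are undefined for non-users")
        p_sex = p_init
        base_w = w
    elif event == "persistence" and population == "users":
        base_w = w * p_init  # users' stratum distribution (unnormalized)
        with np.errstate(invalid="ignore"):
            pers_a = {a: p_joint[a] / p_init for a in (0, 1)}
        p_sex = np.stack([(1 - q[si]) * pers_a[0][si] + q[si] * pers_a[1][si]
                          for si in (0, 1)])
    elif event == "persistence" and population == "all":
        base_w = w
        p_sex = np.stack([(1 - q[si]) * p_joint[0][si] + q[si] * p_joint[1][si]
                          for si in (0, 1)])
    else:
        raise OracleError(f"unknown event/population {event!r}/{population!r}")

    totals = base_w.sum(axis=1)
    p_m = float((base_w[0] * p_sex[0]).sum() / totals[0])
    p_w = float((base_w[1] * p_sex[1]).sum() / totals[1])

    if not include_adverse:
        wm, _ = _aggregate(code, size, base_w[0] / totals[0], p_sex[0])
        ww, rates_w = _aggregate(code, size, base_w[1] / totals[1], p_sex[1])
        keep = (wm > 0) & ~np.isnan(rates_w)
        p_w_adj = float((wm[keep] / wm[keep].sum() * rates_w[keep]).sum())
    else:
        # two-level: within each level-1 stratum, re-weight women's
        # persistence to men's adverse-reaction distribution among users
        user_w = w * p_init
        with np.errstate(invalid="ignore"):
            pers_a = {a: p_joint[a] / p_init for a in (0, 1)}
        # women's rate at each level-2 cell, combined with *men's* adverse
        # distribution among users (independent of stratum by design)
        inner_w = np.zeros(size)
        for a, arr in pers_a.items():
            m_share = q[0] if a == 1 else 1 - q[0]
            _, rate_a = _aggregate(code, size, user_w[1], arr[1])
            inner_w += m_share * np.nan_to_num(rate_a, nan=0.0)
        ww_users, _ = _aggregate(code, size, user_w[1], pers_a[0][1])
        if population == "users":
            wm_users, _ = _aggregate(code, size, user_w[0], pers_a[0][0])
            keep = (wm_users > 0) & (ww_users > 0)
            p_w_adj = float((wm_users[keep] / wm_users[keep].sum()
                             * inner_w[keep]).sum())
        else:
            wm_all, _ = _aggregate(code, size, base_w[0] / totals[0], p_sex[0])
            _, init_w = _aggregate(code, size, w[1], p_init[1])
            composed = init_w * inner_w
            keep = (wm_all > 0) & (ww_users > 0)
            p_w_adj = float((wm_all[keep] / wm_all[keep].sum()
                             * composed[keep]).sum())

    d_obs = p_m - p_w
    d_adj = p_m - p_w_adj
    explained = d_obs - d_adj
    return {
        "p_m": p_m, "p_w": p_w, "p_w_adj": p_w_adj,
        "d_obs": d_obs, "d_adj": d_adj, "explained": explained,
        "fraction": explained / d_obs if d_obs != 0 else None,
    }


def generate_true_decomposition(config: CohortConfig, event: str = "persistence",
                                population: str = "all") -> dict:
    """Explained fraction of each study covariate, and of the joint set, by
    exhaustive enumeration (no sampling).

    For statin use the covariates are age group, smoking and cardiology
    evaluation; for persistence, reported adverse reactions join via the
    second standardization level.
    """
    struct = population_structure(config)
    singles = ["age_group", "ever_smoker", "cardiology_evaluated"]
    out = {}
    for name in singles:
        out[name] = true_disparity(struct, event, (name,),
                                   population=population)["fraction"]
    if event == "persistence":
        out["adverse_reaction"] = true_disparity(
            struct, event, (), include_adverse=True,
            population=population)["fraction"]
        out["joint"] = true_disparity(struct, event, tuple(singles),
                                      include_adverse=True,
                                      population=population)["fraction"]
    else:
        out["joint"] = true_disparity(struct, event, tuple(singles),
                                      population=population)["fraction"]
    return out
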