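"""Multivariable logistic models with provider-cluster-robust inference.

Point estimates are ordinary maximum likelihood (IRLS); clustering within
primary-care providers is handled by a generalized-estimating-equations
formulation with independence working correlation, whose point estimates
coincide with ML and whose covariance is the sandwich estimator with scores
summed within provider.  Wald p-values use the cluster-robust covariance and
are adjusted for multiplicity by the Simes-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = ["FittedModel", "fit_logistic", "simes_hochberg_adjust", "build_design"]

MAX_ITER = 100
TOL = 1e-8
SEPARATION_BOUND = 20.0
_Z975 = norm.ppf(0.975)

#: Reference levels for categorical covariates (dropped dummy).
REFERENCE_LEVELS = {"race": "White", "sex": "male", "age_group": "18-44"}

#: Continuous covariates rescaled before entering the model; LDL is
#: expressed per 10 mg/dL.  Income is already in $1,000s, age in years.
SCALES = {"max_ldl": 0.1}

_SCALED_LABEL = {"max_ldl": "max_ldl_per_10"}


class ModelError(ValueError):
    pass


def build_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Encode covariates into a numeric design matrix with intercept.

    Booleans become 0/1 indicators; object/categorical columns become
    dummies against the declared reference level; numeric columns enter
    linearly after any declared rescaling.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for name in covariates:
        if name == "female":
            cols["female"] = (df["sex"] == "female").to_numpy(float)
            continue
        if name not in df.columns:
            raise ModelError(f"unknown covariate {name!r}")
        s = df[name]
        if s.dtype == bool or str(s.dtype) == "boolean":
            cols[name] = s.astype(float).to_numpy()
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()))
            ref = REFERENCE_LEVELS.get(name, levels[0])
            for lvl in levels:
                if lvl == ref:
                    continue
                cols[f"{name}[{lvl}]"] = (s == lvl).to_numpy(float)
        else:
            cols[_SCALED_LABEL.get(name, name)] = (
                s.to_numpy(float) * SCALES.get(name, 1.0))
    X = pd.DataFrame(cols, index=df.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelError("design matrix is rank deficient after encoding")
    return X


@dataclass
class FittedModel:
    """A fitted logistic model with model-based and cluster-robust
    covariances, odds ratios and multiplicity-adjusted p-values."""

    outcome: str
    terms: list[str]
    coefficients: np.ndarray
    covariance_model: np.ndarray
    covariance_cluster_robust: np.ndarray
    n_obs: int
    n_clusters: int
    converged: bool
    odds_ratios: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    p_values: np.ndarray = field(init=False)
    adjusted_p_values: np.ndarray = field(init=False)

    def __post_init__(self):
        se = np.sqrt(np.diag(self.covariance_cluster_robust))
        self.odds_ratios = np.exp(self.coefficients)
        self.ci_low = np.exp(self.coefficients - _Z975 * se)
        self.ci_high = np.exp(self.coefficients + _Z975 * se)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.coefficients / np.where(se > 0, se, 1.0), np.inf)
        self.p_values = 2 * norm.sf(np.abs(z))
        # intercept excluded from the multiplicity family
        adj = np.array(self.p_values, dtype=float)
        mask = np.array([t != "const" for t in self.terms])
        if mask.any():
            adj[mask] = simes_hochberg_adjust(self.p_values[mask])
        self.adjusted_p_values = adj

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coefficient": self.coefficients,
            "odds_ratio": self.odds_ratios,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_values,
            "p_adjusted": self.adjusted_p_values,
        })


def fit_logistic(df: pd.DataFrame, outcome: str, covariates: list[str],
                 cluster: str | None = "provider_id",
                 freq_weights: np.ndarray | None = None) -> FittedModel:
    """Fit a multivariable logistic model, optionally with cluster-robust
    covariance.

    Rows with a missing outcome or covariate are dropped.  With ``cluster``
    None, the robust covariance is the heteroskedasticity-robust (HC0)
    sandwich, equivalent to singleton clusters.
    """
    needed = [outcome] + [c for c in covariates if c != "female"] \
        + (["sex"] if "female" in covariates else []) \
        + ([cluster] if cluster else [])
    sub = df.dropna(subset=[c for c in needed if c in df.columns])
    y = sub[outcome].astype(bool).to_numpy(float)
    if y.min() == y.max():
        raise ModelError("outcome must have both classes")
    X = build_design(sub, covariates)
    model = sm.GLM(y, X, family=sm.families.Binomial(),
                   freq_weights=freq_weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=MAX_ITER, tol=TOL)
    if cluster is not None:
        groups = pd.factorize(sub[cluster])[0]
        n_clusters = int(groups.max()) + 1
        if n_clusters < 2:
            raise ModelError("cluster-robust covariance requires >= 2 clusters")
    else:
        groups = np.arange(len(sub))
        n_clusters = len(sub)
    cov_robust = _cluster_sandwich(
        X.to_numpy(), y, np.asarray(res.fittedvalues), groups,
        np.asarray(res.cov_params()),
        np.ones(len(sub)) if freq_weights is None else np.asarray(freq_weights, float))
    converged = bool(res.converged) and bool(
        np.all(np.abs(res.params) <= SEPARATION_BOUND))
    return FittedModel(
        outcome=outcome,
        terms=list(X.columns),
        coefficients=np.asarray(res.params),
        covariance_model=np.asarray(res.cov_params()),
        covariance_cluster_robust=cov_robust,
        n_obs=len(sub),
        n_clusters=n_clusters,
        converged=converged,
    )


def _cluster_sandwich(X, y, mu, groups, bread, weights) -> np.ndarray:
    """Sandwich covariance with scores summed within cluster and no
    finite-sample scaling (GEE, independence working correlation).  With
    singleton clusters this is exactly the HC0 heteroskedasticity-robust
    estimator."""
    scores = X * (weights * (y - mu))[:, None]
    k = X.shape[1]
    g = int(groups.max()) + 1
    cluster_scores = np.zeros((g, k))
    np.add.at(cluster_scores, groups, scores)
    meat = cluster_scores.T @ cluster_scores
    return bread @ meat @ bread


def simes_hochberg_adjust(p_values) -> np.ndarray:
    """Simes-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size <= 1:
        return p.copy()
    return multipletests(p, method="simes-hochberg")[1]
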