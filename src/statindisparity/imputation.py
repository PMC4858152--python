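"""Multiple imputation by chained equations for the three incompletely
observed covariates (smoking history, maximum LDL-C, baseline BMI), and
Rubin's rules for pooling per-imputation estimates.

The imputation models condition on sex, age, diabetes, cardiology
evaluation, the outcomes, and the other two imputed variables: a Bayesian
logistic draw for smoking and normal linear draws for LDL and BMI, cycled
ten times per completed dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ImputationSet", "PooledEstimate", "impute", "pool_estimates"]

IMPUTED_VARIABLES = ("ever_smoker", "max_ldl", "baseline_bmi")
N_CYCLES = 10
DEFAULT_M = 20


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSet:
    m: int
    completed_datasets: list  # of DataFrame
    seed: int
    variables: tuple = IMPUTED_VARIABLES

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for j, df in enumerate(self.completed_datasets):
            df.to_csv(outdir / f"imputation_{j:02d}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(
            {"m": self.m, "seed": self.seed,
             "variables": list(self.variables)}, indent=2))


@dataclass
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float


def _predictor_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Design matrix for one imputation model: intercept, sex, age,
    diagnoses, outcomes, and the other two working imputed variables."""
    cols = [np.ones(len(df))]
    cols.append((df["sex"] == "female").to_numpy(float))
    cols.append(df["age_at_entry"].to_numpy(float) / 10.0)
    for c in ("diabetes", "cardiology_evaluated", "statin_use"):
        if c in df.columns:
            cols.append(df[c].fillna(False).astype(bool).to_numpy(float))
    if "persistent" in df.columns:
        cols.append(df["persistent"].fillna(False).astype(bool).to_numpy(float))
    for var in IMPUTED_VARIABLES:
        if var == exclude or var not in df.columns:
            continue
        v = df[f"_work_{var}"].to_numpy(float)
        cols.append(v / 10.0 if var != "ever_smoker" else v)
    return np.column_stack(cols)


def _draw_coefficients(beta: np.ndarray, cov: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        return beta
    return beta + chol @ rng.standard_normal(len(beta))


def _impute_once(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One completed dataset: initialize missing entries from the observed
    empirical distribution, then cycle the three conditional models."""
    work = df.copy()
    observed = {}
    for var in IMPUTED_VARIABLES:
        obs_mask = work[var].notna().to_numpy()
        observed[var] = obs_mask
        vals = work[var].astype(float).to_numpy()
        n_mis = int((~obs_mask).sum())
        if n_mis:
            vals[~obs_mask] = rng.choice(vals[obs_mask], size=n_mis, replace=True)
        work[f"_work_{var}"] = vals

    for _ in range(N_CYCLES):
        for var in IMPUTED_VARIABLES:
            obs = observed[var]
            if obs.all():
                continue
            X = _predictor_matrix(work, exclude=var)
            y = work[f"_work_{var}"].to_numpy(float)
            if var == "ever_smoker":
                model = sm.GLM(y[obs], X[obs], family=sm.families.Binomial())
                res = model.fit(maxiter=50)
                beta = _draw_coefficients(res.params, res.cov_params(), rng)
                p = 1.0 / (1.0 + np.exp(-(X[~obs] @ beta)))
                y[~obs] = (rng.random((~obs).sum()) < p).astype(float)
            else:
                Xo, yo = X[obs], y[obs]
                beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
                resid = yo - Xo @ beta_hat
                dof = max(len(yo) - Xo.shape[1], 1)
                sigma2 = (resid @ resid) / rng.chisquare(dof)
                xtx_inv = np.linalg.pinv(Xo.T @ Xo)
                beta = _draw_coefficients(beta_hat, sigma2 * xtx_inv, rng)
                y[~obs] = X[~obs] @ beta + np.sqrt(sigma2) * rng.standard_normal((~obs).sum())
            work[f"_work_{var}"] = y

    out = df.copy()
    for var in IMPUTED_VARIABLES:
        filled = work[f"_work_{var}"]
        if var == "ever_smoker":
            out[var] = pd.array(filled.to_numpy() > 0.5, dtype="boolean")
        else:
            out[var] = filled.to_numpy(float)
    return out


def impute(rows: pd.DataFrame, m: int = DEFAULT_M, seed: int = 0) -> ImputationSet:
    """Chained-equations multiple imputation producing ``m`` completed
    datasets.  Observed values are identical across datasets; draws differ.
    A variable that is missing for every row makes its model unidentifiable
    and raises :class:`ImputationError`."""
    if m < 2:
        raise ImputationError("m must be >= 2")
    present = [v for v in IMPUTED_VARIABLES if v in rows.columns]
    for var in present:
        if rows[var].isna().all():
            raise ImputationError(f"variable {var!r} is 100% missing")
    any_missing = any(rows[var].isna().any() for var in present)
    if not any_missing:
        return ImputationSet(m=m, completed_datasets=[rows.copy() for _ in range(m)],
                             seed=seed)
    children = np.random.SeedSequence(seed).spawn(m)
    datasets = [_impute_once(rows, np.random.default_rng(ss)) for ss in children]
    return ImputationSet(m=m, completed_datasets=datasets, seed=seed)


def pool_estimates(estimates, variances) -> PooledEstimate:
    """Rubin's rules: pooled point estimate, total variance
    T = W + (1 + 1/m) B, and the standard small-sample degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances must have equal length")
    if len(q) < 2:
        raise ValueError("pooling requires m >= 2")
    if np.any(w < 0):
        raise ValueError("variances must be nonnegative")
    m = len(q)
    qbar = float(q.mean())
    b = float(q.var(ddof=1))
    wbar = float(w.mean())
    total = wbar + (1 + 1 / m) * b
    if b == 0:
        dof = float("inf")
    else:
        dof = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
    return PooledEstimate(estimate=qbar, within_variance=wbar,
                          between_variance=b, total_variance=total, df=dof)
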