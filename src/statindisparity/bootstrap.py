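"""Sex-stratified bootstrap for standardization outputs.

Each replicate resamples patients with replacement separately within men
and within women, preserving each sex's sample size, and recomputes the
statistic end-to-end (stratum weights included).  Variances are sample
variances of the replicates; intervals are 95% percentile intervals.
Replicates where the statistic is undefined (observed disparity exactly
zero) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BootstrapResult", "stratified_bootstrap"]

DEFAULT_N_BOOT = 1000


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    statistic_name: str
    point_estimate: float
    replicates: np.ndarray
    variance: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_degenerate: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "estimate": self.point_estimate,
            "variance": self.variance,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "n_degenerate": self.n_degenerate,
            "seed": self.seed,
        }


def stratified_bootstrap(df: pd.DataFrame, statistic, n_boot: int = DEFAULT_N_BOOT,
                         seed: int = 0, sex_col: str = "sex",
                         cluster_col: str | None = None,
                         name: str = "statistic") -> BootstrapResult:
    """Bootstrap a statistic of the analysis table, stratified by sex.

    ``statistic`` maps a DataFrame to a float (NaN marks a degenerate
    replicate).  With ``cluster_col`` set, whole provider clusters are
    resampled within each sex instead of individual patients (an option;
    patients are the default resampling unit).
    """
    if n_boot < 2:
        raise BootstrapError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    point = float(statistic(df))

    strata_indices = [np.flatnonzero((df[sex_col] == s).to_numpy())
                      for s in ("male", "female")]
    if any(len(ix) == 0 for ix in strata_indices):
        raise BootstrapError("both sexes must be present")

    cluster_map = None
    if cluster_col is not None:
        cluster_map = []
        for ix in strata_indices:
            codes = pd.factorize(df.iloc[ix][cluster_col])[0]
            members = [ix[codes == c] for c in range(codes.max() + 1)]
            cluster_map.append(members)

    reps = np.empty(n_boot)
    for b in range(n_boot):
        parts = []
        for k, ix in enumerate(strata_indices):
            if cluster_map is None:
                parts.append(ix[rng.integers(0, len(ix), len(ix))])
            else:
                members = cluster_map[k]
                chosen = rng.integers(0, len(members), len(members))
                parts.append(np.concatenate([members[c] for c in chosen]))
        idx = np.concatenate(parts)
        reps[b] = statistic(df.iloc[idx])

    valid = reps[~np.isnan(reps)]
    n_degenerate = int(np.isnan(reps).sum())
    if len(valid) == 0:
        raise BootstrapError("every bootstrap replicate was degenerate")
    ci_low, ci_high = np.percentile(valid, [2.5, 97.5])
    return BootstrapResult(
        statistic_name=name,
        point_estimate=point,
        replicates=valid,
        variance=float(valid.var(ddof=1)) if len(valid) > 1 else 0.0,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n_degenerate=n_degenerate,
    )
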