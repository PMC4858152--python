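"""Cohort summary tables and worked-example percentage arithmetic.

Includes the published per-sex counts of the reference study population as
module-level constants; the percentage helpers reproduce the headline
proportions (initiation and persistence by sex, overall use, the cohort's
female share, and the relative initiation disparity) from those counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_COHORT_COUNTS",
    "percentage",
    "relative_disparity_pct",
    "headline_proportions",
    "table_one",
]

#: Per-sex counts of the reference CAD cohort (all patients).
REFERENCE_COHORT_COUNTS = {
    "patients": {"male": 15332, "female": 9006},
    "statin_use": {"male": 13453, "female": 7377},
    "persistent": {"male": 10940, "female": 6032},
}


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A percentage rounded to the reporting precision (one decimal)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, decimals)


def relative_disparity_pct(p_m: float, p_w: float, decimals: int = 1) -> float:
    """How much less likely women are than men, relative to men's
    probability: 100 * (p_m - p_w) / p_m."""
    if p_m == 0:
        raise ZeroDivisionError("men's probability is zero")
    return round(100.0 * (p_m - p_w) / p_m, decimals)


def headline_proportions(counts: dict = REFERENCE_COHORT_COUNTS) -> dict:
    """The study's headline proportions recomputed from per-sex counts."""
    n_m, n_w = counts["patients"]["male"], counts["patients"]["female"]
    use_m, use_w = counts["statin_use"]["male"], counts["statin_use"]["female"]
    per_m, per_w = counts["persistent"]["male"], counts["persistent"]["female"]
    return {
        "initiation_pct_men": percentage(use_m, n_m),
        "initiation_pct_women": percentage(use_w, n_w),
        "persistence_pct_men": percentage(per_m, n_m),
        "persistence_pct_women": percentage(per_w, n_w),
        "overall_statin_use_pct": percentage(use_m + use_w, n_m + n_w),
        "female_cohort_share_pct": percentage(n_w, n_m + n_w, 0),
        "relative_initiation_disparity_pct": relative_disparity_pct(
            use_m / n_m, use_w / n_w),
    }


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ({x.std():.1f})"


def _fmt_n_pct(flag: pd.Series) -> str:
    flag = flag.dropna().astype(bool)
    return f"{int(flag.sum()):,} ({100 * flag.mean():.1f}%)"


def table_one(df: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of the analysis rows by sex, in the layout of a
    clinical baseline table (counts with percentages, means with SDs)."""
    out = {}
    for sex in ("male", "female"):
        g = df[df["sex"] == sex]
        col = {
            "Study patients, n (%)": f"{len(g):,} ({percentage(len(g), len(df))}%)",
            "Age, mean (SD), years": _fmt_mean_sd(g["age_at_entry"]),
            "History of smoking, n (%)": _fmt_n_pct(g["ever_smoker"]),
            "Diabetes mellitus, n (%)": _fmt_n_pct(g["diabetes"]),
            "Family history of CAD, n (%)": _fmt_n_pct(g["family_history_cad"]),
            "Cardiologist evaluation, n (%)": _fmt_n_pct(g["cardiology_evaluated"]),
            "Maximum LDL-C, mg/dL, mean (SD)": _fmt_mean_sd(g["max_ldl"].dropna()),
            "Baseline BMI, kg/m2, mean (SD)": _fmt_mean_sd(g["baseline_bmi"].dropna()),
            "Use of statin therapy, n (%)": _fmt_n_pct(g["statin_use"]),
            "Persistent statin therapy, n (%)": percentage(
                g["persistent"].fillna(False).astype(bool).sum(), len(g)),
        }
        if "income" in g.columns:
            col["Median income, $1,000s, mean (SD)"] = _fmt_mean_sd(g["income"].dropna())
        out[sex] = col
    return pd.DataFrame(out)


def cohort_proportions(df: pd.DataFrame) -> dict:
    """Headline proportions computed from analysis rows (the same rows the
    models consume)."""
    counts = {
        "patients": {s: int((df["sex"] == s).sum()) for s in ("male", "female")},
        "statin_use": {s: int(df.loc[df["sex"] == s, "statin_use"]
                              .fillna(False).astype(bool).sum())
                       for s in ("male", "female")},
        "persistent": {s: int(df.loc[df["sex"] == s, "persistent"]
                              .fillna(False).astype(bool).sum())
                       for s in ("male", "female")},
    }
    return headline_proportions(counts)
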