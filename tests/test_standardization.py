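"""Hand-computed standardization arithmetic, identity properties, and
brute-force oracle equivalence for the decomposition core."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from statindisparity import (CovariateSpec, DecompositionTask,
                             decomposition_suite, direct_standardize,
                             standardize_strata, stratum_weights,
                             two_level_standardize)
from statindisparity.standardization import SpecificationError, run_task

BIN = CovariateSpec("x", kind="binary")


def two_stratum_frame():
    """Men 30/70 across two strata with overall event rate 0.85; women 70/30
    with stratum rates 0.50 / 0.90 (hence P_w = 0.62)."""
    blocks = [
        ("male", 0, 30, 24), ("male", 1, 70, 61),     # P_m = 85/100
        ("female", 0, 70, 35), ("female", 1, 30, 27),  # rates .5, .9
    ]
    rows = []
    for sex, x, n, events in blocks:
        rows += [{"sex": sex, "x": x, "y": i < events} for i in range(n)]
    return pd.DataFrame(rows)


def test_two_stratum_hand_arithmetic():
    """P_w_adj = 0.3*0.5 + 0.7*0.9 = 0.78, so D_obs = 0.23, D_adj = 0.07,
    explained = 0.16 and fraction 0.16/0.23 = 0.6957."""
    res = direct_standardize(two_stratum_frame(), "y", [BIN])
    assert res.p_m == pytest.approx(0.85)
    assert res.p_w == pytest.approx(0.62)
    assert res.p_w_adj == pytest.approx(0.78)
    assert res.d_obs == pytest.approx(0.23)
    assert res.d_adj == pytest.approx(0.07)
    assert res.explained == pytest.approx(0.16)
    assert res.fraction == pytest.approx(0.16 / 0.23, abs=1e-12)
    assert res.explained == res.d_obs - res.d_adj  # exact identity


def test_standardize_strata_pure_function():
    p_w_adj, dropped = standardize_strata([0.3, 0.7], [0.5, 0.9])
    assert p_w_adj == pytest.approx(0.78)
    assert dropped == []


def test_stratum_weights_sum_to_one_and_match_tabulation(small_frame):
    spec = [CovariateSpec("age_group", kind="categorical"),
            CovariateSpec("cardiology_evaluated", kind="binary")]
    w = stratum_weights(small_frame, spec, "male")
    assert w.sum() == pytest.approx(1.0)
    men = small_frame[small_frame.sex == "male"]
    direct = men.groupby(["age_group", "cardiology_evaluated"]).size() / len(men)
    for key, val in direct.items():
        assert w.loc[key] == pytest.approx(val)


def test_constant_rate_leaves_nothing_explained():
    df = two_stratum_frame()
    women = df.sex == "female"
    df.loc[women, "y"] = (df.loc[women].groupby("x").cumcount() % 2 == 0)
    res = direct_standardize(df, "y", [BIN])
    # women's rate is 0.5 in both strata -> reweighting changes nothing
    assert res.p_w_adj == pytest.approx(res.p_w)
    assert res.explained == pytest.approx(0.0, abs=1e-12)


def test_identical_distributions_reproduce_p_w():
    rows = []
    for sex in ("male", "female"):
        rows += [{"sex": sex, "x": x, "y": (i + x) % 3 == 0}
                 for x in (0, 1) for i in range(40)]
    res = direct_standardize(pd.DataFrame(rows), "y", [BIN])
    assert res.p_w_adj == pytest.approx(res.p_w, abs=1e-15)


def test_self_standardization_identity():
    """Standardizing women to women's own distribution returns P_w."""
    df = two_stratum_frame()
    women_w = stratum_weights(df, [BIN], "female")
    rates = df[df.sex == "female"].groupby("x")["y"].mean()
    p_w_adj, _ = standardize_strata(women_w.to_numpy(), rates.to_numpy())
    assert p_w_adj == pytest.approx(0.62)


def test_zero_observed_disparity_gives_undefined_fraction():
    rows = ([{"sex": "male", "x": 0, "y": i < 5} for i in range(10)]
            + [{"sex": "female", "x": 0, "y": i < 5} for i in range(10)])
    res = direct_standardize(pd.DataFrame(rows), "y", [BIN])
    assert res.d_obs == 0
    assert res.fraction is None


def test_men_only_stratum_dropped_and_recorded():
    rows = ([{"sex": "male", "x": x, "y": True} for x in (0, 0, 1)]
            + [{"sex": "female", "x": 0, "y": False} for _ in range(3)])
    res = direct_standardize(pd.DataFrame(rows), "y", [BIN])
    assert len(res.dropped_strata) == 1
    assert 0.0 <= res.p_w_adj <= 1.0


def test_constant_covariate_changes_nothing():
    df = two_stratum_frame()
    base = direct_standardize(df, "y", [BIN])
    df["z"] = 1
    refined = direct_standardize(df, "y", [BIN, CovariateSpec("z")])
    for attr in ("p_m", "p_w", "p_w_adj", "fraction"):
        assert getattr(refined, attr) == pytest.approx(getattr(base, attr))


# ------------------------- two-level ---------------------------------- #

def two_level_frame():
    """Two level-1 strata (men users 50/50).  In stratum A men's level-2
    weights are 0.8/0.2 vs women's 0.5/0.5 with women's rates 0.9/0.5; in
    stratum B everyone persists at 0.7."""
    blocks = [
        ("male", "A", 0, 40, 30), ("male", "A", 1, 10, 6),
        ("male", "B", 0, 50, 35),
        ("female", "A", 0, 20, 18), ("female", "A", 1, 20, 10),
        ("female", "B", 0, 20, 14),
    ]
    rows = []
    for sex, s1, s2, n, events in blocks:
        rows += [{"sex": sex, "s1": s1, "adverse_reaction": bool(s2),
                  "statin_use": True, "persistent": i < events}
                 for i in range(n)]
    return pd.DataFrame(rows)


def test_two_level_hand_arithmetic():
    """Inner adjusted rate in A = 0.8*0.9 + 0.2*0.5 = 0.82; combined with
    men's level-1 weights: P_w_adj = 0.5*0.82 + 0.5*0.7 = 0.76."""
    res = two_level_standardize(
        two_level_frame(), "persistent",
        level1=[CovariateSpec("s1", kind="categorical")],
        level2=[CovariateSpec("adverse_reaction", level="statin_users_only")],
        population="users")
    assert res.p_w_adj == pytest.approx(0.76)


def test_two_level_reduces_to_direct_when_inner_distribution_equal():
    df = two_level_frame()
    # give women stratum A the same 0.8/0.2 adverse split as men
    extra = pd.DataFrame([{"sex": "female", "s1": "A", "adverse_reaction": False,
                           "statin_use": True, "persistent": True}] * 0)
    df = pd.concat([df, extra], ignore_index=True)
    specs1 = [CovariateSpec("s1", kind="categorical")]
    direct = direct_standardize(df[df.statin_use], "persistent", specs1,
                                population="users")
    res = two_level_standardize(df, "persistent", specs1, [], population="users")
    assert res.p_w_adj == pytest.approx(direct.p_w_adj)
    assert res.p_m == pytest.approx(direct.p_m)


def test_level_mixups_raise_specification_error():
    df = two_level_frame()
    with pytest.raises(SpecificationError):
        two_level_standardize(
            df, "persistent",
            level1=[CovariateSpec("adverse_reaction", level="statin_users_only")],
            level2=[])
    with pytest.raises(SpecificationError):
        direct_standardize(df, "persistent",
                           [CovariateSpec("adverse_reaction",
                                          level="statin_users_only")])


def test_unknown_covariate_errors(small_frame):
    with pytest.raises(SpecificationError):
        direct_standardize(small_frame, "statin_use",
                           [CovariateSpec("no_such_column")])


def test_binned_continuous_spec_validation():
    with pytest.raises(SpecificationError):
        CovariateSpec("ldl", kind="binned_continuous")  # no cut points
    with pytest.raises(SpecificationError):
        CovariateSpec("ldl", kind="binned_continuous", bins=(3, 2))
    spec = CovariateSpec("max_ldl", kind="binned_continuous", bins=(130.0,))
    assert spec.bins == (130.0,)


def test_decomposition_suite_single_covariate_matches_direct(small_frame):
    task = DecompositionTask("use:cardio", "statin_use",
                             (CovariateSpec("cardiology_evaluated"),))
    suite = decomposition_suite(small_frame, [task])
    direct = direct_standardize(small_frame, "statin_use",
                                [CovariateSpec("cardiology_evaluated")])
    assert suite.loc[0, "fraction"] == pytest.approx(direct.fraction)


# ------------------------- brute-force oracle ------------------------- #

def brute_force_adjusted(df, covs):
    """Independent enumeration: loop over every observed stratum of men,
    match women row-by-row, renormalize over strata where women exist."""
    men = df[df.sex == "male"]
    women = df[df.sex == "female"]
    total, acc = 0.0, 0.0
    for key, grp in men.groupby(covs, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        mask = np.ones(len(women), dtype=bool)
        for c, v in zip(covs, key):
            mask &= (women[c] == v).to_numpy()
        if mask.sum() == 0:
            continue
        w = len(grp) / len(men)
        total += w
        acc += w * women.loc[mask, "y"].mean()
    return acc / total


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_direct_standardize_matches_brute_force(seed, k):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 80))
    df = pd.DataFrame({"sex": np.where(rng.random(n) < 0.5, "female", "male")})
    if (df.sex == "male").sum() == 0 or (df.sex == "female").sum() == 0:
        return
    covs = []
    for j in range(k):
        df[f"c{j}"] = rng.random(n) < rng.uniform(0.2, 0.8)
        covs.append(f"c{j}")
    df["y"] = rng.random(n) < 0.5
    res = direct_standardize(df, "y", [CovariateSpec(c) for c in covs])
    assert res.p_w_adj == pytest.approx(brute_force_adjusted(df, covs), abs=1e-12)
    # convexity: the adjusted probability is a convex combination of
    # women's stratum rates
    rates = df[df.sex == "female"].groupby(covs)["y"].mean()
    assert rates.min() - 1e-12 <= res.p_w_adj <= rates.max() + 1e-12
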