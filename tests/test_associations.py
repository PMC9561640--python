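"""2x2 odds ratios, baseline comparison, matching, logistic fits, stepwise AIC."""

import numpy as np
import pandas as pd
import pytest

import htnpathways.associations as assoc
from htnpathways.errors import RareEventError


def _logistic_sim(rng, n, betas, intercept=0.0):
    """Simulate (DataFrame, outcome) from a logistic model on named covariates."""
    df = pd.DataFrame()
    eta = np.full(n, intercept, dtype=float)
    for name, (kind, beta) in betas.items():
        x = rng.integers(0, 2, n).astype(float) if kind == "b" else rng.normal(0, 1, n)
        df[name] = x
        eta += beta * x
    df["group"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "changed", "unchanged")
    return df


def test_crude_or_symmetry_and_inversion():
    est = assoc.crude_or(assoc.TwoByTwo(10, 10, 10, 10))
    assert est.odds_ratio == pytest.approx(1.0)
    a = assoc.crude_or(assoc.TwoByTwo(20, 30, 15, 40)).odds_ratio
    b = assoc.crude_or(assoc.TwoByTwo(15, 40, 20, 30)).odds_ratio
    assert a * b == pytest.approx(1.0, abs=1e-12)


def test_zero_cell_requires_continuity_correction():
    with pytest.raises(RareEventError):
        assoc.crude_or(assoc.TwoByTwo(0, 10, 10, 10))
    est = assoc.crude_or(assoc.TwoByTwo(0, 10, 10, 10), continuity_correction=True)
    assert 0 < est.odds_ratio < 1


def test_univariate_logistic_equals_cross_product():
    rng = np.random.default_rng(0)
    df = _logistic_sim(rng, 500, {"x": ("b", 0.8)})
    est = assoc.fit_univariate(df, "x")
    t = assoc.TwoByTwo.from_groups(df["x"] == 1, df["group"] == "changed")
    closed = (t.a * t.d) / (t.b * t.c)
    assert est.odds_ratio == pytest.approx(closed, abs=1e-6)


def test_compare_baseline_identical_groups():
    df = pd.DataFrame(
        {"flag": [1, 0, 1, 0], "age": [60.0, 70.0, 60.0, 70.0],
         "group": ["changed", "changed", "unchanged", "unchanged"]}
    )
    tab = assoc.compare_baseline(df, ["flag", "age"]).set_index("covariate")
    assert tab.loc["flag", "p_value"] == pytest.approx(1.0)
    assert tab.loc["age", "p_value"] == pytest.approx(1.0)


def test_fisher_switch_on_small_expected_cells():
    rows = (
        [("changed", 1)] * 2 + [("changed", 0)] * 48
        + [("unchanged", 1)] * 6 + [("unchanged", 0)] * 44
    )
    df = pd.DataFrame(rows, columns=["group", "rare"])
    tab = assoc.compare_baseline(df, ["rare"])
    assert tab.iloc[0]["test"] == "fisher"
    big = pd.DataFrame(
        [("changed", 1)] * 30 + [("changed", 0)] * 20
        + [("unchanged", 1)] * 25 + [("unchanged", 0)] * 25,
        columns=["group", "common"],
    )
    assert assoc.compare_baseline(big, ["common"]).iloc[0]["test"] == "chi2"


def test_chi2_type_one_error_near_nominal():
    """Null binary covariates rejected at ~5% over 1,000 replicates."""
    rng = np.random.default_rng(42)
    rejections = 0
    n = 200
    group = np.repeat(["changed", "unchanged"], n // 2)
    for _ in range(1000):
        df = pd.DataFrame({"group": group, "x": rng.integers(0, 2, n)})
        p = assoc.compare_baseline(df, ["x"]).iloc[0]["p_value"]
        rejections += p < 0.05
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(rejections / 1000 - 0.05) < 3 * se + 0.005


def test_propensity_closed_forms():
    df = pd.DataFrame(
        {"group": ["changed"] * 3 + ["unchanged"] * 7, "x": [1, 1, 0, 1, 0, 0, 0, 0, 0, 1]}
    )
    scores = assoc.fit_propensity(df, [])
    assert np.allclose(scores, 0.3)
    scores = assoc.fit_propensity(df, ["x"])
    by_stratum = pd.Series(scores).groupby(df["x"]).nunique()
    assert (by_stratum == 1).all()
    prev_x1 = (df[df.x == 1].group == "changed").mean()
    assert scores[df.x == 1][0] == pytest.approx(prev_x1, abs=1e-6)


def test_matching_identical_multisets_is_perfect():
    scores = np.array([0.2, 0.4, 0.6, 0.2, 0.4, 0.6])
    changed = np.array([True, True, True, False, False, False])
    m = assoc.match_1to1(scores, changed, seed=0)
    assert m.n_pairs == 3 and not m.discarded
    for i, j in m.pairs:
        assert scores[i] == scores[j]


def test_caliper_discards_outlier():
    scores = np.array([0.50, 0.51, 0.52, 0.99])
    changed = np.array([False, False, True, True])
    m = assoc.match_1to1(scores, changed, caliper_sd_logit=0.2, seed=0)
    assert m.n_pairs == 1
    assert 3 in m.discarded


def test_matching_deterministic_given_seed():
    rng = np.random.default_rng(3)
    scores = rng.random(200)
    changed = rng.random(200) < 0.5
    a = assoc.match_1to1(scores, changed, seed=11)
    b = assoc.match_1to1(scores, changed, seed=11)
    assert a.pairs == b.pairs


def test_matching_shrinks_confounder_imbalance():
    """Post-match SMDs of a planted confounder shrink versus pre-match."""
    rng = np.random.default_rng(7)
    n = 2000
    z = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(0.8 * z)))
    df = pd.DataFrame({"z": z, "group": np.where(rng.random(n) < p, "changed", "unchanged")})
    changed = (df["group"] == "changed").to_numpy()
    pre = abs(assoc.standardized_mean_difference(df.z[changed], df.z[~changed]))
    scores = assoc.fit_propensity(df, ["z"])
    m = assoc.match_1to1(scores, changed, seed=0)
    ci = [i for i, _ in m.pairs]
    ui = [j for _, j in m.pairs]
    post = abs(assoc.standardized_mean_difference(df.z.iloc[ci], df.z.iloc[ui]))
    assert post < pre


def test_multivariate_single_term_matches_univariate():
    rng = np.random.default_rng(1)
    df = _logistic_sim(rng, 400, {"x": ("b", 0.7)})
    uni = assoc.fit_univariate(df, "x")
    multi = assoc.fit_multivariate(df, ["x"])[0]
    assert multi.odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-9)
    assert multi.adjusted and not uni.adjusted


def test_profile_ci_brackets_wald_for_balanced_data():
    rng = np.random.default_rng(2)
    df = _logistic_sim(rng, 600, {"x": ("c", 0.5)})
    wald = assoc.fit_univariate(df, "x")
    lo, hi = assoc.profile_ci(
        (df["group"] == "changed").astype(float).to_numpy(),
        assoc.build_design(df, ["x"]), "x",
    )
    assert np.exp(lo) == pytest.approx(wald.ci_low, rel=0.1)
    assert np.exp(hi) == pytest.approx(wald.ci_high, rel=0.1)
    assert np.exp(lo) < wald.odds_ratio < np.exp(hi)


# ---------------------------------------------------------------------------
# stepwise AIC
# ---------------------------------------------------------------------------

def test_stepwise_selects_strong_term_among_noise():
    rng = np.random.default_rng(5)
    betas = {"signal": ("b", 1.5)} | {f"noise{i}": ("b", 0.0) for i in range(4)}
    df = _logistic_sim(rng, 1000, betas)
    selected, trace = assoc.stepwise_aic(df, list(betas), include_interactions=False)
    assert "signal" in selected
    # endpoint beats both the null and the full model
    full_aic, _ = assoc.model_aic(df, list(betas))
    null_aic, _ = assoc.model_aic(df, [])
    assert trace[-1][1] <= full_aic + 1e-9
    assert trace[-1][1] <= null_aic + 1e-9


def test_stepwise_agrees_with_exhaustive_subset_oracle():
    rng = np.random.default_rng(8)
    betas = {"signal": ("b", 1.5), "n1": ("b", 0.0), "n2": ("b", 0.0), "n3": ("c", 0.0)}
    df = _logistic_sim(rng, 1000, betas)
    selected, trace = assoc.stepwise_aic(df, list(betas), include_interactions=False)
    import itertools

    best = min(
        (assoc.model_aic(df, list(sub))[0], sorted(sub))
        for r in range(len(betas) + 1)
        for sub in itertools.combinations(betas, r)
    )
    assert trace[-1][1] == pytest.approx(best[0], abs=1e-6)
    assert sorted(selected) == best[1]


def test_stepwise_keeps_hierarchy_for_interaction():
    rng = np.random.default_rng(9)
    n = 2000
    a = rng.integers(0, 2, n).astype(float)
    b = rng.integers(0, 2, n).astype(float)
    eta = -0.5 + 1.8 * a * b  # pure interaction, null mains
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    df = pd.DataFrame({"a": a, "b": b, "group": np.where(y, "changed", "unchanged")})
    selected, _ = assoc.stepwise_aic(df, ["a", "b"], include_interactions=True)
    assert "a:b" in selected
    assert {"a", "b"} <= set(selected)  # hierarchy enforced
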