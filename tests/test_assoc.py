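import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cmrdiet import assoc, validation


# --------------------------------------------------------------------------
# Benjamini-Hochberg step-up rule


def bh_oracle(pvals, q):
    """Independent brute-force step-up: test every k for p_(k) <= k*q/m."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def test_bh_hand_example():
    decisions, cutoff = assoc.bh_adjust([0.01, 0.02, 0.04, 0.20], q=0.05)
    assert decisions == [True, True, False, False]
    assert cutoff == pytest.approx(0.02)


def test_bh_rejects_nothing_when_all_p_one():
    decisions, cutoff = assoc.bh_adjust([1.0] * 6, q=0.05)
    assert decisions == [False] * 6
    assert cutoff == 0.0


def test_bh_invalid_p_raises():
    with pytest.raises(ValueError):
        assoc.bh_adjust([0.5, 1.2], q=0.05)
    with pytest.raises(ValueError):
        assoc.bh_adjust([-0.1], q=0.05)


def test_bh_matches_bruteforce_and_statsmodels():
    rng = np.random.default_rng(42)
    for _ in range(200):
        m = int(rng.integers(1, 9))
        p = np.round(rng.random(m), 3)
        q = float(rng.choice([0.01, 0.05, 0.1]))
        decisions, cutoff = assoc.bh_adjust(p, q=q)
        expected = bh_oracle(p, q)
        assert list(decisions) == list(expected), (p, q)
        sm_reject = multipletests(p, alpha=q, method="fdr_bh")[0]
        assert list(decisions) == list(sm_reject), (p, q)
        if any(decisions):
            assert cutoff == max(p[np.asarray(decisions)])


def test_bh_decisions_monotone_in_raw_p():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = rng.random(8)
        decisions, _ = assoc.bh_adjust(p, q=0.05)
        rejected_ps = p[np.asarray(decisions)]
        kept_ps = p[~np.asarray(decisions)]
        if len(rejected_ps) and len(kept_ps):
            assert rejected_ps.max() < kept_ps.min()


# --------------------------------------------------------------------------
# association fits


@pytest.fixture(scope="module")
def band_data():
    data, truth = validation.simulate_band_trial(n=2000, band_step=-0.2, seed=5)
    return data, truth


def test_band_model_recovers_planted_gradient(band_data):
    data, truth = band_data
    res = assoc.fit_association(data, assoc.model_spec("M3", "cmrs"))
    assert res.used_random_effects
    levels = res.levels.set_index("level")
    for level in ["6", "7", ">=8"]:
        true_beta = truth["band_effects"][level]
        assert levels.loc[level, "ci_low"] - 0.2 < true_beta < levels.loc[level, "ci_high"] + 0.2
    assert res.p_trend < 1e-6
    assert levels.loc[">=8", "beta"] < levels.loc["4", "beta"]


def test_reference_band_is_lowest(band_data):
    data, _ = band_data
    res = assoc.fit_association(data, assoc.model_spec("M1", "cmrs"))
    ref_row = res.levels.set_index("level").loc["<=3"]
    assert ref_row["beta"] == 0.0 and ref_row["se"] == 0.0


def test_outcome_scaling_equivariance(band_data):
    """Scaling the outcome by c scales every beta and CI bound by c."""
    data, _ = band_data
    spec = assoc.model_spec("M1", "cmrs")
    res1 = assoc.fit_association(data, spec, use_random_effects=False)
    scaled = data.copy()
    scaled["delta_cmrs"] = scaled["delta_cmrs"] * 3.0
    scaled["base_cmrs"] = scaled["base_cmrs"] * 3.0
    res3 = assoc.fit_association(scaled, spec, use_random_effects=False)
    for col in ["beta", "ci_low", "ci_high"]:
        assert np.allclose(res3.levels[col], 3.0 * res1.levels[col], atol=1e-8)


def test_constant_exposure_raises(band_data):
    data, _ = band_data
    flat = data.copy()
    flat["hds_band"] = "<=3"
    with pytest.raises(ValueError, match="constant"):
        assoc.fit_association(flat, assoc.model_spec("M1", "cmrs"))


def test_singular_design_raises(band_data):
    data, _ = band_data
    dup = data.copy()
    dup["age2"] = dup["age"]
    spec = assoc.ModelSpec(id="M1", outcome="cmrs", continuous=("age", "age2", "base_cmrs"),
                           categorical=("sex",))
    with pytest.raises(ValueError, match="aliased"):
        assoc.fit_association(dup, spec, use_random_effects=False)


def test_few_clusters_falls_back_to_fixed_effects(band_data):
    data, _ = band_data
    one = data.copy()
    one["class_id"] = "only"
    with pytest.warns(UserWarning, match="fewer than 2 clusters"):
        res = assoc.fit_association(one, assoc.model_spec("M1", "cmrs"))
    assert not res.used_random_effects


def test_mixed_and_ols_agree_without_cluster_variance():
    """With no cluster-level variance the random-intercept fit is
    statistically equivalent to OLS (betas agree well within one SE)."""
    data, _ = validation.simulate_band_trial(n=2000, band_step=-0.2, seed=9,
                                             cluster_sd=0.0, full_covariates=False)
    spec = assoc.model_spec("M1", "cmrs")
    res_m = assoc.fit_association(data, spec)
    res_o = assoc.fit_association(data, spec, use_random_effects=False)
    m = res_m.levels.set_index("level")
    o = res_o.levels.set_index("level")
    gap = (m["beta"] - o["beta"]).abs()
    assert (gap.drop("<=3") < 0.5 * o["se"].drop("<=3")).all()


def test_continuous_exposure_slope(band_data):
    data, truth = band_data
    spec = assoc.model_spec("M2", "cmrs", exposure="hds_continuous")
    res = assoc.fit_association(data, spec)
    # one band step per score point
    assert res.beta == pytest.approx(truth["band_step"], abs=0.06)
    assert res.ci[0] < res.beta < res.ci[1]
    assert res.raw_p == res.p


# --------------------------------------------------------------------------
# pairwise contrasts


def test_pairwise_bonferroni(band_data):
    data, _ = band_data
    res = assoc.fit_association(data, assoc.model_spec("M1", "cmrs"))
    pw = assoc.pairwise_bonferroni(res)
    assert len(pw) == 15  # C(6,2)
    ok = pw.dropna(subset=["p_raw"])
    assert (ok["p_bonferroni"] >= ok["p_raw"] - 1e-12).all()
    assert (ok["p_bonferroni"] <= 1.0).all()
    capped = ok[ok["p_raw"] > 1.0 / 15]
    assert np.allclose(capped["p_bonferroni"],
                       np.minimum(1.0, capped["p_raw"] * 15))


# --------------------------------------------------------------------------
# moderation and subsets


def _interaction_data(n=2000, slope_a=-0.3, slope_b=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 10, n).astype(float)
    stratum = np.where(rng.random(n) < 0.5, "A", "B")
    slope = np.where(stratum == "A", slope_a, slope_b)
    y = slope * x + rng.normal(0, 1.0, n)
    return pd.DataFrame({
        "hds_unweighted": x, "delta_cmrs": y, "base_cmrs": rng.normal(0, 1, n),
        "age": rng.normal(9.5, 1.2, n),
        "sex": rng.choice(["boy", "girl"], n),
        "modifier": stratum,
        "class_id": rng.choice([f"k{i}" for i in range(20)], n),
    })


def test_moderation_detects_planted_interaction():
    detected = 0
    for seed in range(10):
        data = _interaction_data(seed=seed)
        spec = assoc.model_spec("M1", "cmrs", exposure="hds_continuous")
        out = assoc.moderation(data, spec, "modifier")
        strata = out["strata"].set_index("stratum")
        if out["interaction_p"] < 0.05:
            detected += 1
            assert strata.loc["A", "slope"] < strata.loc["B", "slope"]
    assert detected >= 8


def test_moderation_stratified_slopes_pool_without_interaction():
    """With identical exposure distributions and a common slope, the
    n-weighted average of stratum slopes equals the pooled slope."""
    rng = np.random.default_rng(3)
    n = 1000
    x = np.tile(np.arange(10.0), n // 10)
    stratum = np.repeat(["A", "B"], n // 2)
    y = -0.2 * x + rng.normal(0, 1.0, n)
    data = pd.DataFrame({"hds_unweighted": x, "delta_cmrs": y,
                         "modifier": stratum, "class_id": "k0",
                         "base_cmrs": 0.0, "age": 9.5, "sex": "boy"})
    spec = assoc.ModelSpec(id="M1", outcome="cmrs", exposure="hds_continuous")
    out = assoc.moderation(data, spec, "modifier", use_random_effects=False)
    strata = out["strata"]
    pooled = assoc.fit_association(data, spec, use_random_effects=False).beta
    weighted = (strata["slope"] * strata["n"]).sum() / strata["n"].sum()
    assert weighted == pytest.approx(pooled, abs=1e-6)


def test_moderation_omits_degenerate_stratum():
    data = _interaction_data(seed=4)
    data.loc[data.index[:300], "modifier"] = "C"
    data.loc[data["modifier"] == "C", "hds_unweighted"] = 5.0
    spec = assoc.model_spec("M1", "cmrs", exposure="hds_continuous")
    with pytest.warns(UserWarning, match="no exposure variation"):
        out = assoc.moderation(data, spec, "modifier")
    assert sorted(out["strata"]["stratum"]) == ["A", "B"]


def test_sensitivity_subset(band_data):
    data, _ = band_data
    spec = assoc.model_spec("M1", "cmrs")
    res_all = assoc.sensitivity_subset(data, spec, "all")
    res_main = assoc.fit_association(data, spec)
    pd.testing.assert_frame_equal(res_all.levels, res_main.levels)
    res_c = assoc.sensitivity_subset(data, spec, "control")
    res_i = assoc.sensitivity_subset(data, spec, "intervention")
    assert res_c.n + res_i.n == res_all.n
    with pytest.raises(ValueError, match="subset"):
        assoc.sensitivity_subset(data, spec, "placebo")


def test_empty_subset_raises(band_data):
    data, _ = band_data
    only_int = data[data["intervention"] == 1]
    with pytest.raises(ValueError, match="empty"):
        assoc.sensitivity_subset(only_int, assoc.model_spec("M1", "cmrs"), "control")


def test_adjust_family_marks_results(band_data):
    data, _ = band_data
    results = []
    for step, seed in [(-0.2, 1), (0.0, 2), (0.0, 3)]:
        d, _ = validation.simulate_band_trial(n=800, band_step=step, seed=seed,
                                              full_covariates=False)
        results.append(assoc.fit_association(d, assoc.model_spec("M1", "cmrs")))
    cutoff = assoc.adjust_family(results, q=0.05)
    assert results[0].bh_significant  # strong planted trend survives
    assert all(r.bh_significant is not None for r in results)
    assert 0.0 <= cutoff <= 1.0


def test_missing_categorical_kept_as_level():
    data, _ = validation.simulate_band_trial(n=1500, band_step=-0.2, seed=12)
    data.loc[data.index[:100], "income"] = np.nan
    res = assoc.fit_association(data, assoc.model_spec("M3", "cmrs"))
    assert res.n == 1500  # missing income does not drop children
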