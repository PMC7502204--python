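import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cmrdiet import hds, synth

HIGH_GROUPS = ["seafood", "rice", "red_meat_other_than_pork"]
LOW_GROUPS = ["refined_grains", "fried_foods", "ssb", "wheat",
              "fungi_algae", "roots_tubers"]
NINE = HIGH_GROUPS + LOW_GROUPS


@pytest.fixture()
def defn():
    rules = {}
    for g in HIGH_GROUPS:
        rules[g] = hds.GroupRule("healthy_high", median_cutpoint=1.0,
                                 anchor_zero=0.0, anchor_p80=2.0, weight=1 / 9)
    for g in LOW_GROUPS:
        rules[g] = hds.GroupRule("healthy_low", median_cutpoint=1.0,
                                 anchor_zero=0.0, anchor_p80=2.0, weight=1 / 9)
    return hds.HDSDefinition(rules=rules)


def profile(high_val, low_val):
    return pd.Series({**{g: high_val for g in HIGH_GROUPS},
                      **{g: low_val for g in LOW_GROUPS}})


class TestUnweighted:
    def test_all_favorable_scores_nine(self, defn):
        assert hds.score_unweighted(profile(1.5, 0.5), defn) == 9

    def test_all_unfavorable_scores_zero(self, defn):
        assert hds.score_unweighted(profile(0.5, 1.5), defn) == 0

    def test_exactly_at_medians_scores_six(self, defn):
        """At the median, 'more than the median' fails (0 for healthy-high
        groups) while 'equal or less' earns the point for the six
        healthy-low groups."""
        assert hds.score_unweighted(profile(1.0, 1.0), defn) == 6

    def test_monotone_transform_invariance(self, defn):
        """Scoring compares intake to the median, so any increasing
        transform applied to both leaves the score unchanged."""
        p = profile(1.5, 0.3)
        s1 = hds.score_unweighted(p, defn)
        rules2 = {g: hds.GroupRule(r.direction, np.log1p(r.median_cutpoint),
                                   r.anchor_zero, r.anchor_p80, r.weight)
                  for g, r in defn.rules.items()}
        defn2 = hds.HDSDefinition(rules=rules2)
        s2 = hds.score_unweighted(np.log1p(p), defn2)
        assert s1 == s2


class TestWeighted:
    def test_zero_intake_of_adverse_group_full_credit(self, defn):
        p = profile(2.0, 0.0)
        assert hds.score_weighted(p, defn) == pytest.approx(1.0)

    def test_linear_prorating(self, defn):
        p = profile(2.0, 0.0)
        p["seafood"] = 0.4 * defn.rules["seafood"].anchor_p80
        expected = 1.0 - (1 / 9) * (1 - 0.4)
        assert hds.score_weighted(p, defn) == pytest.approx(expected)

    def test_worst_diet_scores_zero(self, defn):
        assert hds.score_weighted(profile(0.0, 5.0), defn) == pytest.approx(0.0)

    def test_bounds(self, defn):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = pd.Series(rng.exponential(1.0, 9), index=NINE)
            s = hds.score_weighted(p, defn)
            assert 0.0 <= s <= 1.0


def test_monotonicity_of_both_scores(defn):
    rng = np.random.default_rng(1)
    base = profile(1.0, 1.0)
    for _ in range(200):
        g = NINE[rng.integers(9)]
        bump = float(rng.exponential(0.5))
        p2 = base.copy()
        p2[g] += bump
        du = hds.score_unweighted(p2, defn) - hds.score_unweighted(base, defn)
        dw = hds.score_weighted(p2, defn) - hds.score_weighted(base, defn)
        if defn.rules[g].direction == "healthy_high":
            assert du >= 0 and dw >= -1e-12
        else:
            assert du <= 0 and dw <= 1e-12


def test_weight_validation():
    rules = {g: hds.GroupRule("healthy_low", 1.0, 0.0, 2.0, 0.5) for g in LOW_GROUPS}
    with pytest.raises(ValueError, match="sum to 1"):
        hds.HDSDefinition(rules=rules)
    with pytest.raises(ValueError):
        hds.GroupRule("healthy_low", 1.0, 0.0, 0.0, 1.0)  # p80 <= 0
    with pytest.raises(ValueError):
        hds.GroupRule("sideways", 1.0, 0.0, 2.0, 1.0)


def test_dichotomize_median_zero_means_any_consumption():
    x = pd.Series([0.0, 0.0, 0.0, 1.0, 2.0])
    high, cut = hds.dichotomize(x)
    assert cut == 0.0
    assert list(high) == [False, False, False, True, True]


def test_banding_matches_analysis_levels():
    scores = pd.Series(range(10))
    bands = hds.band(scores)
    assert list(bands[:4]) == ["<=3"] * 4
    assert list(bands[4:8]) == ["4", "5", "6", "7"]
    assert list(bands[8:]) == [">=8"] * 2


class TestBuildDefinition:
    @pytest.fixture()
    def profiles(self):
        rng = np.random.default_rng(3)
        return pd.DataFrame(
            {g: rng.exponential(1.0, 400) * (rng.random(400) > 0.3) for g in NINE},
            index=[f"c{i}" for i in range(400)])

    @pytest.fixture()
    def contributions(self):
        return pd.Series(np.linspace(19.6, 3.9, 9), index=NINE)

    @pytest.fixture()
    def directions(self):
        return {**{g: "healthy_high" for g in HIGH_GROUPS},
                **{g: "healthy_low" for g in LOW_GROUPS}}

    def test_weights_renormalized(self, profiles, directions, contributions):
        defn = hds.build_definition(profiles, directions, contributions)
        w = np.array([defn.rules[g].weight for g in NINE])
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, contributions.to_numpy() / contributions.sum())

    def test_anchors_from_baseline_percentiles(self, profiles, directions, contributions):
        defn = hds.build_definition(profiles, directions, contributions)
        for g in NINE:
            assert defn.rules[g].anchor_p80 == pytest.approx(
                float(profiles[g].quantile(0.80)))
            assert defn.rules[g].anchor_zero == 0.0

    def test_deterministic_and_roundtrips(self, tmp_path, profiles, directions,
                                          contributions):
        d1 = hds.build_definition(profiles, directions, contributions)
        d2 = hds.build_definition(profiles, directions, contributions)
        assert d1.rules == d2.rules
        path = tmp_path / "hds.json"
        d1.to_json(path)
        d3 = hds.HDSDefinition.from_json(path)
        s1 = hds.score_weighted(profiles, d1)
        s3 = hds.score_weighted(profiles, d3)
        pd.testing.assert_series_equal(s1, s3)
        u1 = hds.score_unweighted(profiles, d1)
        u3 = hds.score_unweighted(profiles, d3)
        pd.testing.assert_series_equal(u1, u3)

    def test_wrong_direction_count_raises(self, profiles, contributions, directions):
        with pytest.raises(ValueError, match="directions"):
            hds.build_definition(profiles, dict(list(directions.items())[:5]),
                                 contributions)


def test_score_cohort_identity_and_unit_step(defn):
    prof = pd.DataFrame([profile(1.5, 0.5), profile(0.5, 1.5)],
                        index=["good", "bad"])
    same = hds.score_cohort(prof, prof, defn)
    assert (same["delta_hds"] == 0).all()
    improved = prof.copy()
    improved.loc["bad", "ssb"] = 0.5  # crosses below the median: +1 point
    rec = hds.score_cohort(prof, improved, defn)
    assert rec.loc["bad", "delta_hds"] == 1
    assert rec.loc["good", "delta_hds"] == 0


def test_score_cohort_missing_visit(defn):
    base = pd.DataFrame([profile(1.5, 0.5), profile(0.5, 1.5)], index=["a", "b"])
    follow = base.loc[["a"]]
    rec = hds.score_cohort(base, follow, defn)
    assert np.isnan(rec.loc["b", "delta_hds"])
    assert rec.loc["a", "delta_hds"] == 0


def test_weighted_and_unweighted_positively_correlated(paperlike_artifacts):
    art = paperlike_artifacts
    directions = {**{g: "healthy_high" for g in HIGH_GROUPS},
                  **{g: "healthy_low" for g in LOW_GROUPS}}
    contributions = pd.Series(np.linspace(19.6, 3.9, 9), index=NINE)
    defn = hds.build_definition(art["profiles"], directions, contributions)
    u = hds.score_unweighted(art["profiles"], defn)
    w = hds.score_weighted(art["profiles"], defn)
    rho = stats.spearmanr(u, w).statistic
    assert rho > 0.5


def test_assign_directions_follows_adjusted_contrast(paperlike_artifacts):
    """On a cohort with planted effects the adjusted low/high contrast
    reproduces the planted direction for each of the nine groups."""
    art = paperlike_artifacts
    truth = art["cohort"].truth["directions"]
    directions = hds.assign_directions(
        art["profiles"], art["delta_cmrs"], art["cohort"].covariates,
        list(truth), model_data=art["model_data"])
    assert directions == truth


def test_assign_directions_all_zero_group_raises(paperlike_artifacts):
    art = paperlike_artifacts
    prof = art["profiles"].copy()
    prof["seafood"] = 0.0
    with pytest.raises(ValueError, match="seafood"):
        hds.assign_directions(prof, art["delta_cmrs"],
                              art["cohort"].covariates, ["seafood"],
                              model_data=art["model_data"])
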