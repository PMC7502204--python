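import warnings

import pandas as pd
import pytest

from cmrdiet import diet, phenotypes, ranking, synth

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def light_ranking_config(seed: int = 0) -> ranking.RankingConfig:
    """Reduced search budget used in tests (single-candidate tree grids)."""
    return ranking.RankingConfig(
        seed=seed, n_trees=150,
        grids={
            "linear": {"alpha": [1e-3, 1e-2], "l1_ratio": [0.5]},
            "forest": {"max_features": [9], "max_depth": [10]},
            "boosting": {"n_estimators": [150], "max_depth": [3],
                         "learning_rate": [0.1], "subsample": [0.8],
                         "max_features": [0.8]},
        },
        permutation_repeats=5,
    )


def process_cohort(cohort: synth.SyntheticCohort) -> dict:
    """Run diet + phenotype stages, returning the frames the tests need."""
    rec = cohort.diet_records
    rec_b = rec[rec["visit"] == "baseline"].drop(columns=["visit"])
    profiles = diet.aggregate_recalls(rec_b)
    base = phenotypes.derive_measures(cohort.baseline_panel)
    follow = phenotypes.derive_measures(cohort.followup_panel)
    ref = phenotypes.fit_reference(base, cohort.covariates)
    z_base = phenotypes.standardize_and_score(base, cohort.covariates, ref)
    z_follow = phenotypes.standardize_and_score(follow, cohort.covariates, ref)
    delta = phenotypes.change_scores(z_base, z_follow)
    groups = list(diet.FoodGroupMap.default().groups)
    return {
        "cohort": cohort, "profiles": profiles, "reference": ref,
        "z_base": z_base, "z_follow": z_follow, "delta": delta,
        "features": profiles[groups], "delta_cmrs": delta["delta_cmrs"],
        "model_data": pd.DataFrame({"base_cmrs": z_base["cmrs"]}),
        "panel_base": base, "panel_follow": follow,
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    return synth.make_fixture_cohort("tiny", seed=1)


@pytest.fixture(scope="session")
def tiny_artifacts(tiny_cohort):
    return process_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def paperlike_artifacts():
    return process_cohort(synth.make_fixture_cohort("paper-like", seed=11))
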