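"""Synthetic longitudinal pediatric cohorts with planted dietary effects.

The generator emulates the data structure of a school-based cohort of
6–13-year-old children measured twice, one year apart:

* 3-day 24-h recall records mapping to 26 food groups. Group intakes are
  zero-inflated lognormal (many groups show SD > mean, i.e. a point mass at
  zero plus right skew), correlated within declared food blocks through a
  Gaussian copula, and expressed internally as g/100 kcal/day.
* Covariates: age, sex, grade, puberty status, cluster-randomized
  intervention arm (assigned at school level), physical activity (MET),
  and parent-reported categoricals with explicit ``Missing`` levels.
* Baseline and follow-up panels of anthropometry, blood pressure, and
  fasting blood measures on physiological scales (glucose ~4.5 mmol/L,
  SBP ~100 mmHg, energy ~1270 kcal/day).
* A planted linear effect of selected food groups on the one-year change in
  the composite risk score (CMRS): a latent change signal
  ``u = sum_g effect_g * standardized intake_g + confounders + class effect
  + noise`` is distributed across the five CMRS components so that the
  pipeline's own Z-scoring recovers ``u`` as the CMRS change.

Class-within-school random intercepts (default SD ~0.23 CMRS units,
an intraclass correlation near 0.05) make cluster adjustment consequential,
and configurable confounder effects on both diet and outcome make the
nested adjustment models distinguishable.

Everything is driven by one :class:`SimConfig` and one integer seed; the
same pair always reproduces the identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diet import FoodGroupMap, default_energy_density

# ---------------------------------------------------------------------------
# defaults

FOOD_BLOCKS = {
    "staples": ["rice", "wheat", "refined_grains", "other_cereals"],
    "treats": ["fried_foods", "ssb", "candy_sugar", "dessert", "sauces"],
    "plants": ["roots_tubers", "deep_color_vegetables", "light_color_vegetables",
               "fungi_algae", "pickled_vegetables", "fruits", "nuts_legumes"],
    "animal": ["pork", "poultry", "red_meat_other_than_pork", "animal_offal",
               "processed_meat", "seafood", "eggs"],
    "dairy": ["milk", "yogurt", "dairy_products"],
}

#: pairwise latent-correlation overrides layered on the block structure.
#: Rice- and wheat-based diets are alternative staple patterns: high rice
#: intake goes with lower wheat, refined grains, fried foods, and sweet
#: beverages (and vice versa), so these pairs are anti-correlated.
DEFAULT_CORRELATION_OVERRIDES = {
    ("rice", "wheat"): -0.35,
    ("rice", "refined_grains"): -0.30,
    ("rice", "fried_foods"): -0.20,
    ("rice", "ssb"): -0.15,
    ("rice", "fungi_algae"): -0.15,
    ("wheat", "fried_foods"): 0.20,
    ("wheat", "refined_grains"): 0.30,
    ("wheat", "roots_tubers"): 0.20,
    ("rice", "seafood"): 0.20,
}


@dataclass(frozen=True)
class FoodGroupParams:
    """Zero-inflated lognormal marginal for one group's g/100 kcal intake."""

    zero_prob: float
    log_mean: float
    log_sd: float
    block: str

    def __post_init__(self):
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError(f"zero_prob must be in [0,1], got {self.zero_prob}")
        if self.log_sd <= 0:
            raise ValueError(f"log_sd must be > 0, got {self.log_sd}")


def default_food_group_params() -> dict[str, FoodGroupParams]:
    """Marginals roughly matching observed school-age intakes (g/100 kcal)."""
    spec = {
        # group: (zero_prob, log_mean, log_sd)
        "rice": (0.05, 1.6, 0.8), "wheat": (0.05, 1.4, 0.8),
        "refined_grains": (0.50, 1.2, 1.0), "other_cereals": (0.60, 0.5, 1.0),
        "fried_foods": (0.55, 0.2, 1.0), "nuts_legumes": (0.40, 0.5, 1.0),
        "roots_tubers": (0.45, 0.6, 1.0), "deep_color_vegetables": (0.10, 1.2, 0.8),
        "light_color_vegetables": (0.10, 1.3, 0.8), "fungi_algae": (0.60, -0.6, 1.0),
        "pickled_vegetables": (0.70, -0.5, 1.0), "fruits": (0.20, 1.3, 0.9),
        "pork": (0.15, 0.9, 0.9), "poultry": (0.50, 0.3, 1.0),
        "red_meat_other_than_pork": (0.65, 0.3, 1.1), "animal_offal": (0.85, -0.7, 1.0),
        "processed_meat": (0.70, -0.3, 1.0), "seafood": (0.55, 0.9, 1.0),
        "eggs": (0.20, 0.8, 0.8), "milk": (0.30, 1.8, 0.8),
        "yogurt": (0.60, 1.0, 0.9), "dairy_products": (0.80, -0.5, 1.0),
        "sauces": (0.50, -0.7, 0.9), "ssb": (0.60, 1.2, 1.1),
        "candy_sugar": (0.70, -0.8, 1.0), "dessert": (0.75, -0.2, 1.0),
    }
    block_of = {g: b for b, gs in FOOD_BLOCKS.items() for g in gs}
    return {g: FoodGroupParams(p, mu, sd, block_of[g]) for g, (p, mu, sd) in spec.items()}


#: within-stratum SDs of the five CMRS components used to translate the
#: latent change signal into raw-unit shifts (wc cm, bp mmHg, mmol/L)
COMPONENT_SD = {"wc": 7.7, "bp_mean": 8.2, "glucose": 0.55, "hdl": 0.30, "tg": 0.40}

#: nine-group effect pattern used by the "paper-like" fixture: positive
#: effects raise the CMRS change (unfavorable), negative lower it.
PAPER_LIKE_EFFECTS = {
    "refined_grains": 0.30, "seafood": -0.26, "fried_foods": 0.22,
    "ssb": 0.19, "wheat": 0.16, "red_meat_other_than_pork": -0.13,
    "rice": -0.10, "fungi_algae": 0.07, "roots_tubers": 0.05,
}


def default_confounder_params() -> dict:
    """Distributions and (diet, outcome) effects for the confounders."""
    return {
        "age_mean": 9.54, "age_sd": 1.19, "age_min": 6.0, "age_max": 13.0,
        "girl_prob": 0.505, "puberty_prob": 0.92,
        "met_mean": 620.0, "met_sd": 550.0,
        "intervention_school_prob": 0.5,
        "categoricals": {
            "birthweight": (["<2500g", "2500-3999g", ">=4000g", "Missing"],
                            [0.035, 0.79, 0.09, 0.085]),
            "mother_bmi": (["<24", "24-27.9", ">=28", "Missing"],
                           [0.755, 0.165, 0.025, 0.055]),
            "father_bmi": (["<24", "24-27.9", ">=28", "Missing"],
                           [0.52, 0.345, 0.08, 0.055]),
            "mother_edu": (["<7y", "7-12y", ">=13y", "Missing"],
                           [0.115, 0.60, 0.215, 0.07]),
            "father_edu": (["<7y", "7-12y", ">=13y", "Missing"],
                           [0.065, 0.62, 0.245, 0.07]),
            "income": (["<750", "751-1500", "1501-2500", ">=2501", "Missing"],
                       [0.11, 0.31, 0.25, 0.25, 0.08]),
            "breastfeeding": (["yes", "no", "Missing"], [0.70, 0.20, 0.10]),
        },
        # outcome effects (CMRS-change units)
        "outcome_effects": {"age_per_year": 0.03, "girl": -0.05,
                            "intervention": -0.10, "income_per_level": -0.03,
                            "met_per_sd": -0.03},
        # income shifts on log-intake of selected groups (per income level)
        "diet_income_effects": {"seafood": 0.08, "milk": 0.06,
                                "roots_tubers": -0.06, "pickled_vegetables": -0.05},
    }


def default_followup_drift() -> dict[str, float]:
    """One-year mean change per outcome, raw units."""
    return {"height_cm": 5.8, "bmi": 0.3, "wc": 2.0, "pbf": 0.2,
            "sbp": 1.5, "dbp": 1.0, "tc": 0.05, "hdl": 0.0, "ldl": 0.05,
            "tg": 0.02, "glucose": 0.05, "insulin": 1.0}


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cohort."""

    n_children: int = 5676
    seed: int = 0
    n_schools: int = 12
    classes_per_school: int = 8
    food_group_params: dict[str, FoodGroupParams] = field(
        default_factory=default_food_group_params)
    effect_vector: dict[str, float] = field(default_factory=dict)
    confounder_params: dict = field(default_factory=default_confounder_params)
    noise_sd: float = 0.6
    component_noise_frac: float = 0.2
    cluster_sd: float = 0.23
    block_rho: float = 0.3
    correlation_overrides: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_OVERRIDES))
    day_cv: float = 0.30
    followup_diet: bool = True
    diet_stability_rho: float = 0.6
    energy_mean: float = 1268.6
    energy_sd: float = 529.1
    energy_range: tuple[float, float] = (400.0, 3400.0)
    followup_drift: dict[str, float] = field(default_factory=default_followup_drift)

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        unknown = set(self.effect_vector) - set(self.food_group_params)
        if unknown:
            raise ValueError(f"effect_vector refers to unknown groups: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground truth."""

    diet_records: pd.DataFrame
    covariates: pd.DataFrame
    baseline_panel: pd.DataFrame
    followup_panel: pd.DataFrame
    truth: dict
    config: SimConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.diet_records.to_csv(out / "diet_records.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.baseline_panel.to_csv(out / "panel_baseline.csv", index=False)
        self.followup_panel.to_csv(out / "panel_followup.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _block_correlation(groups: list[str], params: dict[str, FoodGroupParams],
                       rho: float,
                       overrides: dict[tuple[str, str], float] | None = None
                       ) -> np.ndarray:
    corr = np.eye(len(groups))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i != j and params[gi].block == params[gj].block:
                corr[i, j] = rho
    idx = {g: i for i, g in enumerate(groups)}
    for (ga, gb), r in (overrides or {}).items():
        if ga in idx and gb in idx:
            corr[idx[ga], idx[gb]] = corr[idx[gb], idx[ga]] = r
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("food-block correlation matrix is not positive definite") from exc
    return corr


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _categorical_level(series: pd.Series, levels: list[str]) -> np.ndarray:
    """Ordinal code for a categorical with Missing imputed at the mean."""
    ordered = [lv for lv in levels if lv != "Missing"]
    code = series.map({lv: i for i, lv in enumerate(ordered)})
    return code.fillna(code.mean()).to_numpy(dtype=float)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort from a :class:`SimConfig` (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    cp = config.confounder_params
    gmap = FoodGroupMap.default()
    groups = list(gmap.groups)
    params = config.food_group_params
    missing_groups = set(groups) - set(params)
    if missing_groups:
        raise ValueError(f"food_group_params missing groups: {sorted(missing_groups)}")

    child_id = np.array([f"c{i:05d}" for i in range(n)])

    # --- covariates -------------------------------------------------------
    school = rng.integers(0, config.n_schools, n)
    klass = rng.integers(0, config.classes_per_school, n)
    class_id = np.array([f"s{s:02d}_k{k:02d}" for s, k in zip(school, klass)])
    school_arm = (rng.random(config.n_schools) < cp["intervention_school_prob"]).astype(int)
    intervention = school_arm[school]
    age = _truncated_normal(rng, cp["age_mean"], cp["age_sd"], cp["age_min"], cp["age_max"], n)
    girl = (rng.random(n) < cp["girl_prob"]).astype(int)
    grade = np.clip(np.floor(age).astype(int) - 7, 2, 5)
    puberty = np.where(rng.random(n) < cp["puberty_prob"], "yes", "no")
    met_shape = (cp["met_mean"] / cp["met_sd"]) ** 2
    met = rng.gamma(met_shape, cp["met_mean"] / met_shape, n)

    cov = pd.DataFrame({
        "child_id": child_id, "school": school, "class_id": class_id,
        "age": age, "sex": np.where(girl == 1, "girl", "boy"),
        "grade": grade, "puberty": puberty, "intervention": intervention,
        "met": met,
    })
    for name, (levels, probs) in cp["categoricals"].items():
        cov[name] = rng.choice(levels, size=n, p=probs)
    cov["fiber"] = np.exp(rng.normal(np.log(0.50), 0.45, n))  # g/100 kcal

    # --- diet: correlated zero-inflated lognormal g/100 kcal --------------
    corr = _block_correlation(groups, params, config.block_rho,
                              config.correlation_overrides)
    chol = np.linalg.cholesky(corr)
    z_mag = rng.standard_normal((n, len(groups))) @ chol.T
    z_zero = rng.standard_normal((n, len(groups))) @ chol.T
    from scipy.stats import norm
    income_lvl = _categorical_level(cov["income"], cp["categoricals"]["income"][0])
    income_c = income_lvl - income_lvl.mean()
    intake100 = np.zeros((n, len(groups)))
    diet_inc = cp["diet_income_effects"]
    for j, g in enumerate(groups):
        p = params[g]
        mu = p.log_mean + diet_inc.get(g, 0.0) * income_c
        consumed = norm.cdf(z_zero[:, j]) >= p.zero_prob
        intake100[:, j] = consumed * np.exp(mu + p.log_sd * z_mag[:, j])

    # --- latent change signal u (CMRS units) ------------------------------
    sds = intake100.std(axis=0, ddof=0)
    means = intake100.mean(axis=0)
    x_std = np.where(sds > 0, (intake100 - means) / np.where(sds > 0, sds, 1.0), 0.0)
    beta = np.array([config.effect_vector.get(g, 0.0) for g in groups])
    oe = cp["outcome_effects"]
    conf_term = (
        oe["age_per_year"] * (age - cp["age_mean"])
        + oe["girl"] * girl
        + oe["intervention"] * intervention
        + oe["income_per_level"] * income_c
        + oe["met_per_sd"] * (met - cp["met_mean"]) / cp["met_sd"]
    )
    class_labels, class_inv = np.unique(class_id, return_inverse=True)
    b_class = rng.normal(0.0, config.cluster_sd, len(class_labels))
    u = x_std @ beta + conf_term + b_class[class_inv] + rng.normal(0.0, config.noise_sd, n)

    # --- baseline panel ----------------------------------------------------
    height = 130.0 + 5.8 * (age - 9.5) - 1.0 * girl + rng.normal(0, 6.5, n)
    bmi = 17.2 + 0.25 * (age - 9.5) + rng.normal(0, 3.1, n)
    bmi = np.clip(bmi, 11.5, None)
    weight = bmi * (height / 100.0) ** 2
    wc = 58.5 + 1.2 * (age - 9.5) + 2.3 * (bmi - 17.2) + rng.normal(0, 3.0, n)
    pbf = 24.0 + 1.5 * girl + 0.8 * (bmi - 17.2) + rng.normal(0, 3.5, n)
    pbf = np.clip(pbf, 5.0, 55.0)
    sbp = 100.5 + 1.0 * (age - 9.5) + 0.15 * (wc - 58.5) + rng.normal(0, 10.0, n)
    dbp = 64.0 + 0.45 * (sbp - 100.5) + rng.normal(0, 7.5, n)
    tc = 4.1 + rng.normal(0, 0.78, n)
    hdl = np.clip(1.47 + 0.15 * (tc - 4.1) / 0.78 + rng.normal(0, 0.26, n), 0.4, None)
    ldl = np.clip(2.1 + 0.6 * (tc - 4.1) + rng.normal(0, 0.40, n), 0.3, None)
    tg = np.exp(rng.normal(np.log(0.75), 0.45, n))
    glucose = np.clip(4.5 + rng.normal(0, 0.55, n), 2.5, None)
    insulin = np.exp(rng.normal(np.log(8.0), 0.5, n))

    def panel(visit, **cols):
        return pd.DataFrame({"child_id": child_id, "visit": visit, **cols})

    baseline = panel("baseline", height_cm=height, weight_kg=weight, wc=wc,
                     pbf=pbf, sbp=sbp, dbp=dbp, tc=tc, hdl=hdl, ldl=ldl,
                     tg=tg, glucose=glucose, insulin=insulin)

    # --- follow-up = baseline + drift + planted signal + noise -------------
    drift = config.followup_drift
    tau = config.component_noise_frac
    shift = u / 5.0
    height_f = height + drift["height_cm"]
    bmi_f = bmi + drift["bmi"] + 0.10 * u + rng.normal(0, 0.5, n)
    weight_f = bmi_f * (height_f / 100.0) ** 2
    wc_f = wc + drift["wc"] + shift * COMPONENT_SD["wc"] \
        + rng.normal(0, tau * COMPONENT_SD["wc"], n)
    pbf_f = np.clip(pbf + drift["pbf"] + 0.15 * u + rng.normal(0, 1.0, n), 5.0, 55.0)
    sbp_f = sbp + drift["sbp"] + shift * COMPONENT_SD["bp_mean"] \
        + rng.normal(0, tau * COMPONENT_SD["bp_mean"], n)
    dbp_f = dbp + drift["dbp"] + shift * COMPONENT_SD["bp_mean"] \
        + rng.normal(0, tau * COMPONENT_SD["bp_mean"], n)
    tc_f = tc + drift["tc"] + rng.normal(0, 0.15, n)
    hdl_f = np.clip(hdl + drift["hdl"] - shift * COMPONENT_SD["hdl"]
                    + rng.normal(0, tau * COMPONENT_SD["hdl"], n), 0.3, None)
    ldl_f = np.clip(ldl + drift["ldl"] + rng.normal(0, 0.12, n), 0.3, None)
    tg_f = np.clip(tg + drift["tg"] + shift * COMPONENT_SD["tg"]
                   + rng.normal(0, tau * COMPONENT_SD["tg"], n), 0.05, None)
    glucose_f = np.clip(glucose + drift["glucose"] + shift * COMPONENT_SD["glucose"]
                        + rng.normal(0, tau * COMPONENT_SD["glucose"], n), 2.5, None)
    insulin_f = np.clip(insulin + drift["insulin"] + 0.5 * u + rng.normal(0, 1.5, n), 0.5, None)

    followup = panel("followup", height_cm=height_f, weight_kg=weight_f, wc=wc_f,
                     pbf=pbf_f, sbp=sbp_f, dbp=dbp_f, tc=tc_f, hdl=hdl_f,
                     ldl=ldl_f, tg=tg_f, glucose=glucose_f, insulin=insulin_f)

    # --- 3-day recall records (baseline, plus a correlated follow-up) ------
    energy = _truncated_normal(rng, config.energy_mean, config.energy_sd,
                               config.energy_range[0], config.energy_range[1], n)
    density = default_energy_density()
    dens = np.array([density[g] for g in groups])
    # representative item per group: first item in the packaged map
    rep_item = {}
    for item, g in gmap.item_to_group.items():
        rep_item.setdefault(g, item)

    def recall_frame(intakes, kcal_day, visit):
        grams_day = intakes * kcal_day[:, None] / 100.0  # mean g/day per group
        sig = np.sqrt(np.log(1.0 + config.day_cv ** 2))
        frames = []
        for day in (1, 2, 3):
            mult = np.exp(rng.normal(-0.5 * sig ** 2, sig, (n, len(groups))))
            g_day = grams_day * mult
            kcal_w = g_day * dens
            tot = kcal_w.sum(axis=1)
            tot[tot <= 0] = 1.0
            kcal = kcal_w * (kcal_day / tot)[:, None]
            ci, gi = np.nonzero(g_day > 0)
            frames.append(pd.DataFrame({
                "child_id": child_id[ci], "visit": visit, "day": day,
                "food_item": np.array([rep_item[groups[j]] for j in gi]),
                "grams": g_day[ci, gi], "energy_kcal": kcal[ci, gi],
            }))
        return pd.concat(frames, ignore_index=True)

    records = recall_frame(intake100, energy, "baseline")
    if config.followup_diet:
        rho = config.diet_stability_rho
        z_mag_f = rho * z_mag + np.sqrt(1 - rho**2) * (
            rng.standard_normal((n, len(groups))) @ chol.T)
        z_zero_f = rho * z_zero + np.sqrt(1 - rho**2) * (
            rng.standard_normal((n, len(groups))) @ chol.T)
        intake100_f = np.zeros_like(intake100)
        for j, g in enumerate(groups):
            p = params[g]
            mu = p.log_mean + diet_inc.get(g, 0.0) * income_c
            consumed = norm.cdf(z_zero_f[:, j]) >= p.zero_prob
            intake100_f[:, j] = consumed * np.exp(mu + p.log_sd * z_mag_f[:, j])
        energy_f = np.clip(energy * np.exp(rng.normal(0, 0.10, n)),
                           config.energy_range[0], config.energy_range[1])
        records = pd.concat(
            [records, recall_frame(intake100_f, energy_f, "followup")],
            ignore_index=True)
    records = records.sort_values(["visit", "child_id", "day", "food_item"],
                                  ignore_index=True)

    truth = {
        "effect_vector": {g: float(config.effect_vector.get(g, 0.0)) for g in groups},
        "directions": {g: ("healthy_low" if config.effect_vector[g] > 0 else "healthy_high")
                       for g in config.effect_vector if config.effect_vector[g] != 0.0},
        "noise_sd": config.noise_sd, "cluster_sd": config.cluster_sd,
        "latent_u_sd": float(np.std(u)),
    }
    return SyntheticCohort(diet_records=records, covariates=cov,
                           baseline_panel=baseline, followup_panel=followup,
                           truth=truth, config=config)


FIXTURE_PROFILES = ("null", "paper-like", "tiny")


def make_fixture_cohort(profile: str, seed: int = 0,
                        n_children: int | None = None) -> SyntheticCohort:
    """Standard study cohorts: ``null`` (no diet effect, n=2000),
    ``paper-like`` (nine planted effects among 26 groups, n=3000), and
    ``tiny`` (n=50, for unit tests)."""
    if profile == "null":
        # a true null: no planted effects and no diet-confounder coupling,
        # so diet and outcome change are marginally independent
        cp = default_confounder_params()
        cp["diet_income_effects"] = {}
        cfg = SimConfig(n_children=n_children or 2000, seed=seed,
                        effect_vector={}, confounder_params=cp)
    elif profile == "paper-like":
        cfg = SimConfig(n_children=n_children or 3000, seed=seed,
                        effect_vector=dict(PAPER_LIKE_EFFECTS))
    elif profile == "tiny":
        cfg = SimConfig(n_children=n_children or 50, seed=seed,
                        n_schools=3, classes_per_school=2,
                        effect_vector=dict(PAPER_LIKE_EFFECTS))
    else:
        raise ValueError(f"unknown profile {profile!r}; expected one of {FIXTURE_PROFILES}")
    return simulate_cohort(cfg)
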