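"""Operating-characteristic simulations for the pipeline's inference tools.

These are self-contained Monte-Carlo studies of the procedures the pipeline
relies on: empirical false-discovery-rate control of the step-up
adjustment, and confidence-interval coverage / type-I error of the
cluster-adjusted band model on cohorts with known planted effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc

#: band prevalence used when simulating score-band trials (low to high)
BAND_PROBS = np.array([0.152, 0.180, 0.234, 0.250, 0.136, 0.048])
BAND_PROBS = BAND_PROBS / BAND_PROBS.sum()


def simulate_bh_fdr(n_replicates: int = 2000, n_tests: int = 50,
                    n_null: int = 40, effect: float = 0.5,
                    n_per_arm: int = 200, q: float = 0.05,
                    seed: int = 0) -> dict:
    """Empirical FDR of the step-up rule over replicated test families.

    Each family holds ``n_tests`` two-sample t-tests (``n_per_arm`` per
    arm, unit SD); ``n_tests - n_null`` of them carry a standardized mean
    difference of ``effect``. Test statistics are drawn from their exact
    sampling distributions (normal means, chi-square pooled variances).
    Returns the mean false-discovery proportion (0 when a family rejects
    nothing), average power, and rejection counts.
    """
    rng = np.random.default_rng(seed)
    m, r = n_tests, n_replicates
    n_alt = m - n_null
    mu = np.concatenate([np.zeros(n_null), np.full(n_alt, effect)])
    df = 2 * n_per_arm - 2

    diff = rng.normal(mu, np.sqrt(2.0 / n_per_arm), size=(r, m))
    pooled_var = rng.chisquare(df, size=(r, m)) / df
    t = diff / np.sqrt(pooled_var * 2.0 / n_per_arm)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    is_null = np.arange(m) < n_null
    fdp = np.empty(r)
    power = np.empty(r)
    n_rejections = np.empty(r, dtype=int)
    for i in range(r):
        rejected, _ = assoc.bh_adjust(pvals[i], q=q)
        rej = np.asarray(rejected)
        nr = int(rej.sum())
        n_rejections[i] = nr
        fdp[i] = (rej & is_null).sum() / nr if nr else 0.0
        power[i] = (rej & ~is_null).sum() / n_alt
    return {"fdr": float(fdp.mean()), "power": float(power.mean()),
            "mean_rejections": float(n_rejections.mean()),
            "q": q, "n_replicates": r}


def simulate_band_trial(n: int = 2000, band_step: float = -0.2,
                        seed: int = 0, cluster_sd: float = 0.23,
                        noise_sd: float = 1.0, full_covariates: bool = True
                        ) -> tuple[pd.DataFrame, dict]:
    """One synthetic trial with a linear planted effect per score band.

    The outcome change equals ``band_step * band_index`` plus small
    covariate effects, a class-level random intercept, dependence on the
    baseline value, and Gaussian noise. Returns the analysis frame (ready
    for :func:`cmrdiet.assoc.fit_association`) and the planted truth.
    """
    rng = np.random.default_rng(seed)
    band_idx = rng.choice(len(assoc.HDS_BANDS), size=n, p=BAND_PROBS)
    school = rng.integers(0, 12, n)
    klass = rng.integers(0, 8, n)
    class_id = np.array([f"s{s:02d}_k{k:02d}" for s, k in zip(school, klass)])
    labels, inv = np.unique(class_id, return_inverse=True)
    b_class = rng.normal(0, cluster_sd, len(labels))

    age = np.clip(rng.normal(9.54, 1.19, n), 6, 13)
    girl = (rng.random(n) < 0.505).astype(int)
    base = rng.normal(0.0, 2.4, n)
    y = (band_step * band_idx + 0.03 * (age - 9.54) - 0.05 * girl
         - 0.10 * base / 2.4 + b_class[inv] + rng.normal(0, noise_sd, n))

    data = pd.DataFrame({
        "hds_band": pd.Categorical([assoc.HDS_BANDS[i] for i in band_idx],
                                   categories=assoc.HDS_BANDS, ordered=True),
        "hds_unweighted": band_idx + 3,
        "delta_cmrs": y, "base_cmrs": base, "age": age,
        "sex": np.where(girl == 1, "girl", "boy"), "class_id": class_id,
    })
    if full_covariates:
        data["intervention"] = rng.integers(0, 2, n)
        data["grade"] = rng.integers(2, 6, n)
        data["puberty"] = rng.choice(["yes", "no"], n, p=[0.92, 0.08])
        data["base_bmi"] = rng.normal(17.2, 3.1, n)
        data["met"] = rng.gamma(1.27, 490, n)
        data["energy"] = rng.normal(1270, 520, n)
        data["fiber"] = np.exp(rng.normal(np.log(0.5), 0.45, n))
        for c in ("vegetable", "fruit", "pork", "nuts_legumes"):
            data[c] = np.exp(rng.normal(0.8, 0.8, n))
        data["birthweight"] = rng.choice(
            ["<2500g", "2500-3999g", ">=4000g", "Missing"], n,
            p=[0.035, 0.79, 0.09, 0.085])
        data["breastfeeding"] = rng.choice(["yes", "no", "Missing"], n,
                                           p=[0.70, 0.20, 0.10])
        data["income"] = rng.choice(
            ["<750", "751-1500", "1501-2500", ">=2501", "Missing"], n,
            p=[0.11, 0.31, 0.25, 0.25, 0.08])
        for c in ("mother_bmi", "father_bmi"):
            data[c] = rng.choice(["<24", "24-27.9", ">=28", "Missing"], n,
                                 p=[0.70, 0.20, 0.05, 0.05])
        for c in ("mother_edu", "father_edu"):
            data[c] = rng.choice(["<7y", "7-12y", ">=13y", "Missing"], n,
                                 p=[0.10, 0.60, 0.23, 0.07])
    truth = {"band_step": band_step,
             "band_effects": {b: band_step * i for i, b in enumerate(assoc.HDS_BANDS)}}
    return data, truth


def band_ci_coverage(n_sims: int = 500, n: int = 2000, band_step: float = -0.2,
                     model_id: str = "M3", seed: int = 0,
                     band: str = ">=8") -> dict:
    """CI coverage of the top band's planted effect over repeated trials."""
    rng = np.random.default_rng(seed)
    spec = assoc.model_spec(model_id, "cmrs")
    covered = 0
    for _ in range(n_sims):
        data, truth = simulate_band_trial(
            n=n, band_step=band_step, seed=int(rng.integers(2**31)),
            full_covariates=(model_id != "M1"))
        res = assoc.fit_association(data, spec)
        row = res.levels.set_index("level").loc[band]
        true_beta = truth["band_effects"][band]
        covered += int(row["ci_low"] <= true_beta <= row["ci_high"])
    return {"coverage": covered / n_sims, "n_sims": n_sims, "n": n}


def trend_type1_error(n_sims: int = 1000, n: int = 2000, alpha: float = 0.05,
                      model_id: str = "M1", seed: int = 0) -> dict:
    """Rejection rate of the trend test on null cohorts (no band effect)."""
    rng = np.random.default_rng(seed)
    spec = assoc.model_spec(model_id, "cmrs")
    rejections = 0
    for _ in range(n_sims):
        data, _ = simulate_band_trial(
            n=n, band_step=0.0, seed=int(rng.integers(2**31)),
            full_covariates=(model_id != "M1"))
        res = assoc.fit_association(data, spec)
        rejections += int(res.p_trend < alpha)
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims, "n": n}
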