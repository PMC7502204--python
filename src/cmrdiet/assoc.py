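"""Adjusted associations of diet score with cardiometabolic change.

Each outcome is a one-year change score regressed on the diet-score
exposure (six score bands against the lowest band, the continuous score,
or the score change) under three nested adjustment models:

* **M1** — class-within-school random intercept; age, sex, and the
  outcome's baseline value as fixed effects.
* **M2** — M1 plus intervention arm, grade, puberty, baseline BMI,
  physical activity (MET), and baseline intake of energy, fiber,
  vegetables, fruit, pork, and nuts/legumes.
* **M3** — M2 plus birthweight, breastfeeding, household income, and
  parental BMI and education.

Fits are linear mixed models (random intercept for class within school)
with a fixed-effects fallback when fewer than two clusters are present.
Confidence intervals use the large-sample normal approximation.
Categorical confounders keep an explicit ``Missing`` level; continuous
covariates are complete-case. Multiplicity over the family of outcomes is
controlled by the Benjamini–Hochberg step-up rule (reporting the
data-dependent p cutoff) and pairwise band contrasts use Bonferroni
adjustment. A moderation analysis adds exposure-by-modifier product terms
and reports per-stratum slopes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .hds import HDS_BANDS

logger = logging.getLogger(__name__)

REFERENCE_BAND = HDS_BANDS[0]

M1_CONTINUOUS: list[str] = ["age"]
M1_CATEGORICAL: list[str] = ["sex"]
M2_CONTINUOUS = M1_CONTINUOUS + ["base_bmi", "met", "energy", "fiber",
                                 "vegetable", "fruit", "pork", "nuts_legumes"]
M2_CATEGORICAL = M1_CATEGORICAL + ["intervention", "grade", "puberty"]
M3_CONTINUOUS = M2_CONTINUOUS
M3_CATEGORICAL = M2_CATEGORICAL + ["birthweight", "breastfeeding", "income",
                                   "mother_bmi", "father_bmi",
                                   "mother_edu", "father_edu"]

EXPOSURES = ("hds_bands", "hds_continuous", "delta_hds")


@dataclass(frozen=True)
class ModelSpec:
    """One adjustment model for one outcome and exposure coding."""

    id: str
    outcome: str  # e.g. "cmrs", "bmi" -> columns delta_<outcome>, base_<outcome>
    exposure: str = "hds_bands"
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    cluster: str = "class_id"
    reference_band: str = REFERENCE_BAND

    def __post_init__(self):
        if self.exposure not in EXPOSURES:
            raise ValueError(f"exposure must be one of {EXPOSURES}")


def model_spec(model_id: str, outcome: str, exposure: str = "hds_bands") -> ModelSpec:
    """Build the M1/M2/M3 covariate sets for an outcome."""
    sets = {"M1": (M1_CONTINUOUS, M1_CATEGORICAL),
            "M2": (M2_CONTINUOUS, M2_CATEGORICAL),
            "M3": (M3_CONTINUOUS, M3_CATEGORICAL)}
    if model_id not in sets:
        raise ValueError(f"model id must be one of {sorted(sets)}")
    cont, cat = sets[model_id]
    cont = list(dict.fromkeys(cont + [f"base_{outcome}"]))
    return ModelSpec(id=model_id, outcome=outcome, exposure=exposure,
                     continuous=tuple(cont), categorical=tuple(cat))


@dataclass
class AssociationResult:
    outcome: str
    model_id: str
    exposure: str
    levels: pd.DataFrame | None  # per band: n, beta, se, ci_low, ci_high, p
    beta: float | None  # continuous-exposure slope
    se: float | None
    ci: tuple[float, float] | None
    p: float | None
    p_trend: float | None
    n: int = 0
    used_random_effects: bool = True
    pairwise_bonferroni: pd.DataFrame | None = None
    bh_significant: bool | None = None
    _fit: object = field(default=None, repr=False)
    _band_param_names: dict = field(default_factory=dict, repr=False)

    @property
    def raw_p(self) -> float:
        """Headline p-value entering the multiplicity family."""
        return self.p_trend if self.exposure == "hds_bands" else self.p


def _exposure_column(exposure: str) -> str:
    return {"hds_bands": "hds_band", "hds_continuous": "hds_unweighted",
            "delta_hds": "delta_hds"}[exposure]


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # name columns involved in exact collinearity
        _, r = np.linalg.qr(X.to_numpy(dtype=float))
        aliased = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"singular design; aliased columns: {aliased}")


def _fit_lm(formula: str, data: pd.DataFrame, cluster: str,
            use_random_effects: bool = True):
    """Mixed fit with cluster random intercept; OLS fallback for <2 clusters."""
    n_clusters = data[cluster].nunique()
    if use_random_effects and n_clusters >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=data, groups=data[cluster])
                _check_design(pd.DataFrame(model.exog, columns=model.exog_names))
                try:
                    res = model.fit()
                except np.linalg.LinAlgError:
                    res = model.fit(method="powell", maxiter=500)
            if np.all(np.isfinite(res.params)):
                return res, True
            warnings.warn("mixed fit returned non-finite estimates; "
                          "falling back to fixed effects")
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"mixed fit failed ({exc}); falling back to fixed effects")
    elif use_random_effects:
        warnings.warn("fewer than 2 clusters; falling back to fixed effects")
    model = smf.ols(formula, data=data)
    _check_design(pd.DataFrame(model.exog, columns=model.exog_names))
    return model.fit(), False


def _covariate_terms(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    terms = []
    for c in spec.continuous:
        if c in data.columns:
            terms.append(c)
        else:
            logger.warning("covariate %s absent from data; skipped", c)
    for c in spec.categorical:
        if c in data.columns:
            terms.append(f"C({c})")
        else:
            logger.warning("covariate %s absent from data; skipped", c)
    return terms


def _complete_case(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    cols = [c for c in cols if c in data.columns]
    out = data.dropna(subset=cols).copy()
    return out


def fit_association(data: pd.DataFrame, spec: ModelSpec,
                    use_random_effects: bool = True) -> AssociationResult:
    """Fit one adjusted association model.

    ``data`` must hold ``delta_<outcome>``, ``base_<outcome>``, the exposure
    column, the covariates, and the cluster labels. Band exposures are coded
    against the lowest band with a trend test from the band index; the trend
    p doubles as the headline p entering the BH family.
    """
    ycol = f"delta_{spec.outcome}"
    xcol = _exposure_column(spec.exposure)
    needed = [ycol, xcol] + [c for c in spec.continuous]
    df = _complete_case(data, needed)
    for c in spec.categorical:
        if c in df.columns:
            col = df[c].astype(object)
            df[c] = col.where(col.notna(), "Missing").astype(str)
    if df[xcol].nunique() < 2:
        raise ValueError(f"exposure '{xcol}' is constant; no contrast to estimate")

    cov_terms = _covariate_terms(spec, df)
    n = len(df)

    if spec.exposure == "hds_bands":
        df["hds_band"] = df["hds_band"].astype(str)
        ref = spec.reference_band
        exposure_term = f"C(hds_band, Treatment('{ref}'))"
        formula = f"Q('{ycol}') ~ {exposure_term}"
        if cov_terms:
            formula += " + " + " + ".join(cov_terms)
        res, used_re = _fit_lm(formula, df, spec.cluster, use_random_effects)

        band_idx = {b: i for i, b in enumerate(HDS_BANDS)}
        rows, names = [], {}
        counts = df["hds_band"].value_counts()
        for b in HDS_BANDS:
            if b not in counts.index:
                continue
            if b == ref:
                rows.append({"level": b, "n": int(counts[b]), "beta": 0.0,
                             "se": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                             "p": np.nan})
                continue
            pname = f"{exposure_term}[T.{b}]"
            beta = float(res.params[pname])
            se = float(res.bse[pname])
            rows.append({"level": b, "n": int(counts[b]), "beta": beta,
                         "se": se, "ci_low": beta - 1.959963984540054 * se,
                         "ci_high": beta + 1.959963984540054 * se,
                         "p": 2 * stats.norm.sf(abs(beta / se))})
            names[b] = pname
        levels = pd.DataFrame(rows)

        df["_band_index"] = df["hds_band"].map(band_idx).astype(float)
        tform = f"Q('{ycol}') ~ _band_index"
        if cov_terms:
            tform += " + " + " + ".join(cov_terms)
        tres, _ = _fit_lm(tform, df, spec.cluster, use_random_effects)
        tb, tse = float(tres.params["_band_index"]), float(tres.bse["_band_index"])
        p_trend = 2 * stats.norm.sf(abs(tb / tse))

        return AssociationResult(outcome=spec.outcome, model_id=spec.id,
                                 exposure=spec.exposure, levels=levels,
                                 beta=None, se=None, ci=None, p=None,
                                 p_trend=float(p_trend), n=n,
                                 used_random_effects=used_re,
                                 _fit=res, _band_param_names=names)

    # continuous or change-score exposure: one slope
    formula = f"Q('{ycol}') ~ Q('{xcol}')"
    if cov_terms:
        formula += " + " + " + ".join(cov_terms)
    res, used_re = _fit_lm(formula, df, spec.cluster, use_random_effects)
    pname = f"Q('{xcol}')"
    beta, se = float(res.params[pname]), float(res.bse[pname])
    z = beta / se
    return AssociationResult(outcome=spec.outcome, model_id=spec.id,
                             exposure=spec.exposure, levels=None, beta=beta,
                             se=se, ci=(beta - 1.959963984540054 * se,
                                        beta + 1.959963984540054 * se),
                             p=float(2 * stats.norm.sf(abs(z))),
                             p_trend=None, n=n, used_random_effects=used_re,
                             _fit=res)


def bh_adjust(pvalues, q: float = 0.05) -> tuple[list[bool], float]:
    """Benjamini–Hochberg step-up rule at FDR level ``q``.

    Sort the m p-values ascending, find the largest k with
    ``p_(k) <= k*q/m``, and reject hypotheses 1..k. Returns the decision
    per input p-value (input order) and the data-dependent cutoff
    ``p_(k)`` (0.0 when nothing is rejected).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return [], 0.0
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    if passing.size == 0:
        return [False] * m, 0.0
    k = passing[-1]
    cutoff = float(sorted_p[k])
    return list(p <= cutoff), cutoff


def pairwise_bonferroni(result: AssociationResult) -> pd.DataFrame:
    """All band-pair contrasts with Bonferroni-adjusted p (capped at 1)."""
    if result.levels is None or result._fit is None:
        raise ValueError("pairwise contrasts need a fitted band model")
    res = result._fit
    bands = list(result.levels["level"])
    params = res.params
    cov = res.cov_params()
    names = result._band_param_names
    n_comp = len(bands) * (len(bands) - 1) // 2
    rows = []
    for i in range(len(bands)):
        for j in range(i + 1, len(bands)):
            bi, bj = bands[i], bands[j]
            vec = {}
            if bi in names:
                vec[names[bi]] = -1.0
            if bj in names:
                vec[names[bj]] = 1.0
            est = sum(c * float(params[k]) for k, c in vec.items())
            var = 0.0
            for k1, c1 in vec.items():
                for k2, c2 in vec.items():
                    var += c1 * c2 * float(cov.loc[k1, k2])
            se = np.sqrt(var)
            p_raw = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
            rows.append({"level_a": bi, "level_b": bj, "diff": est, "se": se,
                         "p_raw": p_raw,
                         "p_bonferroni": min(1.0, p_raw * n_comp) if np.isfinite(p_raw) else np.nan})
    out = pd.DataFrame(rows)
    result.pairwise_bonferroni = out
    return out


def adjust_family(results: list[AssociationResult], q: float = 0.05) -> float:
    """Apply BH across a family of results (one exposure, many outcomes).

    Results whose headline p could not be computed (degenerate fits) stay
    undecided (``bh_significant`` is None) and do not enter the family.
    """
    usable = [r for r in results if r.raw_p is not None and np.isfinite(r.raw_p)]
    decisions, cutoff = bh_adjust([r.raw_p for r in usable], q=q)
    for r, d in zip(usable, decisions):
        r.bh_significant = bool(d)
    return cutoff


def moderation(data: pd.DataFrame, spec: ModelSpec, modifier: str,
               use_random_effects: bool = True) -> dict:
    """Exposure-by-modifier interaction with per-stratum slopes.

    The exposure enters continuously; the modifier must be categorical.
    Returns the joint Wald p for the product terms and a per-stratum table
    of adjusted slopes with 95% CIs. Strata without exposure variation are
    omitted with a warning.
    """
    xcol = _exposure_column(spec.exposure if spec.exposure != "hds_bands"
                            else "hds_continuous")
    ycol = f"delta_{spec.outcome}"
    df = _complete_case(data, [ycol, xcol] + list(spec.continuous) + [modifier])
    for c in list(spec.categorical) + [modifier]:
        if c in df.columns:
            col = df[c].astype(object)
            df[c] = col.where(col.notna(), "Missing").astype(str)
    cov_terms = [t for t in _covariate_terms(spec, df) if f"C({modifier})" != t]
    # strata without exposure variation cannot contribute an interaction term
    degenerate = [lv for lv, sub in df.groupby(modifier) if sub[xcol].nunique() < 2]
    for lv in degenerate:
        warnings.warn(f"stratum {modifier}={lv} has no exposure variation; omitted")
    df = df[~df[modifier].isin(degenerate)]
    if df[modifier].nunique() < 2:
        raise ValueError(f"modifier '{modifier}' has fewer than two usable strata")
    formula = f"Q('{ycol}') ~ Q('{xcol}') * C({modifier})"
    if cov_terms:
        formula += " + " + " + ".join(cov_terms)
    res, used_re = _fit_lm(formula, df, spec.cluster, use_random_effects)
    inter = [nm for nm in res.params.index
             if nm.startswith(f"Q('{xcol}'):C({modifier})")]
    if not inter:
        raise ValueError(f"modifier '{modifier}' produced no interaction terms")
    wald = res.wald_test(inter, scalar=True)
    interaction_p = float(wald.pvalue)

    rows = []
    for level, sub in df.groupby(modifier):
        if sub[xcol].nunique() < 2:
            warnings.warn(f"stratum {modifier}={level} has no exposure variation; omitted")
            continue
        sform = f"Q('{ycol}') ~ Q('{xcol}')"
        if cov_terms:
            usable = []
            for t in cov_terms:
                name = t[2:-1] if t.startswith("C(") else t
                nun = sub[name].nunique()
                if (t.startswith("C(") and nun >= 2) or (not t.startswith("C(")):
                    usable.append(t)
            if usable:
                sform += " + " + " + ".join(usable)
        sres, _ = _fit_lm(sform, sub, spec.cluster, use_random_effects)
        b, se = float(sres.params[f"Q('{xcol}')"]), float(sres.bse[f"Q('{xcol}')"])
        rows.append({"stratum": level, "n": len(sub), "slope": b, "se": se,
                     "ci_low": b - 1.959963984540054 * se,
                     "ci_high": b + 1.959963984540054 * se})
    return {"modifier": modifier, "interaction_p": interaction_p,
            "strata": pd.DataFrame(rows), "used_random_effects": used_re}


def sensitivity_subset(data: pd.DataFrame, spec: ModelSpec, subset: str,
                       use_random_effects: bool = True) -> AssociationResult:
    """Re-run the association pipeline on a trial-arm subset."""
    if subset not in ("all", "control", "intervention"):
        raise ValueError("subset must be 'all', 'control', or 'intervention'")
    if subset == "all":
        sub = data
    else:
        arm = 1 if subset == "intervention" else 0
        sub = data[pd.to_numeric(data["intervention"], errors="coerce") == arm]
    if sub.empty:
        raise ValueError(f"subset '{subset}' is empty")
    return fit_association(sub, spec, use_random_effects=use_random_effects)


def adjusted_group_difference(high: pd.Series, delta_cmrs: pd.Series,
                              covariates: pd.DataFrame,
                              model_data: pd.DataFrame | None = None) -> float:
    """Adjusted high-vs-low difference in CMRS change for one food group.

    Uses the baseline-adjusted cluster model (age, sex, baseline CMRS when
    available, class random intercept). Negative values mean high intake is
    favorable.
    """
    cov = covariates.set_index("child_id") if "child_id" in covariates.columns else covariates
    df = pd.DataFrame({"high": high, "delta_cmrs": delta_cmrs}).dropna()
    df = df.join(cov[["age", "sex", "class_id"]], how="inner")
    if model_data is not None and "base_cmrs" in model_data.columns:
        df = df.join(model_data["base_cmrs"], how="left")
    terms = ["high", "age", "C(sex)"]
    if "base_cmrs" in df.columns:
        terms.append("base_cmrs")
    formula = "delta_cmrs ~ " + " + ".join(terms)
    res, _ = _fit_lm(formula, df.dropna(), "class_id")
    return float(res.params["high"])
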