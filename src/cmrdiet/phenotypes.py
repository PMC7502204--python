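"""Derived cardiometabolic measures, Z-standardization, and the CMRS composite.

A visit panel carries raw anthropometry, blood pressure, and fasting blood
measures per child. This module

* fills in derived measures — BMI (kg/m^2), mean arterial pressure
  ``MAP = DBP + 0.33*(SBP-DBP)``, and HOMA-IR
  ``(insulin uU/L * glucose mg/dL)/405`` with glucose converted from mmol/L
  at 18.0 mg/dL per mmol/L;
* standardizes 14 measures to Z-scores using sex- and integer-age-specific
  means and SDs fitted on the baseline visit (strata thinner than a floor
  are pooled with the nearest age within sex);
* computes the composite cardiometabolic risk score

  ``CMRS = z(WC) + z((SBP+DBP)/2) + z(glucose) - z(HDL) + z(TG)``

  where the blood-pressure term standardizes the per-child mean of SBP and
  DBP as a single variable;
* forms change scores (follow-up minus baseline) and classifies effect
  sizes (0.2/0.5/0.8 SD for individual factors; 1.0/2.5/4.0 for CMRS,
  which sums five component Z-scores).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MMOL_TO_MGDL_GLUCOSE = 18.0

#: measures standardized to Z-scores (column names in the derived panel)
Z_MEASURES = [
    "bmi", "wc", "pbf", "sbp", "dbp", "map", "tg", "tc", "hdl", "ldl",
    "tg_hdl", "glucose", "insulin", "homa_ir",
]

#: CMRS components: (column, sign). ``bp_mean`` is (SBP+DBP)/2.
CMRS_COMPONENTS = [("wc", 1.0), ("bp_mean", 1.0), ("glucose", 1.0),
                   ("hdl", -1.0), ("tg", 1.0)]

EFFECT_SIZE_THRESHOLDS = {"individual": (0.2, 0.5, 0.8), "cmrs": (1.0, 2.5, 4.0)}


def derive_measures(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill BMI, MAP, HOMA-IR, bp_mean, and tg_hdl where inputs are present.

    Raw inputs are left untouched; non-positive height or weight is treated
    as missing with a warning.
    """
    out = panel.copy()
    h = pd.to_numeric(out.get("height_cm"), errors="coerce")
    w = pd.to_numeric(out.get("weight_kg"), errors="coerce")
    if h is not None and w is not None:
        bad = (h <= 0) | (w <= 0)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} non-positive height/weight values set to missing")
            h = h.mask(bad)
            w = w.mask(bad)
        bmi = w / (h / 100.0) ** 2
        out["bmi"] = out["bmi"].fillna(bmi) if "bmi" in out else bmi

    if {"sbp", "dbp"} <= set(out.columns):
        mapv = out["dbp"] + 0.33 * (out["sbp"] - out["dbp"])
        out["map"] = out["map"].fillna(mapv) if "map" in out else mapv
        out["bp_mean"] = (out["sbp"] + out["dbp"]) / 2.0

    if {"insulin", "glucose"} <= set(out.columns):
        homa = out["insulin"] * (out["glucose"] * MMOL_TO_MGDL_GLUCOSE) / 405.0
        out["homa_ir"] = out["homa_ir"].fillna(homa) if "homa_ir" in out else homa

    if {"tg", "hdl"} <= set(out.columns):
        out["tg_hdl"] = out["tg"] / out["hdl"]
    return out


@dataclass
class StandardizationReference:
    """Sex- and age-stratum means and SDs for each standardized measure.

    ``table`` is indexed by (sex, age, measure) with columns mean/sd/n;
    ``pooling`` maps a (sex, age) stratum to the (sex, age) stratum whose
    statistics it borrows (identity when no pooling was needed).
    """

    table: pd.DataFrame
    pooling: dict = field(default_factory=dict)
    min_stratum_n: int = 20

    def lookup(self, sex, age, measure: str) -> tuple[float, float]:
        key = self.pooling.get((sex, int(age)), (sex, int(age)))
        try:
            row = self.table.loc[key + (measure,)]
        except KeyError:
            raise KeyError(f"no reference stratum for sex={sex}, age={age} ({measure})")
        return float(row["mean"]), float(row["sd"])

    def to_json(self, path) -> None:
        payload = {
            "min_stratum_n": self.min_stratum_n,
            "pooling": [{"from": list(k), "to": list(v)} for k, v in self.pooling.items()],
            "table": [
                {"sex": s, "age": int(a), "measure": m,
                 "mean": float(r["mean"]), "sd": float(r["sd"]), "n": int(r["n"])}
                for (s, a, m), r in self.table.iterrows()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StandardizationReference":
        with open(path) as fh:
            payload = json.load(fh)
        table = pd.DataFrame(payload["table"]).set_index(["sex", "age", "measure"])
        pooling = {tuple(d["from"]): tuple(d["to"]) for d in payload["pooling"]}
        return cls(table=table, pooling=pooling, min_stratum_n=payload["min_stratum_n"])


def _strata(covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates[["sex", "age"]].copy()
    cov["age"] = cov["age"].astype(float).astype(int)
    return cov


def fit_reference(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    measures: list[str] | None = None,
    min_stratum_n: int = 20,
) -> StandardizationReference:
    """Fit per-(sex, integer age) means/SDs on a (baseline) panel.

    Strata with fewer than ``min_stratum_n`` children borrow the nearest age
    stratum (within sex) that meets the floor. A usable stratum with zero
    variance in any measure is an error naming measure and stratum.
    """
    if measures is None:
        measures = [m for m in Z_MEASURES + ["bp_mean"] if m in panel.columns]
    cov = _strata(covariates.set_index("child_id") if "child_id" in covariates else covariates)
    df = panel.set_index("child_id") if "child_id" in panel.columns else panel
    df = df.join(cov, how="inner")

    rows = []
    sizes = df.groupby(["sex", "age"]).size()
    for (sex, age), n in sizes.items():
        sub = df[(df["sex"] == sex) & (df["age"] == age)]
        for m in measures:
            vals = sub[m].dropna()
            rows.append({"sex": sex, "age": int(age), "measure": m,
                         "mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)})
    # pooled fallback strata for small cohorts: per sex (age -1) and overall
    sex_sizes = df.groupby("sex").size()
    for sex, n in sex_sizes.items():
        sub = df[df["sex"] == sex]
        for m in measures:
            vals = sub[m].dropna()
            rows.append({"sex": sex, "age": -1, "measure": m,
                         "mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)})
    for m in measures:
        vals = df[m].dropna()
        rows.append({"sex": "__all__", "age": -1, "measure": m,
                     "mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)})
    table = pd.DataFrame(rows).set_index(["sex", "age", "measure"])

    pooling: dict = {}
    for (sex, age), n in sizes.items():
        if n >= min_stratum_n:
            continue
        candidates = [(s2, int(a2)) for (s2, a2), n2 in sizes.items()
                      if s2 == sex and n2 >= min_stratum_n]
        if candidates:
            pooling[(sex, int(age))] = min(candidates, key=lambda k: abs(k[1] - age))
        elif sex_sizes[sex] >= min_stratum_n:
            pooling[(sex, int(age))] = (sex, -1)
        else:
            pooling[(sex, int(age))] = ("__all__", -1)

    used = {pooling.get(k, k) for k in ((s, int(a)) for (s, a) in sizes.index)}
    for sex, age in used:
        for m in measures:
            sd = table.loc[(sex, age, m), "sd"]
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(
                    f"zero-variance stratum for measure '{m}' at sex={sex}, age={age}"
                )
    return StandardizationReference(table=table, pooling=pooling, min_stratum_n=min_stratum_n)


def standardize_and_score(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    reference: StandardizationReference,
) -> pd.DataFrame:
    """Z-standardize the 14 measures and compute CMRS per child.

    The panel must already carry derived measures (:func:`derive_measures`).
    CMRS is missing whenever any of its five components is missing.
    """
    cov = _strata(covariates.set_index("child_id") if "child_id" in covariates else covariates)
    df = panel.set_index("child_id") if "child_id" in panel.columns else panel.copy()
    df = df.join(cov, how="inner")

    measures = [m for m in Z_MEASURES + ["bp_mean"] if m in df.columns]
    zcols = {}
    mean_arr = {m: np.full(len(df), np.nan) for m in measures}
    sd_arr = {m: np.full(len(df), np.nan) for m in measures}
    strata = list(zip(df["sex"], df["age"]))
    uniq = sorted(set(strata))
    stratum_idx = {s: np.array([i for i, t in enumerate(strata) if t == s]) for s in uniq}
    for s, idx in stratum_idx.items():
        for m in measures:
            mu, sd = reference.lookup(s[0], s[1], m)
            mean_arr[m][idx] = mu
            sd_arr[m][idx] = sd
    for m in measures:
        zcols["z_" + m] = (df[m].to_numpy(dtype=float) - mean_arr[m]) / sd_arr[m]

    out = pd.DataFrame(zcols, index=df.index)
    comp = sum(sign * out["z_" + col] for col, sign in CMRS_COMPONENTS)
    out["cmrs"] = comp
    if "visit" in panel.columns:
        out.insert(0, "visit", df["visit"])
    out.index.name = "child_id"
    return out


def change_scores(z_baseline: pd.DataFrame, z_followup: pd.DataFrame) -> pd.DataFrame:
    """Follow-up minus baseline per z-measure and CMRS, aligned on child_id.

    A child missing either visit contributes a missing change for every
    measure; a measure missing at one visit yields a missing change for that
    measure only.
    """
    b = z_baseline.drop(columns=["visit"], errors="ignore")
    f = z_followup.drop(columns=["visit"], errors="ignore")
    cols = [c for c in b.columns if c in f.columns]
    delta = f[cols].sub(b[cols], axis=0)
    delta = delta.loc[delta.index.intersection(b.index).intersection(f.index)]
    return delta.add_prefix("delta_").sort_index()


def classify_effect_size(delta_sd: float, is_cmrs: bool = False) -> str:
    """Classify |standardized mean difference| as none/small/medium/large."""
    small, medium, large = EFFECT_SIZE_THRESHOLDS["cmrs" if is_cmrs else "individual"]
    d = abs(float(delta_sd))
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    if d >= large:
        return "large"
    if d >= medium:
        return "medium"
    if d >= small:
        return "small"
    return "none"
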