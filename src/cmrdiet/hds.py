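"""Healthy Diet Score (HDS) construction, serialization, and scoring.

From the k leading food groups (default nine) the score is built in three
steps, all on baseline data:

1. **Directions.** Each group is dichotomized at its baseline median
   (groups whose median is zero dichotomize as zero vs any consumption) and
   the adjusted mean CMRS change is compared between the low and high
   strata with the association module's cluster-adjusted model. A group is
   ``healthy_high`` when high intake carries the lower (more favorable)
   adjusted change, else ``healthy_low``.
2. **Definition.** Median cutpoints, 80th-percentile prorating anchors, and
   importance-derived weights (contributions of the k groups renormalized
   to sum to 1) are frozen into a serializable :class:`HDSDefinition`.
3. **Scoring.** The unweighted score awards one point per group on the
   favorable side of its median (strictly above for ``healthy_high``; at or
   below for ``healthy_low``), giving an integer 0..k. The weighted score
   prorates each group linearly between its anchors — full credit at zero
   intake (``healthy_low``) or at/above the 80th percentile
   (``healthy_high``), zero credit at the opposite anchor — and sums
   weight * sub-score, giving a real in [0, 1].

Both visits are scored against the baseline-frozen definition, so the HDS
change (follow-up minus baseline) reflects dietary change, not cutpoint
drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

DIRECTIONS = ("healthy_high", "healthy_low")

#: unweighted-score band edges used in cohort description and association
#: models: <=3, 4, 5, 6, 7, >=8
HDS_BANDS = ["<=3", "4", "5", "6", "7", ">=8"]


@dataclass(frozen=True)
class GroupRule:
    direction: str
    median_cutpoint: float
    anchor_zero: float
    anchor_p80: float
    weight: float

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.anchor_p80 <= self.anchor_zero:
            raise ValueError("anchor_p80 must exceed anchor_zero")


@dataclass
class HDSDefinition:
    """Frozen scoring rules for the k selected groups (serializable)."""

    rules: dict[str, GroupRule]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        wsum = sum(r.weight for r in self.rules.values())
        if any(r.weight < 0 for r in self.rules.values()):
            raise ValueError("weights must be non-negative")
        if abs(wsum - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1, got {wsum}")

    @property
    def k(self) -> int:
        return len(self.rules)

    @property
    def groups(self) -> list[str]:
        return list(self.rules)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "rules": {g: {"direction": r.direction,
                          "median_cutpoint": r.median_cutpoint,
                          "anchor_zero": r.anchor_zero,
                          "anchor_p80": r.anchor_p80,
                          "weight": r.weight}
                      for g, r in self.rules.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HDSDefinition":
        with open(path) as fh:
            payload = json.load(fh)
        rules = {g: GroupRule(**r) for g, r in payload["rules"].items()}
        return cls(rules=rules, provenance=payload.get("provenance", {}))


def dichotomize(intakes: pd.Series) -> tuple[pd.Series, float]:
    """Split a group's intakes at the median (or 0 vs >0 when median is 0).

    Returns the boolean high-intake indicator and the cutpoint used.
    """
    med = float(intakes.median())
    if not np.isfinite(med):
        raise ValueError("median is not finite")
    return intakes > med, med


def assign_directions(profiles: pd.DataFrame, delta_cmrs: pd.Series,
                      covariates: pd.DataFrame, selected: list[str],
                      model_data: pd.DataFrame | None = None) -> dict[str, str]:
    """Direction per selected group from adjusted low/high comparisons.

    For each group, the CMRS change is regressed on the high-intake
    indicator with the baseline-adjusted cluster model (age, sex, baseline
    CMRS, class-within-school random intercept). ``healthy_high`` when the
    adjusted high-vs-low difference is negative (favorable), ``healthy_low``
    otherwise. ``model_data`` can supply the prepared covariate frame;
    otherwise it is assembled from ``covariates``.
    """
    from . import assoc  # deferred: avoid import cycle

    directions = {}
    for g in selected:
        intakes = profiles[g].dropna()
        high, _ = dichotomize(intakes)
        if not high.any() or high.all():
            raise ValueError(f"group '{g}' has no intake contrast (all-equal stratum)")
        diff = assoc.adjusted_group_difference(
            high.astype(int), delta_cmrs, covariates, model_data=model_data)
        directions[g] = "healthy_high" if diff < 0 else "healthy_low"
    return directions


def build_definition(profiles: pd.DataFrame, directions: dict[str, str],
                     contributions: pd.Series, k: int = 9,
                     provenance: dict | None = None) -> HDSDefinition:
    """Freeze cutpoints, anchors, and weights from baseline profiles.

    ``directions`` must cover exactly the k selected groups; ``contributions``
    (importance percentages) are renormalized over those groups to sum to 1.
    """
    if len(directions) != k:
        raise ValueError(f"expected {k} directions, got {len(directions)}")
    sub = contributions.loc[list(directions)]
    total = float(sub.sum())
    if total <= 0:
        raise ValueError("contributions of the selected groups must be positive")
    rules = {}
    for g, direction in directions.items():
        vals = profiles[g].dropna()
        med = float(vals.median())
        p80 = float(vals.quantile(0.80))
        if not np.isfinite(p80):
            raise ValueError(f"non-finite 80th percentile for group '{g}'")
        if p80 <= 0:
            raise ValueError(f"degenerate intake distribution for group '{g}' (p80=0)")
        rules[g] = GroupRule(direction=direction, median_cutpoint=med,
                             anchor_zero=0.0, anchor_p80=p80,
                             weight=float(sub[g] / total))
    prov = {"date": date.today().isoformat(), "n_children": int(len(profiles))}
    prov.update(provenance or {})
    return HDSDefinition(rules=rules, provenance=prov)


def score_unweighted(profile: pd.Series | pd.DataFrame, defn: HDSDefinition):
    """Integer HDS 0..k: one point per group on the favorable side of the
    median (> median for ``healthy_high``; <= median for ``healthy_low``)."""
    df = profile.to_frame().T if isinstance(profile, pd.Series) else profile
    score = pd.Series(0, index=df.index, dtype=int)
    for g, r in defn.rules.items():
        x = df[g]
        if r.direction == "healthy_high":
            score += (x > r.median_cutpoint).astype(int)
        else:
            score += (x <= r.median_cutpoint).astype(int)
    if isinstance(profile, pd.Series):
        return int(score.iloc[0])
    return score


def score_weighted(profile: pd.Series | pd.DataFrame, defn: HDSDefinition):
    """Weighted HDS in [0,1]: linearly prorated sub-scores times weights."""
    df = profile.to_frame().T if isinstance(profile, pd.Series) else profile
    score = pd.Series(0.0, index=df.index)
    for g, r in defn.rules.items():
        frac = (df[g] - r.anchor_zero) / (r.anchor_p80 - r.anchor_zero)
        if r.direction == "healthy_high":
            sub = frac.clip(0.0, 1.0)
        else:
            sub = (1.0 - frac).clip(0.0, 1.0)
        score += r.weight * sub
    if isinstance(profile, pd.Series):
        return float(score.iloc[0])
    return score


def band(hds_unweighted: pd.Series) -> pd.Series:
    """Band the integer HDS into the six analysis levels <=3 .. >=8."""
    edges = pd.cut(hds_unweighted, bins=[-np.inf, 3, 4, 5, 6, 7, np.inf],
                   labels=HDS_BANDS)
    return edges.astype(pd.CategoricalDtype(HDS_BANDS, ordered=True))


def score_cohort(profiles_baseline: pd.DataFrame,
                 profiles_followup: pd.DataFrame | None,
                 defn: HDSDefinition) -> pd.DataFrame:
    """Score both visits with the baseline-frozen definition.

    Returns one row per child with ``hds_unweighted``, ``hds_weighted`` per
    visit and their deltas (missing when a child lacks a visit).
    """
    out = pd.DataFrame(index=profiles_baseline.index)
    out["hds_unweighted"] = score_unweighted(profiles_baseline, defn)
    out["hds_weighted"] = score_weighted(profiles_baseline, defn)
    out["hds_band"] = band(out["hds_unweighted"])
    if profiles_followup is not None:
        fu_u = score_unweighted(profiles_followup, defn)
        fu_w = score_weighted(profiles_followup, defn)
        out = out.join(fu_u.rename("hds_unweighted_followup"), how="outer")
        out = out.join(fu_w.rename("hds_weighted_followup"), how="outer")
        out["delta_hds"] = out["hds_unweighted_followup"] - out["hds_unweighted"]
        out["delta_hds_weighted"] = out["hds_weighted_followup"] - out["hds_weighted"]
    out.index.name = "child_id"
    return out
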