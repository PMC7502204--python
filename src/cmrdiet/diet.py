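"""Food-group aggregation of 24-h recall records and energy adjustment.

Raw recall records (one row per child x day x food item, with grams and the
item's energy contribution in kcal) are mapped to 26 food groups, summed
within day, averaged over recall days, and expressed per 100 kcal of mean
daily energy::

    intake_g_per_100kcal = 100 * mean_daily_grams / mean_daily_energy_kcal

Energy-implausible children (mean daily energy outside a configurable
[300, 3500] kcal window) and children with no dietary assessment or with no
cardiometabolic measurement at all are removed by :func:`apply_exclusions`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: kcal/day bounds outside which a child's reported intake is implausible.
ENERGY_MIN_KCAL = 300.0
ENERGY_MAX_KCAL = 3500.0

RECORD_COLUMNS = ["child_id", "day", "food_item", "grams", "energy_kcal"]


def _load_packaged_yaml() -> dict:
    with resources.files("cmrdiet.data").joinpath("food_groups.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class FoodGroupMap:
    """Mapping from food items to one of 26 food groups, with frozen order."""

    groups: tuple[str, ...]
    item_to_group: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != len(set(self.groups)):
            raise ValueError("duplicate group labels")
        bad = {i: g for i, g in self.item_to_group.items() if g not in set(self.groups)}
        if bad:
            raise ValueError(f"items mapped to unknown groups: {bad}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @classmethod
    def default(cls) -> "FoodGroupMap":
        """The packaged 26-group map (group order frozen)."""
        data = _load_packaged_yaml()
        return cls(groups=tuple(data["groups"]), item_to_group=dict(data["items"]))

    @classmethod
    def from_yaml(cls, path) -> "FoodGroupMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        items = data.get("item_to_group", data.get("items"))
        return cls(groups=tuple(data["groups"]), item_to_group=dict(items))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"groups": list(self.groups), "item_to_group": dict(self.item_to_group)},
                fh,
                sort_keys=False,
            )


def default_energy_density() -> dict[str, float]:
    """Per-group kcal/g used by the synthetic generator to allocate energy."""
    return dict(_load_packaged_yaml()["energy_density"])


class UnmappedItemsError(ValueError):
    def __init__(self, items: Iterable[str]):
        self.items = sorted(set(items))
        super().__init__(f"food items not in the group map: {self.items}")


def aggregate_recalls(records: pd.DataFrame, group_map: FoodGroupMap | None = None) -> pd.DataFrame:
    """Collapse recall records into per-child energy-adjusted group intakes.

    Parameters
    ----------
    records
        Long table with columns ``child_id, day, food_item, grams, energy_kcal``.
    group_map
        Item-to-group mapping; defaults to the packaged 26-group map.

    Returns
    -------
    DataFrame indexed by ``child_id`` with columns ``energy_kcal_day``, one
    ``<group>`` column per food group (g/100 kcal/day, zero when the child
    never reported the group) and one ``<group>__g_day`` column (g/day).
    Children whose mean daily energy is zero are dropped with a log entry.
    """
    if group_map is None:
        group_map = FoodGroupMap.default()
    missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")

    unmapped = set(records["food_item"]) - set(group_map.item_to_group)
    if unmapped:
        raise UnmappedItemsError(unmapped)

    rec = records.copy()
    rec["group"] = rec["food_item"].map(group_map.item_to_group)

    # grams: sum within (child, day, group), then average over the child's days
    day_grams = (
        rec.pivot_table(
            index=["child_id", "day"], columns="group", values="grams",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(group_map.groups), fill_value=0.0)
    )
    mean_grams = day_grams.groupby(level="child_id").mean()

    day_energy = rec.groupby(["child_id", "day"])["energy_kcal"].sum()
    mean_energy = day_energy.groupby(level="child_id").mean()

    zero_energy = mean_energy.index[mean_energy <= 0]
    if len(zero_energy):
        logger.warning("dropping %d children with zero recorded energy", len(zero_energy))
        mean_energy = mean_energy.drop(zero_energy)
        mean_grams = mean_grams.drop(zero_energy)

    per100 = mean_grams.mul(100.0 / mean_energy, axis=0)
    out = pd.concat(
        [mean_energy.rename("energy_kcal_day"), per100,
         mean_grams.add_suffix("__g_day")],
        axis=1,
    )
    out.index.name = "child_id"
    return out.sort_index()


@dataclass
class ExclusionLog:
    """Counts of children removed per exclusion reason."""

    no_diet: int = 0
    energy_low: int = 0
    energy_high: int = 0
    all_cmr_missing: int = 0
    details: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.no_diet + self.energy_low + self.energy_high + self.all_cmr_missing


def apply_exclusions(
    profiles: pd.DataFrame,
    panels: pd.DataFrame | None = None,
    *,
    energy_min: float = ENERGY_MIN_KCAL,
    energy_max: float = ENERGY_MAX_KCAL,
    cmr_columns: list[str] | None = None,
    all_ids: Iterable | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the cohort-definition filters to aggregated diet profiles.

    Removes (a) children present in ``all_ids`` but absent from ``profiles``
    (no dietary assessment), (b) children with mean daily energy strictly
    above ``energy_max`` or strictly below ``energy_min``, and (c) children
    whose ``panels`` rows are missing for every cardiometabolic column.

    Returns the retained profiles and an :class:`ExclusionLog`.
    """
    log = ExclusionLog()
    if all_ids is not None:
        missing = set(all_ids) - set(profiles.index)
        log.no_diet = len(missing)

    energy = profiles["energy_kcal_day"]
    low = energy < energy_min
    high = energy > energy_max
    log.energy_low = int(low.sum())
    log.energy_high = int(high.sum())
    keep = profiles.loc[~(low | high)]

    if panels is not None:
        if cmr_columns is None:
            cmr_columns = [c for c in panels.columns
                           if c not in ("child_id", "visit", "age", "sex")]
        present = panels.groupby("child_id")[cmr_columns].apply(
            lambda d: bool(d.notna().to_numpy().any())
        )
        all_missing = set(present.index[~present])
        # children with a diet profile but no panel row at all also count
        all_missing |= set(keep.index) - set(panels["child_id"])
        drop = keep.index.intersection(sorted(all_missing))
        log.all_cmr_missing = len(drop)
        keep = keep.drop(drop)

    if keep.empty:
        logger.warning("all children excluded")
    log.details = {"retained": len(keep)}
    return keep, log
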