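"""Convert 24h-recall records into the LP parameters of one target group.

Each child contributes a single 24h recall.  Daily intakes are multiplied by
7 to simulate weekly food intakes; from those weekly distributions come

(i)   the energy equality (7 x the group's daily requirement),
(ii)  minimum/maximum servings from food groups and subgroups per week
      (10th/90th percentiles by default), and
(iii) minimum/maximum grams of each individual food item per week.

Serving sizes are the median portion among *consumers* of the food in the
target group.  Percentile distributions include non-consumers as zeros by
default (configurable), so rarely eaten foods get a genuinely attainable
zero lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CompositionTable,
    ModelParameters,
    ParamFood,
    RecallSet,
    StudyConfig,
    TargetGroup,
)

logger = logging.getLogger(__name__)


def _group_table(recalls: RecallSet, target_group_id: str) -> pd.DataFrame:
    """Per-(child, food) daily grams for one target group (duplicates summed,
    multi-day recalls averaged upstream)."""
    sub = recalls.for_group(target_group_id)
    if sub.empty:
        return sub
    return sub.groupby(["child_id", "food_id"], as_index=False)["grams"].sum()


def median_consumer_portion(
    recalls: RecallSet, food_id: str, target_group_id: str
) -> float:
    """Median daily grams among children who consumed the food (grams summed
    within the day first)."""
    table = _group_table(recalls, target_group_id)
    grams = table.loc[table["food_id"] == food_id, "grams"].to_numpy(float)
    if grams.size == 0:
        raise ValueError(
            f"no consumers of {food_id!r} in target group {target_group_id!r}"
        )
    return float(np.median(grams))


def _per_child_daily(
    recalls: RecallSet, food_ids: list[str], target_group_id: str
) -> np.ndarray:
    """Vector over all children in the group of summed daily grams for the
    given foods; children who ate none of them contribute zeros."""
    table = _group_table(recalls, target_group_id)
    children = recalls.children(target_group_id)
    sel = table[table["food_id"].isin(food_ids)]
    per_child = sel.groupby("child_id")["grams"].sum()
    return np.array([per_child.get(c, 0.0) for c in children], float)


def weekly_item_gram_bounds(
    recalls: RecallSet,
    food_id: str,
    target_group_id: str,
    p_lo: float = 10.0,
    p_hi: float = 90.0,
    consumers_only: bool = False,
) -> tuple[float, float]:
    """(P_lo, P_hi) of the per-child weekly-gram distribution (daily x 7),
    lower bound floored at 0."""
    if p_lo >= p_hi:
        raise ValueError(f"p_lo={p_lo} must be < p_hi={p_hi}")
    daily = _per_child_daily(recalls, [food_id], target_group_id)
    if daily.size == 0 or daily.max() <= 0:
        raise ValueError(
            f"{food_id!r} not consumed in target group {target_group_id!r}"
        )
    if consumers_only:
        daily = daily[daily > 0]
    weekly = 7.0 * daily
    lo, hi = np.percentile(weekly, [p_lo, p_hi], method="linear")
    return (max(0.0, float(lo)), float(hi))


def _group_daily_servings(
    recalls: RecallSet,
    member_foods: list[str],
    target_group_id: str,
    portions: dict[str, float],
) -> np.ndarray:
    """Per child, daily servings for a food group = sum over member foods of
    grams / that food's portion size."""
    table = _group_table(recalls, target_group_id)
    children = recalls.children(target_group_id)
    sel = table[table["food_id"].isin(member_foods)].copy()
    if sel.empty:
        return np.zeros(len(children))
    sel["servings"] = sel["grams"] / sel["food_id"].map(portions)
    per_child = sel.groupby("child_id")["servings"].sum()
    return np.array([per_child.get(c, 0.0) for c in children], float)


def weekly_group_serving_bounds(
    recalls: RecallSet,
    member_foods: list[str],
    target_group_id: str,
    portions: dict[str, float],
    p_lo: float = 10.0,
    p_hi: float = 90.0,
    consumers_only: bool = False,
) -> tuple[float, float]:
    """(P_lo, P_hi) of 7 x the per-child daily group servings distribution."""
    if p_lo >= p_hi:
        raise ValueError(f"p_lo={p_lo} must be < p_hi={p_hi}")
    daily = _group_daily_servings(recalls, member_foods, target_group_id, portions)
    if daily.size == 0 or daily.max() <= 0:
        return (0.0, 0.0)
    if consumers_only:
        daily = daily[daily > 0]
    weekly = 7.0 * daily
    lo, hi = np.percentile(weekly, [p_lo, p_hi], method="linear")
    return (max(0.0, float(lo)), float(hi))


def observed_median_group_servings(
    recalls: RecallSet,
    member_foods: list[str],
    target_group_id: str,
    portions: dict[str, float],
) -> float:
    """Median over all children of 7 x daily group servings (0 when the group
    is unconsumed)."""
    daily = _group_daily_servings(recalls, member_foods, target_group_id, portions)
    if daily.size == 0:
        return 0.0
    return float(np.median(7.0 * daily))


@dataclass
class ConsumptionSummary:
    """Audit summary of one target group's consumption patterns."""

    target_group_id: str
    n_children: int
    consumers: dict[str, int]  # food id -> number of consumers
    portions: dict[str, float]  # food id -> median consumer portion (g)


def summarize_consumption(
    recalls: RecallSet, target_group_id: str
) -> ConsumptionSummary:
    table = _group_table(recalls, target_group_id)
    n_children = len(recalls.children(target_group_id))
    consumers = table.groupby("food_id")["child_id"].nunique().to_dict()
    portions = {
        f: median_consumer_portion(recalls, f, target_group_id) for f in consumers
    }
    return ConsumptionSummary(target_group_id, n_children, consumers, portions)


def build_model_parameters(
    recalls: RecallSet,
    composition: CompositionTable,
    config: StudyConfig,
    target_group: TargetGroup,
) -> ModelParameters:
    """Assemble one target group's complete LP inputs.

    Every food consumed by at least one child in the group enters the model
    with its median consumer portion and weekly gram bounds; group and
    subgroup serving bounds are attached for every represented label.
    """
    th = config.thresholds
    gid = target_group.id
    food_ids = recalls.foods(gid)
    if not food_ids:
        raise ValueError(f"no recall records for target group {gid!r}")
    unknown = [f for f in food_ids if f not in composition]
    if unknown:
        raise ValueError(f"recall foods absent from composition table: {unknown}")

    portions = {f: median_consumer_portion(recalls, f, gid) for f in food_ids}
    table = _group_table(recalls, gid)
    n_consumers = table.groupby("food_id")["child_id"].nunique()
    foods = []
    for f in food_ids:
        if n_consumers[f] < 2:
            # A food reported by a single child stays in the model with a
            # zero floor and a ceiling of 7 x its observed daily grams.
            observed = float(table.loc[table["food_id"] == f, "grams"].sum())
            bounds = (0.0, 7.0 * observed)
        else:
            bounds = weekly_item_gram_bounds(
                recalls, f, gid, th.p_lo, th.p_hi,
                consumers_only=th.bounds_over_consumers_only,
            )
        members = [f]
        med = observed_median_group_servings(recalls, members, gid, portions)
        foods.append(
            ParamFood(
                food_id=f,
                portion_g=portions[f],
                gram_bounds=bounds,
                observed_median_servings_per_week=med,
            )
        )

    def label_bounds(level: str) -> tuple[dict, dict]:
        labels = sorted(
            {
                composition[f].group_id if level == "group" else composition[f].subgroup_id
                for f in food_ids
            }
        )
        bounds, medians = {}, {}
        for label in labels:
            members = [
                f for f in food_ids
                if (composition[f].group_id if level == "group" else composition[f].subgroup_id)
                == label
            ]
            bounds[label] = weekly_group_serving_bounds(
                recalls, members, gid, portions, th.p_lo, th.p_hi,
                consumers_only=th.bounds_over_consumers_only,
            )
            medians[label] = observed_median_group_servings(
                recalls, members, gid, portions
            )
        return bounds, medians

    group_bounds, group_medians = label_bounds("group")
    subgroup_bounds, subgroup_medians = label_bounds("subgroup")

    params = ModelParameters(
        target_group=target_group,
        foods=foods,
        group_bounds=group_bounds,
        subgroup_bounds=subgroup_bounds,
        observed_median_group_servings=group_medians,
        observed_median_subgroup_servings=subgroup_medians,
        composition=composition,
    )
    params.validate()
    logger.info(
        "parameters for %s: %d foods, %d groups, %d subgroups, energy %d kcal/week",
        gid, len(foods), len(group_bounds), len(subgroup_bounds),
        round(params.weekly_energy_target),
    )
    return params


def parameters_to_dict(params: ModelParameters) -> dict:
    """JSON-serializable dump of ModelParameters for audit output."""
    return {
        "target_group": params.target_group.id,
        "weekly_energy_target_kcal": params.weekly_energy_target,
        "breast_milk_grams_per_week": params.weekly_breast_milk_grams,
        "foods": [
            {
                "food_id": pf.food_id,
                "portion_g": pf.portion_g,
                "gram_bounds_per_week": list(pf.gram_bounds),
                "observed_median_servings_per_week": pf.observed_median_servings_per_week,
            }
            for pf in params.foods
        ],
        "group_bounds": {k: list(v) for k, v in sorted(params.group_bounds.items())},
        "subgroup_bounds": {
            k: list(v) for k, v in sorted(params.subgroup_bounds.items())
        },
        "observed_median_group_servings": dict(
            sorted(params.observed_median_group_servings.items())
        ),
        "observed_median_subgroup_servings": dict(
            sorted(params.observed_median_subgroup_servings.items())
        ),
    }
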