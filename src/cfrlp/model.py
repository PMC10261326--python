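"""Domain types shared by every stage of the pipeline.

The analysis revolves around nine *target groups* (three age bands during the
complementary feeding period crossed with three livelihood strata).  Each
target group carries its own energy requirement, breast-milk assumption and
recommended nutrient intakes (RNIs); diets are modelled on a 7-day horizon
with servings/week as the decision variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "KCAL_TO_KJ",
    "AGE_BANDS",
    "DEFAULT_BM_ENERGY_FRACTION",
    "DEFAULT_BM_GRAMS_PER_DAY",
    "DEFAULT_BM_ENERGY_DENSITY_KCAL_G",
    "TARGET_MICRONUTRIENTS",
    "ExclusionReason",
    "Nutrient",
    "FoodItem",
    "CompositionTable",
    "BreastMilkAssumption",
    "TargetGroup",
    "RecallSet",
    "ParamFood",
    "ModelParameters",
    "DietSolution",
    "CFR",
    "CFRSetResult",
    "Thresholds",
    "StudyConfig",
    "kcal_to_kj",
]

# Exact thermochemical calorie; kJ appears only at presentation time.
KCAL_TO_KJ = 4.184

AGE_BANDS = ("m6_8", "m9_11", "m12_23")

# Breast milk is assumed, not measured: it contributes a fixed fraction of the
# median energy requirement in each age band, at 0.66 kcal/g.
DEFAULT_BM_ENERGY_FRACTION = {"m6_8": 0.67, "m9_11": 0.55, "m12_23": 0.39}
DEFAULT_BM_GRAMS_PER_DAY = {"m6_8": 570.0, "m9_11": 520.0, "m12_23": 420.0}
DEFAULT_BM_ENERGY_DENSITY_KCAL_G = 0.66

# The eleven micronutrients whose adequacy is modelled.  Energy and protein
# are tracked but never classified as problem nutrients.
TARGET_MICRONUTRIENTS = (
    "calcium",
    "iron",
    "zinc",
    "riboflavin",
    "niacin",
    "thiamin",
    "folate",
    "vitamin_a",
    "vitamin_b6",
    "vitamin_b12",
    "vitamin_c",
)


def kcal_to_kj(kcal: float) -> float:
    return kcal * KCAL_TO_KJ


class ExclusionReason(str, Enum):
    condiment = "condiment"
    no_nutritional_value = "no_nutritional_value"
    therapeutic = "therapeutic"
    uncommon = "uncommon"
    none = "none"


@dataclass(frozen=True)
class Nutrient:
    id: str
    name: str
    unit: str
    is_target_micronutrient: bool = False


@dataclass
class FoodItem:
    """One food with nutrient densities per 100 g edible portion."""

    id: str
    name: str
    group_id: str
    subgroup_id: str
    composition: dict[str, float]
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.none

    def density(self, nutrient_id: str) -> float:
        return self.composition.get(nutrient_id, 0.0)


@dataclass
class CompositionTable:
    """Food-composition table keyed by food id."""

    foods: dict[str, FoodItem]
    nutrient_ids: list[str]

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.foods

    def __getitem__(self, food_id: str) -> FoodItem:
        return self.foods[food_id]

    def __len__(self) -> int:
        return len(self.foods)

    def subgroup_of(self, food_id: str) -> str:
        return self.foods[food_id].subgroup_id

    def group_of(self, food_id: str) -> str:
        return self.foods[food_id].group_id

    def included_ids(self) -> list[str]:
        return [f.id for f in self.foods.values() if not f.excluded]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.foods.values():
            row = {
                "food_id": f.id,
                "name": f.name,
                "group": f.group_id,
                "subgroup": f.subgroup_id,
            }
            for n in self.nutrient_ids:
                row[n] = f.composition.get(n, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BreastMilkAssumption:
    """Fixed breast-milk intake for one age band.

    ``energy_fraction`` is the share of the median daily energy requirement
    assumed to come from breast milk; ``grams_per_day`` the corresponding
    intake at ``energy_density`` kcal/g.  ``composition`` is a per-100 g
    nutrient density vector (a config input; never estimated from recalls).
    """

    age_band: str
    energy_fraction: float
    grams_per_day: float
    energy_density: float = DEFAULT_BM_ENERGY_DENSITY_KCAL_G
    composition: dict[str, float] = field(default_factory=dict)

    @property
    def energy_per_day(self) -> float:
        return self.grams_per_day * self.energy_density

    def daily_amount(self, nutrient_id: str) -> float:
        """Daily nutrient contribution (nutrient units/day)."""
        if nutrient_id == "energy":
            return self.energy_per_day
        return self.grams_per_day * self.composition.get(nutrient_id, 0.0) / 100.0

    @classmethod
    def default_for(cls, age_band: str, composition: Optional[Mapping[str, float]] = None):
        return cls(
            age_band=age_band,
            energy_fraction=DEFAULT_BM_ENERGY_FRACTION[age_band],
            grams_per_day=DEFAULT_BM_GRAMS_PER_DAY[age_band],
            composition=dict(composition or {}),
        )


@dataclass
class TargetGroup:
    """One age band x livelihood stratum with its LP-relevant assumptions."""

    id: str
    age_band: str
    livelihood: str
    energy_requirement: float  # kcal/day
    rni: dict[str, float]  # nutrient id -> daily RNI in nutrient units
    breast_milk: BreastMilkAssumption
    # Labels recording which RNI column was chosen; not multipliers.
    zinc_bioavailability_level: str = "15%"
    iron_bioavailability_level: str = "5%"

    def validate(self) -> None:
        missing = [n for n in TARGET_MICRONUTRIENTS if self.rni.get(n, 0.0) <= 0]
        if missing:
            raise ValueError(
                f"target group {self.id}: missing/non-positive RNI for {missing}"
            )


@dataclass
class RecallSet:
    """Single 24h recalls, one row per (child, food): child_id, target_group,
    food_id, grams. Duplicate (child, food) rows are summed on load."""

    records: pd.DataFrame
    excluded_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["child_id", "target_group", "food_id", "grams", "reason"]
        )
    )

    COLUMNS = ["child_id", "target_group", "food_id", "grams"]

    def for_group(self, target_group_id: str) -> pd.DataFrame:
        return self.records[self.records["target_group"] == target_group_id]

    def children(self, target_group_id: str) -> list[str]:
        sub = self.for_group(target_group_id)
        return sorted(sub["child_id"].unique())

    def foods(self, target_group_id: str) -> list[str]:
        return sorted(self.for_group(target_group_id)["food_id"].unique())

    def total_grams(self) -> float:
        return float(self.records["grams"].sum())


@dataclass
class ParamFood:
    """Per-food LP inputs for one target group."""

    food_id: str
    portion_g: float  # median consumer portion, grams/serving
    gram_bounds: tuple[float, float]  # weekly grams (min, max)
    observed_median_servings_per_week: float

    @property
    def serving_bounds(self) -> tuple[float, float]:
        return (
            self.gram_bounds[0] / self.portion_g,
            self.gram_bounds[1] / self.portion_g,
        )


@dataclass
class ModelParameters:
    """Complete LP inputs for one target group (7-day horizon)."""

    target_group: TargetGroup
    foods: list[ParamFood]
    group_bounds: dict[str, tuple[float, float]]  # servings/week
    subgroup_bounds: dict[str, tuple[float, float]]
    observed_median_group_servings: dict[str, float]
    observed_median_subgroup_servings: dict[str, float]
    composition: CompositionTable

    @property
    def weekly_energy_target(self) -> float:
        return 7.0 * self.target_group.energy_requirement

    @property
    def weekly_breast_milk_grams(self) -> float:
        return 7.0 * self.target_group.breast_milk.grams_per_day

    def breast_milk_weekly(self, nutrient_id: str) -> float:
        return 7.0 * self.target_group.breast_milk.daily_amount(nutrient_id)

    def food_ids(self) -> list[str]:
        return [pf.food_id for pf in self.foods]

    def members(self, level: str, target_id: str) -> list[str]:
        """Indices of foods belonging to a group/subgroup, in model order."""
        out = []
        for i, pf in enumerate(self.foods):
            item = self.composition[pf.food_id]
            label = item.group_id if level == "group" else item.subgroup_id
            if label == target_id:
                out.append(i)
        return out

    def validate(self) -> None:
        for pf in self.foods:
            if pf.portion_g <= 0:
                raise ValueError(f"non-positive portion for {pf.food_id}")
            if pf.gram_bounds[0] > pf.gram_bounds[1]:
                raise ValueError(f"gram bounds inverted for {pf.food_id}")
        for d in (self.group_bounds, self.subgroup_bounds):
            for g, (lo, hi) in d.items():
                if lo > hi:
                    raise ValueError(f"serving bounds inverted for {g}")
        bm_energy = self.breast_milk_weekly("energy")
        if bm_energy > self.weekly_energy_target:
            raise ValueError(
                f"breast milk alone exceeds energy target for "
                f"{self.target_group.id}: {bm_energy:.0f} kcal/week "
                f"> {self.weekly_energy_target:.0f} kcal/week"
            )


@dataclass
class DietSolution:
    """A modelled 7-day diet."""

    status: str  # "optimal" | "infeasible"
    servings: dict[str, float]  # food id -> servings/week
    nutrient_totals: dict[str, float]  # nutrient id -> amount/day (bm incl.)
    pct_rni: dict[str, float]  # nutrient id -> percent of RNI
    objective_value: float = float("nan")
    diagnosis: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @classmethod
    def infeasible(cls, diagnosis: str = "") -> "DietSolution":
        return cls(status="infeasible", servings={}, nutrient_totals={},
                   pct_rni={}, diagnosis=diagnosis)


@dataclass(frozen=True)
class CFR:
    """A complementary feeding recommendation: a promoted weekly consumption
    level of a food group or subgroup, on top of breast-feeding on demand."""

    level: str  # "group" | "subgroup"
    target_id: str
    servings_per_week: float
    portion_g: float

    @property
    def identity(self) -> tuple[str, str]:
        return (self.level, self.target_id)


@dataclass
class CFRSetResult:
    """Worst-case (per-nutrient minimized) adequacy of one CFR set."""

    cfr_set: list[CFR]
    minimized_pct_rni: dict[str, float]
    n_adequate: Optional[int]  # None when infeasible ("NF")
    feasible: bool
    diet_cost: Optional[float] = None

    @property
    def member_ids(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(c.identity for c in self.cfr_set))


@dataclass
class Thresholds:
    """Decision thresholds of the analysis, in percent of RNI unless noted."""

    adequacy_cutoff: float = 65.0  # minimized %RNI >= this => adequate
    rni_cutoff: float = 100.0  # problem-nutrient boundary
    source_share: float = 5.0  # best-source share threshold, percent
    source_min_nutrients: int = 5  # micronutrients needed to flag a source
    p_lo: float = 10.0  # lower percentile for weekly bounds
    p_hi: float = 90.0  # upper percentile for weekly bounds
    keep_k: int = 8  # candidates kept after screening
    max_set_size: int = 5  # largest CFR combination tested
    energy_slack: float = 0.0  # relative slack on the energy equality
    bounds_over_consumers_only: bool = False


@dataclass
class StudyConfig:
    """Fully validated study configuration."""

    nutrients: list[Nutrient]
    target_groups: list[TargetGroup]
    thresholds: Thresholds = field(default_factory=Thresholds)
    exclusions: dict[str, str] = field(default_factory=dict)  # food id -> reason

    def nutrient_ids(self) -> list[str]:
        return [n.id for n in self.nutrients]

    def target_micronutrients(self) -> list[str]:
        return [n.id for n in self.nutrients if n.is_target_micronutrient]

    def group(self, group_id: str) -> TargetGroup:
        for tg in self.target_groups:
            if tg.id == group_id:
                return tg
        raise KeyError(group_id)

    def validate(self) -> None:
        n_target = sum(n.is_target_micronutrient for n in self.nutrients)
        if n_target == 0:
            raise ValueError("no target micronutrients declared")
        for tg in self.target_groups:
            tg.validate()
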