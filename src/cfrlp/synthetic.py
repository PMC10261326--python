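"""Synthetic food systems and 24h-recall surveys with planted ground truth.

The generator emulates the statistical structure the analysis assumes so that
every pipeline stage is testable without external data: nine target groups
(three age bands x three livelihood strata), a food catalog dominated by
dairy, grains, added fats and sugar, skewed consumption frequencies,
lognormal portions, and per-livelihood food availability.

Planted truth is calibrated constructively, not by trial:

* *gap* nutrients are made scarce system-wide.  Under the energy equality,
  any diet's intake of nutrient n is at most
  ``budget x max_f(density_f / energy_density_f)`` plus the breast-milk term,
  so capping each food's gap density at
  ``(margin x RNI - breast_milk) x energy_f / budget`` (taken over all bands)
  guarantees even the maximized diet stays below the RNI — the nutrient is an
  absolute problem by construction.
* *fix* pairs (subgroup, nutrient) are made rich: the subgroup's density for
  that nutrient is raised until it clearly dominates the rest of the food
  system, so the subgroup is flagged by the best-source rule wherever it is
  available.
* a *uniquely optimal CFR* is planted through a signature nutrient
  (vitamin B12) carried almost exclusively by animal milk: the worst-case
  diet without a dairy recommendation stays below the adequacy cutoff, while
  any recommended weekly level of milk lifts it above — every winning CFR set
  must therefore contain the dairy recommendation.

Everything is deterministic per seed (named substreams per stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    AGE_BANDS,
    DEFAULT_BM_ENERGY_FRACTION,
    BreastMilkAssumption,
    CompositionTable,
    FoodItem,
    RecallSet,
    StudyConfig,
    TargetGroup,
    Thresholds,
)
from .io import _default_nutrients

LIVELIHOODS = ("settled", "pastoralist", "agro_pastoralist")

#: Placeholder breast-milk composition per 100 g (synthetic stand-in for the
#: mature-human-milk vector the analysis takes as a config input).
BREAST_MILK_COMPOSITION = {
    "protein": 1.0, "fat": 4.4, "calcium": 28.0, "iron": 0.03, "zinc": 0.12,
    "riboflavin": 0.035, "niacin": 0.18, "thiamin": 0.014, "folate": 8.5,
    "vitamin_a": 48.0, "vitamin_b6": 0.011, "vitamin_b12": 0.05,
    "vitamin_c": 5.0,
}

#: Daily energy requirements (kcal) by age band — config inputs of the study,
#: set to values typical of breast-fed children at these ages.
DEFAULT_ENERGY_REQUIREMENTS = {"m6_8": 615.0, "m9_11": 686.0, "m12_23": 894.0}

#: Daily RNIs by age band (FAO/WHO-2004-like placeholder values; Fe at the 5 %
#: and Zn at the 15 % bioavailability column).
DEFAULT_RNI = {
    "m6_8": {
        "calcium": 400.0, "iron": 18.6, "zinc": 4.1, "riboflavin": 0.4,
        "niacin": 4.0, "thiamin": 0.3, "folate": 80.0, "vitamin_a": 400.0,
        "vitamin_b6": 0.3, "vitamin_b12": 0.7, "vitamin_c": 30.0,
    },
    "m9_11": {
        "calcium": 400.0, "iron": 18.6, "zinc": 4.1, "riboflavin": 0.4,
        "niacin": 4.0, "thiamin": 0.3, "folate": 80.0, "vitamin_a": 400.0,
        "vitamin_b6": 0.3, "vitamin_b12": 0.7, "vitamin_c": 30.0,
    },
    "m12_23": {
        "calcium": 500.0, "iron": 11.6, "zinc": 4.8, "riboflavin": 0.5,
        "niacin": 6.0, "thiamin": 0.5, "folate": 150.0, "vitamin_a": 400.0,
        "vitamin_b6": 0.5, "vitamin_b12": 0.9, "vitamin_c": 30.0,
    },
}

_NUTRIENTS = ["energy", "protein", "fat", "calcium", "iron", "zinc",
              "riboflavin", "niacin", "thiamin", "folate", "vitamin_a",
              "vitamin_b6", "vitamin_b12", "vitamin_c"]

# Catalog entry: (food_id, group, subgroup, base portion g, consumption
# probability per livelihood (None = unavailable), base composition/100 g).
# The diet is deliberately dominated by dairy, grains, added fats and sugar.
_CATALOG = [
    ("cow_milk", "dairy", "animal_milk", 120,
     {"settled": 0.50, "pastoralist": None, "agro_pastoralist": None},
     dict(energy=64, protein=3.3, fat=3.7, calcium=119, iron=0.05, zinc=0.40,
          riboflavin=0.17, niacin=0.10, thiamin=0.04, folate=5, vitamin_a=46,
          vitamin_b6=0.04, vitamin_b12=0.45, vitamin_c=1.0)),
    ("goat_milk", "dairy", "animal_milk", 110,
     {"settled": 0.35, "pastoralist": 0.30, "agro_pastoralist": 0.55},
     dict(energy=69, protein=3.6, fat=4.1, calcium=134, iron=0.05, zinc=0.30,
          riboflavin=0.14, niacin=0.28, thiamin=0.05, folate=1, vitamin_a=57,
          vitamin_b6=0.05, vitamin_b12=0.45, vitamin_c=1.3)),
    ("camel_milk", "dairy", "animal_milk", 130,
     {"settled": None, "pastoralist": 0.65, "agro_pastoralist": None},
     dict(energy=61, protein=3.0, fat=3.5, calcium=105, iron=0.05, zinc=0.40,
          riboflavin=0.16, niacin=0.20, thiamin=0.03, folate=1, vitamin_a=50,
          vitamin_b6=0.05, vitamin_b12=0.45, vitamin_c=3.0)),
    ("maize_flour", "grains", "refined_grains", 70,
     {"settled": 0.70, "pastoralist": 0.70, "agro_pastoralist": 0.75},
     dict(energy=365, protein=9.4, fat=3.9, calcium=7, iron=2.7, zinc=1.7,
          riboflavin=0.20, niacin=3.6, thiamin=0.39, folate=25, vitamin_a=0,
          vitamin_b6=0.40, vitamin_b12=0, vitamin_c=0)),
    ("rice", "grains", "refined_grains", 60,
     {"settled": 0.50, "pastoralist": 0.45, "agro_pastoralist": None},
     dict(energy=360, protein=6.6, fat=0.6, calcium=9, iron=0.8, zinc=1.1,
          riboflavin=0.05, niacin=1.6, thiamin=0.07, folate=8, vitamin_a=0,
          vitamin_b6=0.16, vitamin_b12=0, vitamin_c=0)),
    ("spaghetti", "grains", "refined_grains", 45,
     {"settled": 0.20, "pastoralist": 0.15, "agro_pastoralist": None},
     dict(energy=371, protein=13.0, fat=1.5, calcium=21, iron=1.3, zinc=1.4,
          riboflavin=0.06, niacin=1.7, thiamin=0.09, folate=18, vitamin_a=0,
          vitamin_b6=0.14, vitamin_b12=0, vitamin_c=0)),
    ("sorghum", "grains", "whole_grains", 55,
     {"settled": 0.15, "pastoralist": 0.20, "agro_pastoralist": 0.45},
     dict(energy=339, protein=11.3, fat=3.3, calcium=28, iron=4.4, zinc=1.6,
          riboflavin=0.14, niacin=2.9, thiamin=0.24, folate=20, vitamin_a=0,
          vitamin_b6=0.44, vitamin_b12=0, vitamin_c=0)),
    ("millet_flour", "grains", "whole_grains", 55,
     {"settled": 0.15, "pastoralist": 0.15, "agro_pastoralist": 0.35},
     dict(energy=382, protein=11.0, fat=4.2, calcium=8, iron=3.0, zinc=1.7,
          riboflavin=0.29, niacin=4.7, thiamin=0.42, folate=85, vitamin_a=0,
          vitamin_b6=0.38, vitamin_b12=0, vitamin_c=0)),
    ("potato", "starchy_plants", "roots_tubers", 60,
     {"settled": 0.40, "pastoralist": 0.30, "agro_pastoralist": 0.30},
     dict(energy=77, protein=2.0, fat=0.1, calcium=12, iron=0.8, zinc=0.30,
          riboflavin=0.03, niacin=1.1, thiamin=0.08, folate=16, vitamin_a=0,
          vitamin_b6=0.30, vitamin_b12=0, vitamin_c=20)),
    ("green_banana", "starchy_plants", "roots_tubers", 55,
     {"settled": 0.25, "pastoralist": 0.15, "agro_pastoralist": 0.15},
     dict(energy=89, protein=1.1, fat=0.3, calcium=5, iron=0.3, zinc=0.15,
          riboflavin=0.07, niacin=0.7, thiamin=0.03, folate=20, vitamin_a=3,
          vitamin_b6=0.37, vitamin_b12=0, vitamin_c=9)),
    ("cassava", "starchy_plants", "roots_tubers", 55,
     {"settled": None, "pastoralist": None, "agro_pastoralist": 0.30},
     dict(energy=160, protein=1.4, fat=0.3, calcium=16, iron=0.3, zinc=0.34,
          riboflavin=0.05, niacin=0.85, thiamin=0.09, folate=27, vitamin_a=1,
          vitamin_b6=0.09, vitamin_b12=0, vitamin_c=21)),
    # Legumes are modelled as thick whole-bean preparations, nutrient-dense
    # per 100 g as consumed — the catalog's designated multi-nutrient
    # plant-source subgroup (planted-fix target).
    ("pinto_beans", "legumes", "beans", 50,
     {"settled": 0.45, "pastoralist": 0.30, "agro_pastoralist": 0.40},
     dict(energy=143, protein=9.0, fat=0.7, calcium=50, iron=2.1, zinc=1.3,
          riboflavin=0.10, niacin=0.9, thiamin=0.30, folate=172, vitamin_a=0,
          vitamin_b6=0.30, vitamin_b12=0, vitamin_c=0.8)),
    ("mung_beans", "legumes", "beans", 50,
     {"settled": 0.25, "pastoralist": 0.20, "agro_pastoralist": 0.30},
     dict(energy=120, protein=7.5, fat=0.4, calcium=40, iron=1.8, zinc=1.1,
          riboflavin=0.10, niacin=0.8, thiamin=0.25, folate=159, vitamin_a=1,
          vitamin_b6=0.25, vitamin_b12=0, vitamin_c=1.0)),
    ("black_beans", "legumes", "beans", 50,
     {"settled": 0.25, "pastoralist": None, "agro_pastoralist": 0.25},
     dict(energy=132, protein=8.9, fat=0.5, calcium=40, iron=2.1, zinc=1.2,
          riboflavin=0.10, niacin=0.85, thiamin=0.28, folate=149, vitamin_a=0,
          vitamin_b6=0.28, vitamin_b12=0, vitamin_c=0)),
    ("vegetable_oil", "fats_oils", "added_fats", 10,
     {"settled": 0.80, "pastoralist": 0.75, "agro_pastoralist": 0.80},
     dict(energy=884, protein=0, fat=100, calcium=0, iron=0, zinc=0,
          riboflavin=0, niacin=0, thiamin=0, folate=0, vitamin_a=0,
          vitamin_b6=0, vitamin_b12=0, vitamin_c=0)),
    ("fortified_margarine", "fats_oils", "added_fats", 8,
     {"settled": 0.30, "pastoralist": 0.25, "agro_pastoralist": None},
     dict(energy=717, protein=0.2, fat=80, calcium=3, iron=0, zinc=0,
          riboflavin=0.01, niacin=0, thiamin=0.01, folate=1, vitamin_a=800,
          vitamin_b6=0, vitamin_b12=0, vitamin_c=0)),
    ("sugar", "fats_oils", "added_sugar", 15,
     {"settled": 0.85, "pastoralist": 0.85, "agro_pastoralist": 0.80},
     dict(energy=387, protein=0, fat=0, calcium=1, iron=0.05, zinc=0,
          riboflavin=0.02, niacin=0, thiamin=0, folate=0, vitamin_a=0,
          vitamin_b6=0, vitamin_b12=0, vitamin_c=0)),
    ("kale", "vegetables", "leafy_vegetables", 30,
     {"settled": 0.20, "pastoralist": None, "agro_pastoralist": 0.10},
     dict(energy=49, protein=4.3, fat=0.9, calcium=150, iron=1.5, zinc=0.6,
          riboflavin=0.13, niacin=1.0, thiamin=0.11, folate=141, vitamin_a=500,
          vitamin_b6=0.27, vitamin_b12=0, vitamin_c=120)),
    ("tomato", "vegetables", "other_vegetables", 25,
     {"settled": 0.35, "pastoralist": 0.25, "agro_pastoralist": 0.25},
     dict(energy=18, protein=0.9, fat=0.2, calcium=10, iron=0.27, zinc=0.17,
          riboflavin=0.019, niacin=0.59, thiamin=0.037, folate=15, vitamin_a=42,
          vitamin_b6=0.08, vitamin_b12=0, vitamin_c=14)),
    ("onion", "vegetables", "other_vegetables", 20,
     {"settled": 0.30, "pastoralist": 0.25, "agro_pastoralist": 0.20},
     dict(energy=40, protein=1.1, fat=0.1, calcium=23, iron=0.21, zinc=0.17,
          riboflavin=0.027, niacin=0.12, thiamin=0.046, folate=19, vitamin_a=0,
          vitamin_b6=0.12, vitamin_b12=0, vitamin_c=7.4)),
    ("carrot", "vegetables", "other_vegetables", 25,
     {"settled": 0.15, "pastoralist": 0.10, "agro_pastoralist": None},
     dict(energy=41, protein=0.9, fat=0.2, calcium=33, iron=0.30, zinc=0.24,
          riboflavin=0.058, niacin=0.98, thiamin=0.066, folate=19, vitamin_a=835,
          vitamin_b6=0.14, vitamin_b12=0, vitamin_c=5.9)),
    ("banana", "fruit", "fruit", 60,
     {"settled": 0.15, "pastoralist": None, "agro_pastoralist": None},
     dict(energy=89, protein=1.1, fat=0.3, calcium=5, iron=0.26, zinc=0.15,
          riboflavin=0.073, niacin=0.67, thiamin=0.031, folate=20, vitamin_a=3,
          vitamin_b6=0.37, vitamin_b12=0, vitamin_c=8.7)),
    ("papaya", "fruit", "fruit", 55,
     {"settled": 0.10, "pastoralist": None, "agro_pastoralist": None},
     dict(energy=43, protein=0.5, fat=0.3, calcium=20, iron=0.25, zinc=0.08,
          riboflavin=0.027, niacin=0.36, thiamin=0.023, folate=37, vitamin_a=47,
          vitamin_b6=0.04, vitamin_b12=0, vitamin_c=61)),
    ("goat_meat", "meat", "red_meat", 30,
     {"settled": 0.08, "pastoralist": 0.10, "agro_pastoralist": None},
     dict(energy=143, protein=27.0, fat=3.0, calcium=17, iron=3.7, zinc=4.0,
          riboflavin=0.61, niacin=4.0, thiamin=0.10, folate=5, vitamin_a=0,
          vitamin_b6=0.10, vitamin_b12=0.30, vitamin_c=0)),
    ("mutton", "meat", "red_meat", 30,
     {"settled": 0.05, "pastoralist": 0.08, "agro_pastoralist": None},
     dict(energy=160, protein=25.0, fat=6.5, calcium=15, iron=2.7, zinc=3.9,
          riboflavin=0.40, niacin=4.5, thiamin=0.12, folate=3, vitamin_a=0,
          vitamin_b6=0.13, vitamin_b12=0.30, vitamin_c=0)),
]

_BAND_PORTION_FACTOR = {"m6_8": 0.70, "m9_11": 0.85, "m12_23": 1.00}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; defaults mirror the survey design
    (95 children per age band per livelihood, nine target groups)."""

    seed: int = 0
    n_children: int = 95
    livelihoods: tuple[str, ...] = LIVELIHOODS
    planted_gaps: tuple[str, ...] = ("iron", "zinc")
    planted_fixes: tuple[tuple[str, str], ...] = (
        ("beans", "folate"),
        ("animal_milk", "vitamin_b12"),
    )
    planted_unique_cfr: Optional[tuple[str, str]] = ("subgroup", "animal_milk")
    signature_nutrient: str = "vitamin_b12"
    gap_margin: float = 0.85  # maximized-diet ceiling as a fraction of RNI
    fix_dominance: float = 3.0  # fix subgroup density vs rest-of-system mean
    portion_sigma: float = 0.40  # lognormal dispersion of portions
    energy_sigma: float = 0.12  # lognormal dispersion of child energy intake
    density_jitter: float = 0.08  # lognormal jitter on nutrient densities
    #: per-food consumption-probability overrides (applied in every
    #: livelihood where the food is available)
    probability_overrides: dict = field(default_factory=dict)
    energy_requirements: dict = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_REQUIREMENTS))
    rni: dict = field(default_factory=lambda: {b: dict(v) for b, v in DEFAULT_RNI.items()})

    def group_id(self, livelihood: str, band: str) -> str:
        return f"{livelihood}_{band}"

    def group_ids(self) -> list[str]:
        return [self.group_id(l, b) for l in self.livelihoods for b in AGE_BANDS]

    def complementary_budget(self, band: str) -> float:
        """Daily kcal to come from complementary foods."""
        return self.energy_requirements[band] * (1.0 - DEFAULT_BM_ENERGY_FRACTION[band])

    def validate(self) -> None:
        if not self.livelihoods:
            raise ValueError("empty livelihood list")
        known = {e[0] for e in _CATALOG}
        subgroups = {e[2] for e in _CATALOG}
        for sg, n in self.planted_fixes:
            if sg not in subgroups:
                raise ValueError(f"planted fix references unknown subgroup {sg!r}")
            if n in self.planted_gaps:
                raise ValueError(
                    f"contradictory plant: {n!r} is both a gap and a fix nutrient"
                )
        for l in self.livelihoods:
            if not any(e[4].get(l) for e in _CATALOG):
                raise ValueError(f"no foods available for livelihood {l!r}")


@dataclass
class GroundTruth:
    """Expected pipeline findings implied by the planted structure."""

    gap_nutrients: list[str]
    fixes: list[tuple[str, str]]  # (subgroup, nutrient)
    winning_identity: Optional[tuple[str, str]]
    intended_portions: dict  # group id -> {food id -> median grams}
    complementary_budgets: dict  # group id -> kcal/day from complementary foods

    def empty(self) -> bool:
        return not (self.gap_nutrients or self.fixes or self.winning_identity)


def _rng(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), *stream])


def _gap_caps(spec: SyntheticSpec, nutrient: str, energy_density: float) -> float:
    """Max density/100 g for ``nutrient`` in a food of given energy density so
    that no energy-feasible diet reaches ``gap_margin`` x RNI in any band."""
    caps = []
    for band in AGE_BANDS:
        rni = spec.rni[band][nutrient]
        bm = BreastMilkAssumption.default_for(band, BREAST_MILK_COMPOSITION)
        allowed = spec.gap_margin * rni - bm.daily_amount(nutrient)
        if allowed <= 0:
            raise ValueError(
                f"breast milk alone exceeds the planted-gap ceiling for {nutrient}"
            )
        caps.append(allowed * energy_density / spec.complementary_budget(band))
    return min(caps)


def generate_food_system(spec: SyntheticSpec) -> CompositionTable:
    """Deterministic composition table with planted gaps and fixes honoured."""
    spec.validate()
    rng = _rng(spec, 0)
    foods: dict[str, FoodItem] = {}
    jitter_sd = spec.density_jitter
    for food_id, group, subgroup, _portion, _probs, base in _CATALOG:
        comp = {}
        for n in _NUTRIENTS:
            v = float(base.get(n, 0.0))
            if n not in ("energy",) and v > 0:
                v *= float(np.exp(rng.normal(0.0, jitter_sd)))
            comp[n] = v
        foods[food_id] = FoodItem(food_id, food_id.replace("_", " "),
                                  group, subgroup, comp)

    # Planted gaps: cap densities so the nutrient is unreachable anywhere.
    for n in spec.planted_gaps:
        for item in foods.values():
            cap = _gap_caps(spec, n, item.composition["energy"])
            item.composition[n] = min(item.composition[n], cap)

    # Planted fixes: raise the subgroup's density until it dominates the rest
    # of the food system for that nutrient.
    for sg, n in spec.planted_fixes:
        members = [f for f in foods.values() if f.subgroup_id == sg]
        others = [f.composition[n] for f in foods.values() if f.subgroup_id != sg]
        floor = spec.fix_dominance * (np.mean(others) if others else 1.0)
        for item in members:
            item.composition[n] = max(item.composition[n], float(floor))

    return CompositionTable(foods=foods, nutrient_ids=list(_NUTRIENTS))


def _calibrated_portions(
    spec: SyntheticSpec, food_system: CompositionTable,
    livelihood: str, band: str,
) -> dict[str, float]:
    """Median portion per food, scaled so the expected complementary energy
    of a child matches the band's budget (keeps the post-hoc energy rescale
    near 1 and the portion medians recoverable)."""
    expected = 0.0
    base_portions = {}
    mean_factor = float(np.exp(spec.portion_sigma**2 / 2.0))
    for food_id, _g, _sg, portion, probs, _c in _CATALOG:
        p = probs.get(livelihood)
        if not p:
            continue
        g = portion * _BAND_PORTION_FACTOR[band]
        base_portions[food_id] = g
        e = food_system[food_id].composition["energy"]
        expected += p * g * mean_factor * e / 100.0
    scale = spec.complementary_budget(band) / expected
    return {f: g * scale for f, g in base_portions.items()}


def generate_recalls(spec: SyntheticSpec, food_system: CompositionTable) -> RecallSet:
    """One 24h recall per child: foods drawn by availability x probability,
    grams lognormal around the calibrated median, then rescaled so the
    child's complementary energy sits near the band budget."""
    spec.validate()
    rows = []
    for li, livelihood in enumerate(spec.livelihoods):
        for bi, band in enumerate(AGE_BANDS):
            rng = _rng(spec, 1, li, bi)
            gid = spec.group_id(livelihood, band)
            portions = _calibrated_portions(spec, food_system, livelihood, band)
            food_ids = sorted(portions)
            probs = {
                e[0]: spec.probability_overrides.get(e[0], e[4][livelihood])
                for e in _CATALOG
                if e[4].get(livelihood)
            }
            budget = spec.complementary_budget(band)
            for i in range(spec.n_children):
                child = f"{gid}_c{i:03d}"
                eaten = [f for f in food_ids if rng.random() < probs[f]]
                if not eaten:  # every surveyed child ate something
                    staples = [f for f in ("maize_flour", "goat_milk", "sugar")
                               if f in food_ids]
                    eaten = [staples[0] if staples else food_ids[0]]
                grams = {
                    f: portions[f] * float(np.exp(rng.normal(0.0, spec.portion_sigma)))
                    for f in eaten
                }
                energy = sum(
                    g * food_system[f].composition["energy"] / 100.0
                    for f, g in grams.items()
                )
                noise = float(np.exp(rng.normal(
                    -spec.energy_sigma**2 / 2.0, spec.energy_sigma)))
                scale = budget * noise / energy
                for f in eaten:
                    rows.append((child, gid, f, round(grams[f] * scale, 2)))
    df = pd.DataFrame(rows, columns=RecallSet.COLUMNS)
    df = df.sort_values(["target_group", "child_id", "food_id"]).reset_index(drop=True)
    return RecallSet(records=df)


def generate_study_config(spec: SyntheticSpec) -> StudyConfig:
    spec.validate()
    groups = []
    for livelihood in spec.livelihoods:
        for band in AGE_BANDS:
            groups.append(
                TargetGroup(
                    id=spec.group_id(livelihood, band),
                    age_band=band,
                    livelihood=livelihood,
                    energy_requirement=spec.energy_requirements[band],
                    rni=dict(spec.rni[band]),
                    breast_milk=BreastMilkAssumption.default_for(
                        band, BREAST_MILK_COMPOSITION),
                )
            )
    config = StudyConfig(nutrients=_default_nutrients(), target_groups=groups,
                         thresholds=Thresholds())
    config.validate()
    return config


def ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Expected classifications implied by the planted structure (test
    harness only; derived from the spec, not from any pipeline run)."""
    spec.validate()
    food_system = generate_food_system(spec)
    portions = {}
    budgets = {}
    for livelihood in spec.livelihoods:
        for band in AGE_BANDS:
            gid = spec.group_id(livelihood, band)
            portions[gid] = _calibrated_portions(spec, food_system, livelihood, band)
            budgets[gid] = spec.complementary_budget(band)
    return GroundTruth(
        gap_nutrients=list(spec.planted_gaps),
        fixes=list(spec.planted_fixes),
        winning_identity=spec.planted_unique_cfr,
        intended_portions=portions,
        complementary_budgets=budgets,
    )


@dataclass
class SyntheticStudy:
    spec: SyntheticSpec
    composition: CompositionTable
    recalls: RecallSet
    config: StudyConfig
    truth: GroundTruth


def make_study(spec: Optional[SyntheticSpec] = None) -> SyntheticStudy:
    spec = spec or SyntheticSpec()
    composition = generate_food_system(spec)
    recalls = generate_recalls(spec, composition)
    config = generate_study_config(spec)
    truth = ground_truth(spec)
    return SyntheticStudy(spec, composition, recalls, config, truth)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Emit composition.csv / recalls.csv / study.yaml / truth.json in the
    exact formats the pipeline consumes."""
    from . import io as cfrlp_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfrlp_io.write_composition_table(study.composition, out / "composition.csv")
    cfrlp_io.write_recalls(study.recalls, out / "recalls.csv")
    cfrlp_io.write_study_config(study.config, out / "study.yaml")
    truth = study.truth
    (out / "truth.json").write_text(json.dumps({
        "gap_nutrients": truth.gap_nutrients,
        "fixes": [list(f) for f in truth.fixes],
        "winning_identity": list(truth.winning_identity) if truth.winning_identity else None,
        "complementary_budgets": truth.complementary_budgets,
        "intended_portions": truth.intended_portions,
    }, indent=2, sort_keys=True))
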