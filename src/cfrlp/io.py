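"""Readers and writers for the CSV/YAML artifacts the pipeline touches.

Formats
-------
composition.csv : ``food_id,name,group,subgroup,<nutrient>...`` (per 100 g)
recalls.csv     : ``child_id,target_group,food_id,grams`` (one 24h recall/child)
study.yaml      : target groups, RNI table, breast-milk block, thresholds,
                  exclusions.

Nutrient identifiers are canonical lower-snake tokens; config files may map
aliases onto them (composition CSVs vary in column naming).  Missing nutrient
values are read as zeros with a logged count — the LP must be conservative
about nutrient credit, so no imputation is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    AGE_BANDS,
    DEFAULT_BM_ENERGY_DENSITY_KCAL_G,
    DEFAULT_BM_ENERGY_FRACTION,
    DEFAULT_BM_GRAMS_PER_DAY,
    TARGET_MICRONUTRIENTS,
    BreastMilkAssumption,
    CompositionTable,
    ExclusionReason,
    FoodItem,
    Nutrient,
    RecallSet,
    StudyConfig,
    TargetGroup,
    Thresholds,
)

logger = logging.getLogger(__name__)

_META_COLUMNS = ("food_id", "name", "group", "subgroup")


def canonical_token(label: str) -> str:
    return label.strip().lower().replace(" ", "_").replace("-", "_")


def load_composition_table(
    path,
    nutrient_ids: Optional[Sequence[str]] = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> CompositionTable:
    """Read a food-composition CSV (densities per 100 g edible portion).

    Columns outside the declared nutrient list are ignored with a warning;
    missing (NaN) densities become 0 with a logged count.  Duplicate food ids
    and negative densities are hard errors.
    """
    df = pd.read_csv(path)
    df.columns = [canonical_token(c) for c in df.columns]
    if aliases:
        df = df.rename(columns={canonical_token(k): v for k, v in aliases.items()})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"composition table missing column {col!r}")

    dupes = df["food_id"][df["food_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate food id(s) in composition table: {dupes}")

    present = [c for c in df.columns if c not in _META_COLUMNS]
    if nutrient_ids is None:
        nutrient_ids = present
    else:
        unknown = [c for c in present if c not in nutrient_ids]
        if unknown:
            logger.warning("ignoring unknown nutrient column(s): %s", unknown)
        nutrient_ids = [n for n in nutrient_ids if n in present]

    n_missing = int(df[nutrient_ids].isna().sum().sum())
    if n_missing:
        logger.warning("treating %d missing nutrient values as 0", n_missing)
        df[nutrient_ids] = df[nutrient_ids].fillna(0.0)

    for n in nutrient_ids:
        bad = df.loc[df[n] < 0, "food_id"].tolist()
        if bad:
            raise ValueError(f"negative {n} density for food(s): {bad}")

    foods: dict[str, FoodItem] = {}
    for _, row in df.iterrows():
        foods[row["food_id"]] = FoodItem(
            id=row["food_id"],
            name=row["name"],
            group_id=row["group"],
            subgroup_id=row["subgroup"],
            composition={n: float(row[n]) for n in nutrient_ids},
        )
    return CompositionTable(foods=foods, nutrient_ids=list(nutrient_ids))


def write_composition_table(table: CompositionTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_recalls(
    path,
    composition: Optional[CompositionTable] = None,
    exclusions: Optional[Mapping[str, str]] = None,
) -> RecallSet:
    """Read 24h-recall records, dropping excluded foods and summing duplicate
    (child, food) rows.

    ``exclusions`` maps food id -> reason (condiment, tea-like items of no
    nutritional value, therapeutic foods, foods deemed uncommon).  Dropped
    rows are kept in ``RecallSet.excluded_log`` so the exclusion is auditable:
    total loaded grams equal input grams minus excluded grams exactly.
    """
    df = pd.read_csv(path)
    df.columns = [canonical_token(c) for c in df.columns]
    missing_cols = [c for c in RecallSet.COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"recall table missing column(s): {missing_cols}")
    df = df[RecallSet.COLUMNS].copy()
    if (df["grams"] <= 0).any():
        bad = df.loc[df["grams"] <= 0]
        raise ValueError(f"non-positive grams in recall rows: {bad.index.tolist()}")

    exclusions = dict(exclusions or {})
    mask = df["food_id"].isin(exclusions)
    excluded = df[mask].copy()
    if not excluded.empty:
        excluded["reason"] = excluded["food_id"].map(exclusions)
        logger.info(
            "excluded %d recall rows (%.0f g) for %d foods",
            len(excluded), excluded["grams"].sum(), excluded["food_id"].nunique(),
        )
    df = df[~mask]

    if composition is not None:
        unknown = sorted(set(df["food_id"]) - set(composition.foods))
        if unknown:
            raise ValueError(
                f"recall foods absent from composition table: {unknown}"
            )

    df = (
        df.groupby(["child_id", "target_group", "food_id"], as_index=False)["grams"]
        .sum()
        .sort_values(["target_group", "child_id", "food_id"])
        .reset_index(drop=True)
    )
    return RecallSet(records=df, excluded_log=excluded.reset_index(drop=True))


def write_recalls(recalls: RecallSet, path) -> None:
    recalls.records.to_csv(path, index=False)


def _parse_nutrients(raw: list[dict]) -> list[Nutrient]:
    out = []
    for item in raw:
        out.append(
            Nutrient(
                id=canonical_token(item["id"]),
                name=item.get("name", item["id"]),
                unit=item.get("unit", ""),
                is_target_micronutrient=bool(item.get("is_target_micronutrient", False)),
            )
        )
    return out


def _default_nutrients() -> list[Nutrient]:
    units = {
        "energy": "kcal", "protein": "g", "fat": "g",
        "calcium": "mg", "iron": "mg", "zinc": "mg", "riboflavin": "mg",
        "niacin": "mg", "thiamin": "mg", "folate": "µg", "vitamin_a": "µg RE",
        "vitamin_b6": "mg", "vitamin_b12": "µg", "vitamin_c": "mg",
    }
    return [
        Nutrient(n, n.replace("_", " "), units[n], n in TARGET_MICRONUTRIENTS)
        for n in units
    ]


def load_study_config(path) -> StudyConfig:
    """Read and validate a study config (YAML or JSON — YAML parses both).

    Defaults applied when omitted: adequacy cutoff 65 % RNI, problem-nutrient
    cutoff 100 % RNI, best-source rule >=5 % of >=5 micronutrients, weekly
    bounds at the 10th/90th percentiles, breast-milk assumption per age band
    (67/55/39 % of energy; 570/520/420 g/d at 0.66 kcal/g).
    """
    raw = yaml.safe_load(Path(path).read_text())
    nutrients = (
        _parse_nutrients(raw["nutrients"]) if "nutrients" in raw else _default_nutrients()
    )

    th_raw = raw.get("thresholds", {})
    thresholds = Thresholds(
        adequacy_cutoff=float(th_raw.get("adequacy_cutoff", 65.0)),
        rni_cutoff=float(th_raw.get("rni_cutoff", 100.0)),
        source_share=float(th_raw.get("source_share", 5.0)),
        source_min_nutrients=int(th_raw.get("source_min_nutrients", 5)),
        p_lo=float(th_raw.get("p_lo", 10.0)),
        p_hi=float(th_raw.get("p_hi", 90.0)),
        keep_k=int(th_raw.get("keep_k", 8)),
        max_set_size=int(th_raw.get("max_set_size", 5)),
        energy_slack=float(th_raw.get("energy_slack", 0.0)),
        bounds_over_consumers_only=bool(th_raw.get("bounds_over_consumers_only", False)),
    )
    logger.info("study thresholds: %s", thresholds)

    bm_composition = {
        canonical_token(k): float(v)
        for k, v in raw.get("breast_milk_composition", {}).items()
    }

    target_micros = [n.id for n in nutrients if n.is_target_micronutrient]
    groups: list[TargetGroup] = []
    for g in raw["target_groups"]:
        band = g["age_band"]
        if band not in AGE_BANDS:
            raise ValueError(f"unknown age band {band!r}")
        bm_raw = g.get("breast_milk", {})
        bm = BreastMilkAssumption(
            age_band=band,
            energy_fraction=float(
                bm_raw.get("energy_fraction", DEFAULT_BM_ENERGY_FRACTION[band])
            ),
            grams_per_day=float(
                bm_raw.get("grams_per_day", DEFAULT_BM_GRAMS_PER_DAY[band])
            ),
            energy_density=float(
                bm_raw.get("energy_density", DEFAULT_BM_ENERGY_DENSITY_KCAL_G)
            ),
            composition={
                canonical_token(k): float(v)
                for k, v in bm_raw.get("composition", bm_composition).items()
            },
        )
        rni = {canonical_token(k): float(v) for k, v in g["rni"].items()}
        missing = [n for n in target_micros if n not in rni]
        if missing:
            raise ValueError(
                f"target group {g['id']}: missing RNI for target micronutrient(s) {missing}"
            )
        groups.append(
            TargetGroup(
                id=g["id"],
                age_band=band,
                livelihood=g.get("livelihood", ""),
                energy_requirement=float(g["energy_requirement"]),
                rni=rni,
                breast_milk=bm,
                zinc_bioavailability_level=str(g.get("zinc_bioavailability_level", "15%")),
                iron_bioavailability_level=str(g.get("iron_bioavailability_level", "5%")),
            )
        )

    exclusions = {
        canonical_token(k): str(v) for k, v in raw.get("exclusions", {}).items()
    }
    for reason in exclusions.values():
        ExclusionReason(reason)  # raises on unknown labels

    config = StudyConfig(
        nutrients=nutrients,
        target_groups=groups,
        thresholds=thresholds,
        exclusions=exclusions,
    )
    config.validate()
    return config


def write_study_config(config: StudyConfig, path) -> None:
    raw = {
        "nutrients": [
            {
                "id": n.id,
                "name": n.name,
                "unit": n.unit,
                "is_target_micronutrient": n.is_target_micronutrient,
            }
            for n in config.nutrients
        ],
        "thresholds": {
            "adequacy_cutoff": config.thresholds.adequacy_cutoff,
            "rni_cutoff": config.thresholds.rni_cutoff,
            "source_share": config.thresholds.source_share,
            "source_min_nutrients": config.thresholds.source_min_nutrients,
            "p_lo": config.thresholds.p_lo,
            "p_hi": config.thresholds.p_hi,
            "keep_k": config.thresholds.keep_k,
            "max_set_size": config.thresholds.max_set_size,
            "energy_slack": config.thresholds.energy_slack,
            "bounds_over_consumers_only": config.thresholds.bounds_over_consumers_only,
        },
        "exclusions": dict(config.exclusions),
        "target_groups": [
            {
                "id": tg.id,
                "age_band": tg.age_band,
                "livelihood": tg.livelihood,
                "energy_requirement": tg.energy_requirement,
                "rni": dict(tg.rni),
                "zinc_bioavailability_level": tg.zinc_bioavailability_level,
                "iron_bioavailability_level": tg.iron_bioavailability_level,
                "breast_milk": {
                    "energy_fraction": tg.breast_milk.energy_fraction,
                    "grams_per_day": tg.breast_milk.grams_per_day,
                    "energy_density": tg.breast_milk.energy_density,
                    "composition": dict(tg.breast_milk.composition),
                },
            }
            for tg in config.target_groups
        ],
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
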