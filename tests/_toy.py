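"""Hand-built toy ModelParameters for unit and oracle tests."""

from __future__ import annotations

from cfrlp.model import (
    BreastMilkAssumption,
    CompositionTable,
    FoodItem,
    ModelParameters,
    ParamFood,
    TargetGroup,
)

MICROS = ("calcium", "iron", "zinc", "riboflavin", "niacin", "thiamin",
          "folate", "vitamin_a", "vitamin_b6", "vitamin_b12", "vitamin_c")


def toy_params(
    foods,
    energy_requirement=100.0,
    rni=None,
    bm_grams=0.0,
    bm_composition=None,
    group_bounds=None,
    subgroup_bounds=None,
    medians=None,
    age_band="m6_8",
):
    """Build ModelParameters from dicts:
    ``{id, group, subgroup, portion, bounds (weekly grams), comp, median?}``.

    Unlisted nutrients default to 0; every target micronutrient has RNI 10
    unless overridden; breast milk defaults to absent (0 g/d).
    """
    rni = {**{n: 10.0 for n in MICROS}, **(rni or {})}
    nutrient_ids = ["energy", "protein", *MICROS]
    items = {}
    pfoods = []
    for f in foods:
        comp = {n: 0.0 for n in nutrient_ids}
        comp.update(f["comp"])
        items[f["id"]] = FoodItem(f["id"], f["id"], f["group"], f["subgroup"], comp)
        pfoods.append(
            ParamFood(
                food_id=f["id"],
                portion_g=f["portion"],
                gram_bounds=tuple(f["bounds"]),
                observed_median_servings_per_week=f.get("median", 0.0),
            )
        )
    table = CompositionTable(foods=items, nutrient_ids=nutrient_ids)
    bm = BreastMilkAssumption(
        age_band=age_band, energy_fraction=0.0, grams_per_day=bm_grams,
        energy_density=0.66, composition=dict(bm_composition or {}),
    )
    tg = TargetGroup(
        id="toy", age_band=age_band, livelihood="settled",
        energy_requirement=energy_requirement, rni=rni, breast_milk=bm,
    )
    if group_bounds is None:
        group_bounds = {}
        for f in foods:
            group_bounds.setdefault(f["group"], (0.0, 1e6))
    if subgroup_bounds is None:
        subgroup_bounds = {}
        for f in foods:
            subgroup_bounds.setdefault(f["subgroup"], (0.0, 1e6))
    params = ModelParameters(
        target_group=tg,
        foods=pfoods,
        group_bounds=group_bounds,
        subgroup_bounds=subgroup_bounds,
        observed_median_group_servings=dict(medians or {}),
        observed_median_subgroup_servings={},
        composition=table,
    )
    params.validate()
    return params
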