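"""LP engine: structure, evaluation, optima vs brute-force grid oracle."""

import numpy as np
import pytest

from cfrlp.lp import (
    build_diet_lp,
    nutrient_profile,
    solve_best_diet,
    solve_nutrient_extreme,
    to_lp_text,
)
from cfrlp.model import CFR

from _grid import (
    extreme_tolerance,
    grid_best_objective,
    grid_extreme,
    objective_tolerance,
    random_instance,
)
from _toy import MICROS, toy_params


def two_food_params(**kw):
    foods = [
        {"id": "a", "group": "ga", "subgroup": "sa", "portion": 100.0,
         "bounds": (0.0, 1000.0), "comp": {"energy": 100.0, "iron": 5.0}},
        {"id": "b", "group": "gb", "subgroup": "sb", "portion": 50.0,
         "bounds": (0.0, 1000.0), "comp": {"energy": 200.0, "zinc": 8.0}},
    ]
    return toy_params(foods, **kw)


def test_single_food_energy_forces_unique_solution():
    foods = [{"id": "a", "group": "g", "subgroup": "s", "portion": 100.0,
              "bounds": (0.0, 2000.0), "comp": {"energy": 100.0, "iron": 2.0}}]
    # weekly target 700 kcal; one serving = 100 kcal -> s = 7 forced
    params = toy_params(foods, energy_requirement=100.0)
    sol = solve_nutrient_extreme(build_diet_lp(params), "iron", "min")
    assert sol.optimal
    assert sol.servings["a"] == pytest.approx(7.0, abs=1e-7)


def test_cfr_constraint_adds_row_and_validates():
    params = two_food_params()
    lp = build_diet_lp(params, [CFR("subgroup", "sa", 3.0, 100.0)])
    assert len(lp.cfr_rows) == 1
    with pytest.raises(ValueError, match="absent"):
        build_diet_lp(params, [CFR("subgroup", "dairy", 1.0, 100.0)])
    tight = toy_params(
        [{"id": "a", "group": "ga", "subgroup": "sa", "portion": 100.0,
          "bounds": (0.0, 1000.0), "comp": {"energy": 100.0}}],
        subgroup_bounds={"sa": (0.0, 2.0)},
    )
    with pytest.raises(ValueError, match="exceeds"):
        build_diet_lp(tight, [CFR("subgroup", "sa", 5.0, 100.0)])


def test_nutrient_profile_breast_milk_only_and_linearity():
    params = two_food_params(bm_grams=500.0, bm_composition={"iron": 0.4},
                             energy_requirement=400.0)
    prof0 = nutrient_profile({}, params)
    assert prof0["iron"][0] == pytest.approx(500 * 0.4 / 100)
    p1 = nutrient_profile({"a": 2.0, "b": 1.0}, params)
    p2 = nutrient_profile({"a": 4.0, "b": 2.0}, params)
    bm = prof0["iron"][0]
    assert p2["iron"][0] - bm == pytest.approx(2 * (p1["iron"][0] - bm), rel=1e-12)
    with pytest.raises(ValueError, match="unknown food"):
        nutrient_profile({"nope": 1.0}, params)


def test_nutrient_profile_hand_computed():
    params = two_food_params(rni={"iron": 10.0, "zinc": 16.0})
    prof = nutrient_profile({"a": 7.0, "b": 3.5}, params)
    # iron: 7 serv x 100 g x 5/100 g = 35 mg/week -> 5/day; 50% RNI
    assert prof["iron"][0] == pytest.approx(5.0, abs=1e-9)
    assert prof["iron"][1] == pytest.approx(50.0, abs=1e-9)
    # zinc: 3.5 x 50 x 8/100 = 14 /week -> 2/day; 12.5% of 16
    assert prof["zinc"][0] == pytest.approx(2.0, abs=1e-9)
    assert prof["zinc"][1] == pytest.approx(12.5, abs=1e-9)


def test_best_diet_zero_density_nutrient_contributes_zero():
    params = two_food_params(rni={"iron": 1.0, "zinc": 1.0})
    sol = solve_best_diet(build_diet_lp(params))
    assert sol.optimal
    # folate has zero density everywhere and no breast milk -> 0 %RNI
    assert sol.pct_rni["folate"] == 0.0
    # iron and zinc saturate their (tiny) RNIs -> objective == 2
    assert sol.objective_value == pytest.approx(2.0, abs=1e-6)


def test_best_diet_saturation_single_rich_food():
    comp = {"energy": 100.0, **{n: 50.0 for n in MICROS}}
    foods = [{"id": "rich", "group": "g", "subgroup": "s", "portion": 100.0,
              "bounds": (0.0, 5000.0), "comp": comp}]
    params = toy_params(foods, energy_requirement=200.0, rni={n: 10.0 for n in MICROS})
    sol = solve_best_diet(build_diet_lp(params))
    assert sol.objective_value == pytest.approx(len(MICROS), abs=1e-6)
    assert all(sol.pct_rni[n] >= 100.0 - 1e-6 for n in MICROS)


def test_infeasible_instance_reports_diagnosis():
    foods = [{"id": "a", "group": "g", "subgroup": "s", "portion": 100.0,
              "bounds": (0.0, 100.0), "comp": {"energy": 100.0}}]
    # max 1 serving/week = 100 kcal < 700 kcal target
    params = toy_params(foods, energy_requirement=100.0)
    sol = solve_best_diet(build_diet_lp(params))
    assert sol.status == "infeasible"
    assert sol.diagnosis


def test_minimized_optional_food_is_unused():
    params = two_food_params()
    lp = build_diet_lp(params)
    sol = solve_nutrient_extreme(lp, "iron", "min")
    assert sol.optimal
    assert sol.servings["a"] == pytest.approx(0.0, abs=1e-8)
    assert sol.pct_rni["iron"] <= solve_nutrient_extreme(lp, "iron", "max").pct_rni["iron"]


def test_extreme_direction_validation():
    lp = build_diet_lp(two_food_params())
    with pytest.raises(ValueError, match="direction"):
        solve_nutrient_extreme(lp, "iron", "up")
    with pytest.raises(ValueError, match="unknown nutrient"):
        solve_nutrient_extreme(lp, "unobtainium", "min")


def test_solver_determinism_repeated_solves():
    params, nutrients = random_instance(np.random.default_rng(42), n_foods=3)
    lp = build_diet_lp(params)
    sols = [solve_best_diet(lp).servings for _ in range(3)]
    assert sols[0] == sols[1] == sols[2]


@pytest.mark.parametrize("seed", range(6))
def test_lp_matches_grid_oracle(seed):
    """Best/min/max LP optima agree with dense 0.01-serving enumeration."""
    rng = np.random.default_rng(1000 + seed)
    params, nutrients = random_instance(rng)
    lp = build_diet_lp(params)
    best = solve_best_diet(lp)
    assert best.optimal
    assert best.objective_value == pytest.approx(
        grid_best_objective(params, nutrients),
        abs=objective_tolerance(params, nutrients),
    )
    for n in nutrients:
        for direction in ("min", "max"):
            sol = solve_nutrient_extreme(lp, n, direction)
            assert sol.nutrient_totals[n] == pytest.approx(
                grid_extreme(params, n, direction),
                abs=extreme_tolerance(params, n),
            )


def test_energy_conservation_and_lp_text_export():
    params, _ = random_instance(np.random.default_rng(7), n_foods=3)
    lp = build_diet_lp(params)
    sol = solve_best_diet(lp)
    energy = sol.nutrient_totals["energy"]
    assert energy * 7 == pytest.approx(lp.params.weekly_energy_target, rel=1e-7)
    text = to_lp_text(lp)
    assert "energy:" in text and text.startswith("\\ diet LP")
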