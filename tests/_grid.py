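"""Brute-force grid-enumeration oracle for small diet LPs.

Independent of the LP path: feasible diets are enumerated on a 0.01-serving
grid (the last food's servings solved exactly from the energy equality), and
the capped-adequacy objective / per-nutrient intakes evaluated directly.
"""

from __future__ import annotations

import numpy as np

from _toy import MICROS, toy_params

GRID_STEP = 0.01


def random_instance(rng: np.random.Generator, n_foods=None):
    """Random feasible toy instance with box bounds only (<=4 foods)."""
    n = int(n_foods or rng.integers(2, 4))
    nutrients = ["iron", "zinc", "folate"]
    foods = []
    for i in range(n):
        comp = {"energy": float(rng.uniform(80, 400))}
        for nu in nutrients:
            comp[nu] = float(rng.uniform(0.0, 40.0))
        hi = float(rng.uniform(2.0, 8.0 if n == 2 else 5.0))
        foods.append({
            "id": f"f{i}", "group": f"g{i}", "subgroup": f"sg{i}",
            "portion": 100.0, "bounds": (0.0, hi * 100.0), "comp": comp,
        })
    rni = {nu: float(rng.uniform(5.0, 60.0)) for nu in nutrients}
    # energy target from an interior feasible point => LP always feasible
    s_star = np.array([rng.uniform(0.25, 0.75) * f["bounds"][1] / 100.0
                       for f in foods])
    e = np.array([f["comp"]["energy"] for f in foods])  # kcal/serving
    weekly_energy = float(s_star @ e)
    params = toy_params(foods, energy_requirement=weekly_energy / 7.0, rni=rni)
    return params, nutrients


def _feasible_grid(params):
    """All feasible serving vectors: grid the first n-1 foods, solve the last
    from the energy equality, keep points inside the box bounds."""
    e = np.array([pf.portion_g * params.composition[pf.food_id].density("energy") / 100.0
                  for pf in params.foods])
    target = params.weekly_energy_target
    bounds = [pf.serving_bounds for pf in params.foods]
    axes = [np.arange(lo, hi + GRID_STEP / 2, GRID_STEP) for lo, hi in bounds[:-1]]
    if axes:
        mesh = np.meshgrid(*axes, indexing="ij")
        head = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        head = np.zeros((1, 0))
    last = (target - head @ e[:-1]) / e[-1]
    lo, hi = bounds[-1]
    ok = (last >= lo - 1e-9) & (last <= hi + 1e-9)
    return np.column_stack([head[ok], last[ok]])


def _intakes(params, grid):
    """Daily intake per nutrient for every grid point (breast milk included)."""
    out = {}
    for n in MICROS:
        q = np.array([
            pf.portion_g * params.composition[pf.food_id].density(n) / 100.0
            for pf in params.foods
        ])
        out[n] = grid @ q / 7.0 + params.target_group.breast_milk.daily_amount(n)
    return out


def grid_best_objective(params, nutrients):
    """Max over the grid of sum_n min(1, intake_n/RNI_n)."""
    grid = _feasible_grid(params)
    assert grid.size, "empty feasible grid"
    intakes = _intakes(params, grid)
    rni = params.target_group.rni
    obj = sum(np.minimum(1.0, intakes[n] / rni[n]) for n in nutrients)
    # remaining micronutrients have zero density everywhere -> contribute 0
    return float(obj.max())


def grid_extreme(params, nutrient, direction):
    grid = _feasible_grid(params)
    assert grid.size
    vals = _intakes(params, grid)[nutrient]
    return float(vals.min() if direction == "min" else vals.max())


def _substitution_factor(params):
    """Moving a gridded food by one step moves the energy-solved food by
    e_f/e_last servings, so value sensitivity scales with the energy ratio."""
    e = [pf.portion_g * params.composition[pf.food_id].density("energy") / 100.0
         for pf in params.foods]
    return 1.0 + max(e) / min(e)


def objective_tolerance(params, nutrients):
    """Grid-resolution error bound on the best-diet objective."""
    tol = 0.0
    for n in nutrients:
        q = max(
            pf.portion_g * params.composition[pf.food_id].density(n) / 100.0
            for pf in params.foods
        )
        tol += q / (7.0 * params.target_group.rni[n])
    return tol * GRID_STEP * len(params.foods) * _substitution_factor(params) + 1e-7


def extreme_tolerance(params, nutrient):
    q = max(
        pf.portion_g * params.composition[pf.food_id].density(nutrient) / 100.0
        for pf in params.foods
    )
    return q / 7.0 * GRID_STEP * len(params.foods) * _substitution_factor(params) + 1e-9
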