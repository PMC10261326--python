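"""Formulate and solve the 7-day diet linear programs.

Decision variables are continuous servings/week per food.  Breast milk is a
fixed constant, never a variable.  All diets satisfy

* an energy equality: complementary energy + breast-milk energy = 7 x the
  daily energy requirement (exact by default; a relative slack is available
  for coarse synthetic data and is reported, never silently applied);
* weekly gram bounds per food item (entering as variable bounds);
* weekly serving bounds per food group and subgroup;
* optional CFR lower bounds (a promoted group/subgroup must reach its
  recommended servings/week).

Two solve modes:

* the *nutritionally best diet*: maximize the summed capped adequacy
  sum_n min(1, intake_n / RNI_n) over the target micronutrients, linearized
  with auxiliary variables z_n in [0, 1], z_n <= intake_n / RNI_n.  A second
  lexicographic pass minimizes total absolute deviation of group servings
  from their observed medians so the reported diet is deterministic and
  resembles observed food patterns.
* per-nutrient *minimized/maximized diets* ("worst-case scenario" analyses):
  minimize or maximize one nutrient's intake subject to the same constraints.

The solver sits behind a single pluggable interface; the default backend is
HiGHS via ``scipy.optimize.linprog``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import CFR, DietSolution, ModelParameters

logger = logging.getLogger(__name__)

#: solver signature: (c, A_ub, b_ub, A_eq, b_eq, bounds) -> (ok, x, message)
SolverFn = Callable[..., tuple[bool, Optional[np.ndarray], str]]


def _scipy_highs_solver(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    return res.status == 0, res.x, res.message


DEFAULT_SOLVER: SolverFn = _scipy_highs_solver


@dataclass
class DietLP:
    """One target group's diet LP, reproducible from (params, cfr) alone."""

    params: ModelParameters
    cfr: list[CFR] = field(default_factory=list)
    energy_slack: float = 0.0

    # Derived arrays (filled by build_diet_lp)
    food_ids: list[str] = field(default_factory=list)
    portions: np.ndarray = field(default_factory=lambda: np.empty(0))
    # per-serving weekly nutrient content, nutrient id -> vector over foods
    per_serving: dict[str, np.ndarray] = field(default_factory=dict)
    var_bounds: list[tuple[float, float]] = field(default_factory=list)
    # label constraint rows: (indicator row over foods, lo, hi, label)
    label_rows: list[tuple[np.ndarray, float, float, str]] = field(default_factory=list)
    # CFR rows: (indicator row, lower bound, label)
    cfr_rows: list[tuple[np.ndarray, float, str]] = field(default_factory=list)

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    @property
    def energy_row(self) -> np.ndarray:
        return self.per_serving["energy"]

    @property
    def complementary_energy_target(self) -> float:
        return self.params.weekly_energy_target - self.params.breast_milk_weekly("energy")


def build_diet_lp(
    params: ModelParameters,
    cfr_constraints: Sequence[CFR] = (),
    energy_slack: Optional[float] = None,
) -> DietLP:
    """Pure function from ModelParameters (+ CFR list) to a solvable LP.

    Raises before solving when a CFR references a group/subgroup absent from
    the parameters, or when its lower bound exceeds that label's upper
    serving bound (such a set could never be honoured).
    """
    lp = DietLP(params=params, cfr=list(cfr_constraints))
    lp.energy_slack = 0.0 if energy_slack is None else float(energy_slack)
    lp.food_ids = params.food_ids()
    lp.portions = np.array([pf.portion_g for pf in params.foods])

    comp = params.composition
    for n in comp.nutrient_ids:
        dens = np.array([comp[f].density(n) for f in lp.food_ids])
        lp.per_serving[n] = lp.portions * dens / 100.0

    lp.var_bounds = [pf.serving_bounds for pf in params.foods]

    for level, bounds in (("group", params.group_bounds), ("subgroup", params.subgroup_bounds)):
        for label in sorted(bounds):
            lo, hi = bounds[label]
            members = params.members(level, label)
            row = np.zeros(lp.n_foods)
            row[members] = 1.0
            lp.label_rows.append((row, lo, hi, f"{level}:{label}"))

    for c in lp.cfr:
        bounds = params.group_bounds if c.level == "group" else params.subgroup_bounds
        if c.target_id not in bounds:
            raise ValueError(
                f"CFR targets {c.level} {c.target_id!r} absent from this "
                f"target group's food system"
            )
        if c.servings_per_week > bounds[c.target_id][1] + 1e-9:
            raise ValueError(
                f"CFR lower bound {c.servings_per_week} exceeds the "
                f"{c.level} {c.target_id!r} upper bound {bounds[c.target_id][1]}"
            )
        members = params.members(c.level, c.target_id)
        row = np.zeros(lp.n_foods)
        row[members] = 1.0
        lp.cfr_rows.append((row, c.servings_per_week, f"cfr:{c.level}:{c.target_id}"))

    return lp


def _base_constraints(lp: DietLP, n_extra: int = 0):
    """(A_ub, b_ub, A_eq, b_eq) over [s, extra] for the shared constraint set."""
    n = lp.n_foods + n_extra
    A_ub, b_ub = [], []
    A_eq, b_eq = [], []

    def pad(row: np.ndarray) -> np.ndarray:
        return np.concatenate([row, np.zeros(n_extra)]) if n_extra else row

    target = lp.complementary_energy_target
    if lp.energy_slack > 0:
        A_ub.append(pad(lp.energy_row)); b_ub.append(target * (1 + lp.energy_slack))
        A_ub.append(pad(-lp.energy_row)); b_ub.append(-target * (1 - lp.energy_slack))
    else:
        A_eq.append(pad(lp.energy_row)); b_eq.append(target)

    for row, lo, hi, _label in lp.label_rows:
        A_ub.append(pad(row)); b_ub.append(hi)
        if lo > 0:
            A_ub.append(pad(-row)); b_ub.append(-lo)

    for row, lower, _label in lp.cfr_rows:
        A_ub.append(pad(-row)); b_ub.append(-lower)

    return (
        np.array(A_ub) if A_ub else None,
        np.array(b_ub) if b_ub else None,
        np.array(A_eq) if A_eq else None,
        np.array(b_eq) if b_eq else None,
    )


def nutrient_profile(
    servings: dict[str, float], params: ModelParameters
) -> dict[str, tuple[float, Optional[float]]]:
    """Evaluate any diet: nutrient id -> (amount/day incl. breast milk, %RNI).

    %RNI is None for nutrients without an RNI (energy, protein, fat).  Pure
    evaluation — servings need not satisfy the LP bounds.
    """
    comp = params.composition
    portion = {pf.food_id: pf.portion_g for pf in params.foods}
    unknown = [f for f in servings if f not in portion]
    if unknown:
        raise ValueError(f"unknown food id(s) in servings: {unknown}")
    out: dict[str, tuple[float, Optional[float]]] = {}
    for n in comp.nutrient_ids:
        weekly = sum(
            s * portion[f] * comp[f].density(n) / 100.0 for f, s in servings.items()
        )
        daily = weekly / 7.0 + params.target_group.breast_milk.daily_amount(n)
        rni = params.target_group.rni.get(n)
        pct = 100.0 * daily / rni if rni else None
        out[n] = (daily, pct)
    return out


def _solution_from_servings(
    lp: DietLP, s: np.ndarray, objective: float = float("nan")
) -> DietSolution:
    servings = {f: float(v) for f, v in zip(lp.food_ids, s)}
    profile = nutrient_profile(servings, lp.params)
    return DietSolution(
        status="optimal",
        servings=servings,
        nutrient_totals={n: amt for n, (amt, _) in profile.items()},
        pct_rni={n: pct for n, (_, pct) in profile.items() if pct is not None},
        objective_value=objective,
    )


def _diagnose(lp: DietLP, message: str) -> str:
    """Name the obviously violated row when infeasibility has a simple cause."""
    target = lp.complementary_energy_target
    lo = np.array([b[0] for b in lp.var_bounds])
    hi = np.array([b[1] for b in lp.var_bounds])
    for row, lower, label in lp.cfr_rows:
        if row @ hi < lower - 1e-9:
            return f"{label}: item upper bounds cannot reach {lower} servings/week"
    min_energy = lp.energy_row @ lo
    for row, lower, label in lp.cfr_rows:
        extra = np.where(row > 0, lp.energy_row, 0.0)
        # cheapest way to honour the CFR: fill with the least caloric member
        member_e = lp.energy_row[row > 0] if (row > 0).any() else np.array([0.0])
        min_energy_cfr = min_energy + max(
            0.0, (lower - row @ lo)
        ) * member_e.min()
        if min_energy_cfr > target * (1 + lp.energy_slack) + 1e-6:
            return (
                f"{label}: honouring the recommendation exceeds the "
                f"complementary energy budget ({target:.0f} kcal/week)"
            )
    if min_energy > target * (1 + lp.energy_slack) + 1e-6:
        return "item lower bounds alone exceed the complementary energy budget"
    return message or "infeasible"


def _solve(lp: DietLP, c, A_ub, b_ub, A_eq, b_eq, bounds, solver: SolverFn):
    t0 = time.perf_counter()
    ok, x, msg = solver(c, A_ub, b_ub, A_eq, b_eq, bounds)
    logger.debug(
        "LP solve group=%s vars=%d ok=%s ms=%.1f",
        lp.params.target_group.id, len(c), ok, 1e3 * (time.perf_counter() - t0),
    )
    return ok, x, msg


def solve_best_diet(lp: DietLP, solver: SolverFn = DEFAULT_SOLVER) -> DietSolution:
    """Solve the nutritionally best diet (maximize summed capped adequacy).

    Two passes: (1) maximize sum_n z_n; (2) holding the optimum, minimize
    total absolute deviation of group servings from their observed medians,
    making the reported servings deterministic.
    """
    params = lp.params
    micros = [n for n in _target_micros(params) if n in lp.per_serving]
    nz = len(micros)
    nf = lp.n_foods

    A_ub, b_ub, A_eq, b_eq = _base_constraints(lp, n_extra=nz)
    rows, rhs = [], []
    for k, n in enumerate(micros):
        rni_week = 7.0 * params.target_group.rni[n]
        row = np.zeros(nf + nz)
        row[:nf] = -lp.per_serving[n] / rni_week
        row[nf + k] = 1.0
        rows.append(row)
        rhs.append(params.breast_milk_weekly(n) / rni_week)
    A_ub = np.vstack([A_ub, rows]) if A_ub is not None else np.array(rows)
    b_ub = np.concatenate([b_ub, rhs]) if b_ub is not None else np.array(rhs)

    c = np.concatenate([np.zeros(nf), -np.ones(nz)])
    bounds = lp.var_bounds + [(0.0, 1.0)] * nz
    ok, x, msg = _solve(lp, c, A_ub, b_ub, A_eq, b_eq, bounds, solver)
    if not ok:
        return DietSolution.infeasible(_diagnose(lp, msg))
    opt = -c @ x

    # Lexicographic tie-break pass: keep sum z at the optimum, minimize total
    # absolute deviation of group servings from observed medians.
    group_labels = sorted(params.group_bounds)
    nd = len(group_labels)
    n_extra = nz + nd
    A_ub2, b_ub2, A_eq2, b_eq2 = _base_constraints(lp, n_extra=n_extra)
    rows2, rhs2 = [], []
    for k, n in enumerate(micros):
        rni_week = 7.0 * params.target_group.rni[n]
        row = np.zeros(nf + n_extra)
        row[:nf] = -lp.per_serving[n] / rni_week
        row[nf + k] = 1.0
        rows2.append(row); rhs2.append(params.breast_milk_weekly(n) / rni_week)
    # sum z >= opt - eps
    row = np.zeros(nf + n_extra)
    row[nf:nf + nz] = -1.0
    rows2.append(row); rhs2.append(-(opt - 1e-7 * max(1.0, abs(opt))))
    for j, g in enumerate(group_labels):
        members = params.members("group", g)
        med = params.observed_median_group_servings.get(g, 0.0)
        ind = np.zeros(nf + n_extra)
        ind[members] = 1.0
        ind[nf + nz + j] = -1.0
        rows2.append(ind.copy()); rhs2.append(med)       # sum s - d <= med
        ind[:nf] *= -1.0
        rows2.append(ind); rhs2.append(-med)             # -sum s - d <= -med
    A_ub2 = np.vstack([A_ub2, rows2]) if A_ub2 is not None else np.array(rows2)
    b_ub2 = np.concatenate([b_ub2, rhs2]) if b_ub2 is not None else np.array(rhs2)
    c2 = np.concatenate([np.zeros(nf + nz), np.ones(nd)])
    bounds2 = lp.var_bounds + [(0.0, 1.0)] * nz + [(0.0, None)] * nd
    ok2, x2, _ = _solve(lp, c2, A_ub2, b_ub2, A_eq2, b_eq2, bounds2, solver)
    s = x2[:nf] if ok2 else x[:nf]
    return _solution_from_servings(lp, s, objective=float(opt))


def solve_nutrient_extreme(
    lp: DietLP,
    nutrient_id: str,
    direction: str,
    solver: SolverFn = DEFAULT_SOLVER,
) -> DietSolution:
    """Minimize or maximize one nutrient's intake over the feasible diets.

    The minimized diet is the "worst-case scenario": the feasible 7-day diet
    with the lowest content of the nutrient; its %RNI >= the adequacy cutoff
    defines population-level adequacy.
    """
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    if nutrient_id not in lp.per_serving:
        raise ValueError(f"unknown nutrient {nutrient_id!r}")
    A_ub, b_ub, A_eq, b_eq = _base_constraints(lp)
    sign = 1.0 if direction == "min" else -1.0
    c = sign * lp.per_serving[nutrient_id] / 7.0
    ok, x, msg = _solve(lp, c, A_ub, b_ub, A_eq, b_eq, lp.var_bounds, solver)
    if not ok:
        return DietSolution.infeasible(_diagnose(lp, msg))
    return _solution_from_servings(lp, x, objective=float(sign * c @ x))


def _target_micros(params: ModelParameters) -> list[str]:
    from .model import TARGET_MICRONUTRIENTS

    return [n for n in TARGET_MICRONUTRIENTS if n in params.target_group.rni]


def to_lp_text(lp: DietLP) -> str:
    """Render the shared constraint set in CPLEX LP format for debugging."""
    lines = ["\\ diet LP for " + lp.params.target_group.id, "Minimize", " obj: 0",
             "Subject To"]

    def term(coef: float, i: int) -> str:
        return f"{coef:+.6g} s{i}"

    e = lp.energy_row
    expr = " ".join(term(e[i], i) for i in range(lp.n_foods) if e[i])
    lines.append(f" energy: {expr} = {lp.complementary_energy_target:.6g}")
    for row, lo, hi, label in lp.label_rows:
        expr = " ".join(term(1.0, i) for i in np.flatnonzero(row))
        lines.append(f" {label}_hi: {expr} <= {hi:.6g}")
        if lo > 0:
            lines.append(f" {label}_lo: {expr} >= {lo:.6g}")
    for row, lower, label in lp.cfr_rows:
        expr = " ".join(term(1.0, i) for i in np.flatnonzero(row))
        lines.append(f" {label.replace(':', '_')}: {expr} >= {lower:.6g}")
    lines.append("Bounds")
    for i, (lo, hi) in enumerate(lp.var_bounds):
        lines.append(f" {lo:.6g} <= s{i} <= {hi:.6g}")
    lines.append("End")
    return "\n".join(lines) + "\n"
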