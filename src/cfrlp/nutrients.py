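"""Problem-nutrient classification and best-food-source identification.

A nutrient is an *absolute* problem when it stays below the RNI cutoff
(default 100 %) both in the nutritionally best diet and in its own maximized
diet — its requirement is impossible to meet with local foods within the
observed-pattern constraints.  A *partial* problem nutrient falls short in
the best diet but reaches the cutoff in its own maximized diet: attainable,
but at the expense of other nutrients.  The boundary is strict: exactly
100.0 % is not a problem nutrient.

A *good food source* is a food subgroup (breast milk counts as its own
subgroup) contributing at least 5 % of a nutrient's content in the best diet,
for at least five of the eleven target micronutrients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DietSolution, ModelParameters
from .lp import _target_micros


@dataclass
class ProblemNutrientCall:
    nutrient_id: str
    klass: str  # "absolute" | "partial" | "none"
    best_pct_rni: float
    max_pct_rni: float


@dataclass
class BestSourceCall:
    subgroup_id: str
    n_nutrients_supported: int
    shares: dict[str, float]  # nutrient -> percent contribution in best diet
    flagged: bool
    undefined_nutrients: list[str]  # zero-total nutrients (share reported 0)


def classify_problem_nutrients(
    best_profile: dict[str, float],
    max_profiles: dict[str, float],
    target_micronutrients: list[str],
    rni_cutoff: float = 100.0,
) -> list[ProblemNutrientCall]:
    """Classify each target micronutrient from its best-diet %RNI and the
    %RNI it reaches in its own maximized diet (no CFR constraints).

    The classes are exhaustive and mutually exclusive:
    best < cutoff and max < cutoff -> absolute; best < cutoff <= max ->
    partial; best >= cutoff -> none.
    """
    calls = []
    for n in target_micronutrients:
        if n not in best_profile:
            raise ValueError(f"best-diet profile missing nutrient {n!r}")
        if n not in max_profiles:
            raise ValueError(f"maximized profiles missing nutrient {n!r}")
        best, mx = best_profile[n], max_profiles[n]
        if best < rni_cutoff:
            klass = "absolute" if mx < rni_cutoff else "partial"
        else:
            klass = "none"
        calls.append(ProblemNutrientCall(n, klass, best, mx))
    return calls


BREAST_MILK_SUBGROUP = "breast_milk"


def best_food_sources(
    best_diet: DietSolution,
    params: ModelParameters,
    share_threshold: float = 5.0,
    min_nutrients: int = 5,
) -> list[BestSourceCall]:
    """Per-subgroup percent contribution to each target micronutrient in the
    best diet, with the >=share/>=count best-source flag.

    Shares of a nutrient sum to 100 across subgroups whenever the diet's
    total for that nutrient is positive.  A zero-total nutrient has an
    undefined share, reported as 0 and listed in ``undefined_nutrients``.
    """
    if not best_diet.optimal:
        raise ValueError("best diet is not optimal")
    micros = _target_micros(params)
    comp = params.composition
    portion = {pf.food_id: pf.portion_g for pf in params.foods}
    bm = params.target_group.breast_milk

    subgroups = sorted({comp[f].subgroup_id for f in best_diet.servings})
    subgroups.append(BREAST_MILK_SUBGROUP)

    # daily amounts by (subgroup, nutrient)
    amounts = {sg: {n: 0.0 for n in micros} for sg in subgroups}
    totals = {n: 0.0 for n in micros}
    for f, s in best_diet.servings.items():
        sg = comp[f].subgroup_id
        for n in micros:
            amt = s * portion[f] * comp[f].density(n) / 100.0 / 7.0
            amounts[sg][n] += amt
            totals[n] += amt
    for n in micros:
        amt = bm.daily_amount(n)
        amounts[BREAST_MILK_SUBGROUP][n] += amt
        totals[n] += amt

    calls = []
    for sg in subgroups:
        shares, undefined = {}, []
        for n in micros:
            if totals[n] > 0:
                shares[n] = 100.0 * amounts[sg][n] / totals[n]
            else:
                shares[n] = 0.0
                undefined.append(n)
        n_supported = sum(1 for n in micros if shares[n] >= share_threshold
                          and n not in undefined)
        calls.append(
            BestSourceCall(
                subgroup_id=sg,
                n_nutrients_supported=n_supported,
                shares=shares,
                flagged=n_supported >= min_nutrients,
                undefined_nutrients=undefined,
            )
        )
    return calls


@dataclass
class GroupAnalysis:
    """Module II/III suite results for one target group."""

    target_group_id: str
    best_diet: DietSolution
    max_diets: dict[str, DietSolution]  # nutrient -> its maximized diet
    problem_nutrients: list[ProblemNutrientCall]
    best_sources: list[BestSourceCall]


def run_group_analysis(
    params: ModelParameters,
    rni_cutoff: float = 100.0,
    share_threshold: float = 5.0,
    min_nutrients: int = 5,
) -> GroupAnalysis:
    """Best diet, eleven per-nutrient maximized diets (one LP each),
    problem-nutrient classification and best-source identification."""
    from .lp import build_diet_lp, solve_best_diet, solve_nutrient_extreme

    lp = build_diet_lp(params)
    best = solve_best_diet(lp)
    if not best.optimal:
        raise RuntimeError(
            f"baseline diet LP infeasible for {params.target_group.id}: "
            f"{best.diagnosis}"
        )
    micros = _target_micros(params)
    max_diets = {n: solve_nutrient_extreme(lp, n, "max") for n in micros}
    best_profile = {n: best.pct_rni[n] for n in micros}
    max_profiles = {n: max_diets[n].pct_rni[n] for n in micros}
    calls = classify_problem_nutrients(best_profile, max_profiles, micros, rni_cutoff)
    sources = best_food_sources(best, params, share_threshold, min_nutrients)
    return GroupAnalysis(
        target_group_id=params.target_group.id,
        best_diet=best,
        max_diets=max_diets,
        problem_nutrients=calls,
        best_sources=sources,
    )
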