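"""CFR pipeline: candidate rules, screening, worst-case testing, search."""

import math

import pytest

from cfrlp.cfr import (
    CandidateCFR,
    evaluate_cfr_set,
    generate_candidates,
    recommended_servings,
    round_half_up,
    screen_candidates,
    systematic_search,
)
from cfrlp.lp import build_diet_lp, nutrient_profile, solve_best_diet, solve_nutrient_extreme
from cfrlp.model import CFR, DietSolution
from cfrlp.nutrients import GroupAnalysis, best_food_sources

from _toy import MICROS, toy_params


def _diet(servings, params):
    profile = nutrient_profile(servings, params)
    return DietSolution("optimal", dict(servings),
                        {n: a for n, (a, _) in profile.items()},
                        {n: p for n, (_, p) in profile.items() if p is not None})


def _analysis(params, servings):
    diet = _diet(servings, params)
    return GroupAnalysis(
        target_group_id=params.target_group.id,
        best_diet=diet,
        max_diets={},
        problem_nutrients=[],
        best_sources=best_food_sources(diet, params),
    )


def test_rounding_rule():
    assert round_half_up(10.4) == 10
    assert round_half_up(10.5) == 11
    assert recommended_servings(10.4, upper_bound=20.0) == 10.0
    assert recommended_servings(10.4, upper_bound=9.2) == 9.2  # clamped
    assert recommended_servings(0.2, upper_bound=20.0) == 1.0  # floor at 1


def _pattern_system():
    foods = [
        {"id": "milk", "group": "dairy", "subgroup": "animal_milk",
         "portion": 100.0, "bounds": (0.0, 2000.0),
         "comp": {"energy": 100.0, "calcium": 120.0}},
        {"id": "maize", "group": "grains", "subgroup": "refined_grains",
         "portion": 100.0, "bounds": (0.0, 2000.0),
         "comp": {"energy": 100.0, "iron": 1.0}},
    ]
    return toy_params(
        foods, energy_requirement=250.0,
        group_bounds={"dairy": (0.0, 20.0), "grains": (0.0, 20.0)},
        subgroup_bounds={"animal_milk": (0.0, 20.0), "refined_grains": (0.0, 20.0)},
        medians={"dairy": 7.0, "grains": 7.0},
    )


def test_pattern_rule_candidate_and_strict_boundary():
    params = _pattern_system()
    # dairy modelled above its median, grains exactly at it
    analysis = _analysis(params, {"milk": 10.4, "maize": 7.0})
    cands = generate_candidates(analysis, params)
    idents = {c.identity: c for c in cands}
    assert ("group", "dairy") in idents
    assert idents[("group", "dairy")].cfr.servings_per_week == 10.0
    assert idents[("group", "dairy")].provenance == "pattern_rule"
    assert ("group", "grains") not in idents  # strict >


def _source_system():
    rich = {"energy": 100.0, "calcium": 120.0, "riboflavin": 0.2,
            "vitamin_b12": 0.5, "vitamin_a": 50.0, "zinc": 0.5, "niacin": 0.3}
    foods = [
        {"id": "milk", "group": "dairy", "subgroup": "animal_milk",
         "portion": 100.0, "bounds": (0.0, 2000.0), "comp": rich},
        {"id": "maize", "group": "grains", "subgroup": "refined_grains",
         "portion": 100.0, "bounds": (0.0, 2000.0),
         "comp": {"energy": 100.0, "iron": 1.0}},
    ]
    return toy_params(
        foods, energy_requirement=250.0,
        group_bounds={"dairy": (0.0, 20.0), "grains": (0.0, 20.0)},
        subgroup_bounds={"animal_milk": (0.0, 20.0), "refined_grains": (0.0, 20.0)},
        medians={"dairy": 7.0, "grains": 7.0},
    )


def test_source_rule_candidate_wins_over_parent_group():
    params = _source_system()
    analysis = _analysis(params, {"milk": 10.4, "maize": 7.0})
    cands = generate_candidates(analysis, params)
    idents = {c.identity: c for c in cands}
    # milk supplies >=5% of >=5 micronutrients -> subgroup source candidate
    assert ("subgroup", "animal_milk") in idents
    assert idents[("subgroup", "animal_milk")].provenance == "source_rule"
    # parent dairy group pattern candidate is deduplicated away
    assert ("group", "dairy") not in idents


def test_no_candidates_is_allowed():
    params = _pattern_system()
    analysis = _analysis(params, {"milk": 7.0, "maize": 7.0})  # at medians
    assert generate_candidates(analysis, params) == []


def _two_candidate_system():
    foods = [
        {"id": "a", "group": "ga", "subgroup": "sa", "portion": 100.0,
         "bounds": (0.0, 3000.0), "comp": {"energy": 100.0, "iron": 8.0}},
        {"id": "b", "group": "gb", "subgroup": "sb", "portion": 100.0,
         "bounds": (0.0, 3000.0), "comp": {"energy": 100.0, "zinc": 8.0}},
        {"id": "filler", "group": "gf", "subgroup": "sf", "portion": 100.0,
         "bounds": (0.0, 5000.0), "comp": {"energy": 100.0}},
    ]
    return toy_params(foods, energy_requirement=400.0,
                      rni={"iron": 10.0, "zinc": 10.0})


def _cand(level, target, servings):
    return CandidateCFR(cfr=CFR(level, target, servings, 100.0),
                        provenance="source_rule",
                        best_diet_servings=servings, observed_median=0.0)


def test_screening_keeps_unique_bests_and_single_candidate():
    params = _two_candidate_system()
    ca, cb = _cand("subgroup", "sa", 5.0), _cand("subgroup", "sb", 5.0)
    assert screen_candidates([ca], params) == [ca]
    kept = {c.identity for c in screen_candidates([ca, cb], params, keep_k=2)}
    assert kept == {("subgroup", "sa"), ("subgroup", "sb")}


def test_screening_drops_dominated_when_truncation_binds():
    params = _two_candidate_system()
    strong, weak = _cand("subgroup", "sa", 10.0), _cand("subgroup", "sa", 2.0)
    # same target: 'strong' yields >= minimized %RNI for every nutrient
    kept = screen_candidates([strong, weak], params, keep_k=1)
    assert len(kept) == 1 and kept[0].cfr.servings_per_week == 10.0


def test_screening_drops_candidate_infeasible_alone():
    params = _two_candidate_system()
    # 40 servings x 100 kcal = 4000 kcal/week > 2800 target -> infeasible
    params.subgroup_bounds["sa"] = (0.0, 60.0)
    bad = _cand("subgroup", "sa", 40.0)
    ok = _cand("subgroup", "sb", 5.0)
    kept = screen_candidates([bad, ok], params)
    assert [c.identity for c in kept] == [("subgroup", "sb")]


def test_evaluate_empty_set_is_baseline_worst_case():
    params = _two_candidate_system()
    res = evaluate_cfr_set([], params)
    lp = build_diet_lp(params)
    for n in ("iron", "zinc"):
        direct = solve_nutrient_extreme(lp, n, "min").pct_rni[n]
        assert res.minimized_pct_rni[n] == pytest.approx(direct, abs=1e-9)
    assert res.feasible


def test_adequacy_cutoff_is_inclusive():
    params = _two_candidate_system()
    res = evaluate_cfr_set([CFR("subgroup", "sa", 5.0, 100.0)], params)
    v = res.minimized_pct_rni["iron"]
    assert v > 0
    at_cutoff = evaluate_cfr_set([CFR("subgroup", "sa", 5.0, 100.0)], params,
                                 adequacy_cutoff=v)
    # a nutrient sitting exactly at the cutoff counts as adequate (>=)
    assert at_cutoff.n_adequate >= 1


def test_cfr_monotonicity_nested_sets():
    params = _two_candidate_system()
    c1, c2 = CFR("subgroup", "sa", 4.0, 100.0), CFR("subgroup", "sb", 4.0, 100.0)
    r0 = evaluate_cfr_set([], params)
    r1 = evaluate_cfr_set([c1], params)
    r2 = evaluate_cfr_set([c1, c2], params)
    assert r0.feasible and r1.feasible and r2.feasible
    for n in MICROS:
        assert r1.minimized_pct_rni[n] >= r0.minimized_pct_rni[n] - 1e-9
        assert r2.minimized_pct_rni[n] >= r1.minimized_pct_rni[n] - 1e-9
    assert r0.n_adequate <= r1.n_adequate <= r2.n_adequate


def test_infeasible_set_reported_nf_not_error():
    params = _two_candidate_system()
    params.subgroup_bounds["sa"] = (0.0, 60.0)
    res = evaluate_cfr_set([CFR("subgroup", "sa", 40.0, 100.0)], params)
    assert not res.feasible
    assert res.n_adequate is None and res.minimized_pct_rni == {}


def test_systematic_search_completeness_and_ranking():
    params = _two_candidate_system()
    cands = [_cand("subgroup", "sa", 5.0), _cand("subgroup", "sb", 5.0),
             _cand("group", "gf", 3.0)]
    table = systematic_search(cands, params, max_set_size=5)
    assert len(table) == 7  # 2^3 - 1
    sizes = [len(r.cfr_set) for r in table]
    n_adq = [r.n_adequate for r in table if r.feasible]
    assert max(n_adq) == (table[0].n_adequate if table[0].feasible else None)
    # with a size cap, only subsets up to the cap appear
    capped = systematic_search(cands, params, max_set_size=2)
    assert len(capped) == 3 + 3
    assert all(len(r.cfr_set) <= 2 for r in capped)


def test_tie_break_prefers_smaller_set():
    params = _two_candidate_system()
    useful = _cand("subgroup", "sa", 5.0)
    vacuous = _cand("subgroup", "sb", 0.0)  # lower bound 0: changes nothing
    table = systematic_search([useful, vacuous], params)
    assert table[0].member_ids == (("subgroup", "sa"),)
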