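"""Consolidation across age bands: 2-of-3 rule, idempotence, NF reporting."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfrlp.cfr import evaluate_cfr_set
from cfrlp.consolidate import apply_consolidated, consolidate_identities
from cfrlp.lp import build_diet_lp, solve_best_diet
from cfrlp.model import CFR

from _toy import toy_params

BANDS = ("m6_8", "m9_11", "m12_23")


def _cfr(target, servings=5.0, level="subgroup"):
    return CFR(level, target, servings, 100.0)


def test_two_of_three_rule():
    a, b, c = _cfr("milk"), _cfr("beans"), _cfr("grains")
    sets = {"m6_8": [a, b], "m9_11": [a, c], "m12_23": [a]}
    idents = consolidate_identities(sets)
    assert ("subgroup", "milk") in idents  # in all three
    assert ("subgroup", "beans") not in idents  # single band: eliminated
    assert ("subgroup", "grains") not in idents
    sets2 = {"m6_8": [a, b], "m9_11": [b], "m12_23": [a]}
    assert consolidate_identities(sets2) == [("subgroup", "beans"),
                                             ("subgroup", "milk")]


def test_requires_exactly_three_sets():
    with pytest.raises(ValueError, match="exactly 3"):
        consolidate_identities({"m6_8": [], "m9_11": []})


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.lists(st.sampled_from(["milk", "beans", "grains", "veg"]),
                         max_size=4), min_size=3, max_size=3))
def test_two_of_three_rule_is_order_invariant(raw_sets):
    sets = [[_cfr(t) for t in s] for s in raw_sets]
    results = set()
    for perm in itertools.permutations(range(3)):
        by_band = {band: sets[perm[i]] for i, band in enumerate(BANDS)}
        results.add(tuple(consolidate_identities(by_band)))
    assert len(results) == 1


def _band_system(energy_requirement=400.0):
    foods = [
        {"id": "milk", "group": "dairy", "subgroup": "animal_milk",
         "portion": 100.0, "bounds": (0.0, 3000.0),
         "comp": {"energy": 100.0, "calcium": 120.0, "vitamin_b12": 0.5}},
        {"id": "beans", "group": "legumes", "subgroup": "beans",
         "portion": 100.0, "bounds": (0.0, 3000.0),
         "comp": {"energy": 130.0, "folate": 150.0, "iron": 2.0}},
        {"id": "filler", "group": "gf", "subgroup": "sf", "portion": 100.0,
         "bounds": (0.0, 9000.0), "comp": {"energy": 100.0}},
    ]
    return toy_params(
        foods, energy_requirement=energy_requirement,
        rni={"calcium": 400.0, "vitamin_b12": 0.7, "folate": 80.0, "iron": 10.0},
        medians={"dairy": 5.0, "legumes": 2.0, "gf": 5.0},
    )


def test_idempotence_on_identical_sets():
    params = _band_system()
    own_set = [_cfr("animal_milk", 6.0), _cfr("beans", 3.0)]
    best = solve_best_diet(build_diet_lp(params))
    idents = consolidate_identities({b: own_set for b in BANDS})
    out = apply_consolidated(
        idents,
        {b: params for b in BANDS},
        {b: best for b in BANDS},
        {b: own_set for b in BANDS},
    )
    reference = evaluate_cfr_set(own_set, params)
    for band in BANDS:
        res = out.bands[band].result
        assert out.bands[band].newly_added == []
        assert {c.identity for c in out.bands[band].applied} == set(idents)
        assert res.n_adequate == reference.n_adequate
        for n, v in reference.minimized_pct_rni.items():
            assert res.minimized_pct_rni[n] == pytest.approx(v, abs=1e-9)


def test_newly_added_cfr_gets_frequency_from_receiving_band_best_diet():
    params = _band_system()
    milk, beans = _cfr("animal_milk", 6.0), _cfr("beans", 3.0)
    sets = {"m6_8": [milk, beans], "m9_11": [milk, beans], "m12_23": [milk]}
    best = solve_best_diet(build_diet_lp(params))
    idents = consolidate_identities(sets)
    out = apply_consolidated(idents, {b: params for b in BANDS},
                             {b: best for b in BANDS}, sets)
    young = out.bands["m12_23"]
    assert ("subgroup", "beans") in young.newly_added
    applied = {c.identity: c for c in young.applied}
    # frequency derived from this band's best diet by the shared rounding rule
    from cfrlp.cfr import recommended_servings

    expected = recommended_servings(best.servings["beans"],
                                    params.subgroup_bounds["beans"][1])
    assert applied[("subgroup", "beans")].servings_per_week == expected
    # bands that had the CFR keep their own frequency
    assert {c.identity: c for c in out.bands["m6_8"].applied}[
        ("subgroup", "beans")].servings_per_week == 3.0


def test_absent_label_flagged_not_applicable():
    params = _band_system()
    params_no_beans = toy_params(
        [{"id": "milk", "group": "dairy", "subgroup": "animal_milk",
          "portion": 100.0, "bounds": (0.0, 3000.0),
          "comp": {"energy": 100.0, "calcium": 120.0}},
         {"id": "filler", "group": "gf", "subgroup": "sf", "portion": 100.0,
          "bounds": (0.0, 9000.0), "comp": {"energy": 100.0}}],
        energy_requirement=400.0,
    )
    milk, beans = _cfr("animal_milk", 6.0), _cfr("beans", 3.0)
    sets = {"m6_8": [milk, beans], "m9_11": [milk, beans], "m12_23": [milk]}
    best = solve_best_diet(build_diet_lp(params))
    best_nb = solve_best_diet(build_diet_lp(params_no_beans))
    out = apply_consolidated(
        consolidate_identities(sets),
        {"m6_8": params, "m9_11": params, "m12_23": params_no_beans},
        {"m6_8": best, "m9_11": best, "m12_23": best_nb},
        sets,
    )
    young = out.bands["m12_23"]
    assert ("subgroup", "beans") in young.not_applicable
    assert all(c.identity != ("subgroup", "beans") for c in young.applied)
    assert young.feasible


def test_low_energy_band_reports_nf_exactly_when_budget_exceeded():
    # milk CFR of 10 servings costs 1000 kcal/week
    milk = _cfr("animal_milk", 10.0)
    sets = {b: [milk] for b in BANDS}
    tight = _band_system(energy_requirement=100.0)  # 700 kcal/week budget
    roomy = _band_system(energy_requirement=400.0)  # 2800 kcal/week
    best_t = solve_best_diet(build_diet_lp(tight))
    best_r = solve_best_diet(build_diet_lp(roomy))
    out = apply_consolidated(
        consolidate_identities(sets),
        {"m6_8": tight, "m9_11": roomy, "m12_23": roomy},
        {"m6_8": best_t, "m9_11": best_r, "m12_23": best_r},
        sets,
    )
    assert not out.bands["m6_8"].feasible  # 1000 > 700: NF
    assert out.bands["m9_11"].feasible and out.bands["m12_23"].feasible
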