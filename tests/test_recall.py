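"""Recall processing: portions, weekly bounds, observed medians."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfrlp.model import RecallSet
from cfrlp.recall import (
    build_model_parameters,
    median_consumer_portion,
    observed_median_group_servings,
    weekly_group_serving_bounds,
    weekly_item_gram_bounds,
)
from cfrlp.synthetic import SyntheticSpec, generate_food_system, generate_study_config

from _toy import toy_params  # noqa: F401  (shared helper import path check)


def recall_set(rows):
    """rows: (child, food, grams) in one target group 'g'."""
    df = pd.DataFrame(
        [(c, "g", f, g) for c, f, g in rows], columns=RecallSet.COLUMNS
    )
    return RecallSet(records=df)


def sorted_percentile(values, q):
    """Independent linear-interpolation percentile oracle."""
    x = sorted(values)
    pos = q / 100.0 * (len(x) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return x[lo] + (pos - lo) * (x[hi] - x[lo])


@pytest.mark.parametrize(
    "grams,expected",
    [([40, 60, 80], 60.0), ([40, 60], 50.0), ([55], 55.0)],
)
def test_median_consumer_portion(grams, expected):
    rows = [(f"c{i}", "f", g) for i, g in enumerate(grams)]
    rows += [(f"z{i}", "other", 10) for i in range(3)]  # non-consumers
    assert median_consumer_portion(recall_set(rows), "f", "g") == expected


def test_median_consumer_portion_sums_within_day_and_errors_without_consumers():
    rs = recall_set([("c1", "f", 30), ("c1", "f", 20), ("c2", "f", 10)])
    assert median_consumer_portion(rs, "f", "g") == 30.0  # {50, 10}
    with pytest.raises(ValueError, match="no consumers"):
        median_consumer_portion(rs, "unknown", "g")


def test_item_bounds_sparse_consumption_has_zero_floor():
    rows = [("c0", "f", 70)] + [(f"c{i}", "other", 5) for i in range(1, 10)]
    lo, hi = weekly_item_gram_bounds(recall_set(rows), "f", "g")
    assert lo == 0.0 and hi > 0.0


def test_item_bounds_degenerate_distribution():
    rows = [(f"c{i}", "f", 30) for i in range(8)]
    assert weekly_item_gram_bounds(recall_set(rows), "f", "g") == (210.0, 210.0)


def test_item_bounds_match_percentile_oracle():
    rows = [(f"c{i:02d}", "f", float(i)) for i in range(1, 21)]
    lo, hi = weekly_item_gram_bounds(recall_set(rows), "f", "g")
    weekly = [7.0 * i for i in range(1, 21)]
    assert lo == pytest.approx(sorted_percentile(weekly, 10), abs=1e-9)
    assert hi == pytest.approx(sorted_percentile(weekly, 90), abs=1e-9)


def test_item_bounds_invalid_percentiles():
    rs = recall_set([("c", "f", 10)])
    with pytest.raises(ValueError, match="p_lo"):
        weekly_item_gram_bounds(rs, "f", "g", p_lo=90, p_hi=10)


def test_group_bounds_single_portion_per_day():
    rows = [(f"c{i}", "f", 50.0) for i in range(10)]
    bounds = weekly_group_serving_bounds(
        recall_set(rows), ["f"], "g", {"f": 50.0})
    assert bounds == (7.0, 7.0)


def test_group_bounds_unconsumed_group_is_zero():
    rows = [(f"c{i}", "other", 30.0) for i in range(5)]
    assert weekly_group_serving_bounds(
        recall_set(rows), ["f"], "g", {"f": 50.0}) == (0.0, 0.0)


def test_group_bounds_two_food_group_matches_bruteforce():
    rng = np.random.default_rng(5)
    rows = []
    per_child = {}
    for i in range(17):
        a, b = rng.uniform(0, 80, 2)
        rows += [(f"c{i:02d}", "fa", a), (f"c{i:02d}", "fb", b)]
        per_child[f"c{i:02d}"] = a / 40.0 + b / 25.0
    portions = {"fa": 40.0, "fb": 25.0}
    lo, hi = weekly_group_serving_bounds(
        recall_set(rows), ["fa", "fb"], "g", portions)
    weekly = [7 * v for v in per_child.values()]
    assert lo == pytest.approx(sorted_percentile(weekly, 10), abs=1e-9)
    assert hi == pytest.approx(sorted_percentile(weekly, 90), abs=1e-9)
    med = observed_median_group_servings(recall_set(rows), ["fa", "fb"], "g", portions)
    assert med == pytest.approx(sorted_percentile(weekly, 50), abs=1e-9)


def test_observed_median_group_servings_cases():
    rows = [(f"c{i}", "f", 50.0) for i in range(9)]
    assert observed_median_group_servings(recall_set(rows), ["f"], "g",
                                          {"f": 50.0}) == 7.0
    # half of children 0/day, half 2/day -> median of {0,...,14} = 7
    rows = [(f"c{i}", "f", 100.0) for i in range(5)]
    rows += [(f"z{i}", "other", 10.0) for i in range(5)]
    assert observed_median_group_servings(recall_set(rows), ["f"], "g",
                                          {"f": 50.0}) == 7.0
    assert observed_median_group_servings(recall_set(rows), ["nope"], "g",
                                          {}) == 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    grams=st.lists(st.floats(1.0, 500.0), min_size=3, max_size=40),
    c=st.floats(0.1, 10.0),
)
def test_scaling_recalls_scales_portions_and_bounds(grams, c):
    rows = [(f"c{i:02d}", "f", g) for i, g in enumerate(grams)]
    scaled = [(f"c{i:02d}", "f", g * c) for i, g in enumerate(grams)]
    rs, rs_c = recall_set(rows), recall_set(scaled)
    assert median_consumer_portion(rs_c, "f", "g") == pytest.approx(
        c * median_consumer_portion(rs, "f", "g"), rel=1e-12)
    lo, hi = weekly_item_gram_bounds(rs, "f", "g")
    lo_c, hi_c = weekly_item_gram_bounds(rs_c, "f", "g")
    assert (lo_c, hi_c) == pytest.approx((c * lo, c * hi), rel=1e-9)
    assert lo <= hi  # bounds ordering
    # servings are scale-free when portions rescale proportionally
    b = weekly_group_serving_bounds(rs, ["f"], "g",
                                    {"f": median_consumer_portion(rs, "f", "g")})
    b_c = weekly_group_serving_bounds(rs_c, ["f"], "g",
                                      {"f": median_consumer_portion(rs_c, "f", "g")})
    assert b_c == pytest.approx(b, rel=1e-9)


def _study_inputs(**kw):
    spec = SyntheticSpec(**kw)
    fs = generate_food_system(spec)
    config = generate_study_config(spec)
    return spec, fs, config


def test_build_model_parameters_structure(small_study):
    s = small_study
    tg = s.config.group("settled_m9_11")
    params = build_model_parameters(s.recalls, s.composition, s.config, tg)
    assert params.weekly_energy_target == 7 * tg.energy_requirement
    assert params.weekly_breast_milk_grams == 7 * 520.0
    # every consumed food is present with valid bounds
    assert set(params.food_ids()) == set(s.recalls.foods(tg.id))
    for pf in params.foods:
        assert pf.portion_g > 0
        assert pf.gram_bounds[0] <= pf.gram_bounds[1]
    for lo, hi in params.group_bounds.values():
        assert 0 <= lo <= hi


def test_build_model_parameters_breast_milk_exceeding_energy_is_error(small_study):
    s = small_study
    tg = s.config.group("settled_m6_8")
    tg_small = type(tg)(
        id=tg.id, age_band=tg.age_band, livelihood=tg.livelihood,
        energy_requirement=300.0,  # < breast-milk energy (570 g x 0.66)
        rni=tg.rni, breast_milk=tg.breast_milk,
    )
    with pytest.raises(ValueError, match="breast milk alone exceeds"):
        build_model_parameters(s.recalls, s.composition, s.config, tg_small)


def test_build_model_parameters_empty_group_is_error(small_study):
    s = small_study
    tg = s.config.group("settled_m6_8")
    empty = RecallSet(records=s.recalls.records.iloc[0:0])
    with pytest.raises(ValueError, match="no recall records"):
        build_model_parameters(empty, s.composition, s.config, tg)


def test_two_identical_children_collapse_bounds():
    rows = [("c1", "f", 40.0), ("c2", "f", 40.0)]
    rs = recall_set(rows)
    assert weekly_item_gram_bounds(rs, "f", "g") == (280.0, 280.0)
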