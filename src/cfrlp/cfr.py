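"""Generate, screen, and systematically test complementary feeding
recommendations (CFR) for one target group.

Candidate CFR come from two rules applied to the nutritionally best diet:

* *pattern rule* (food-group level): groups modelled at more servings than
  the median observed for that group — food-group patterns with nutritional
  benefits;
* *source rule* (subgroup level): subgroups contributing >=5 % of the content
  of at least five target micronutrients — the best food sources.

Candidates are screened in worst-case mode (per-nutrient minimized diets with
the candidate's lower bound active), then every combination of the screened
candidates up to a maximum set size is evaluated.  Population-level adequacy
for a nutrient means its minimized 7-day diet value reaches >=65 % of the RNI;
sets are ranked by the number of adequate micronutrients, then parsimony,
then total worst-case adequacy, then diet cost when a price table is
supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .lp import _target_micros, build_diet_lp, solve_nutrient_extreme
from .model import CFR, CFRSetResult, ModelParameters
from .nutrients import BREAST_MILK_SUBGROUP, BestSourceCall, GroupAnalysis

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CandidateCFR:
    cfr: CFR
    provenance: str  # "pattern_rule" | "source_rule"
    best_diet_servings: float
    observed_median: float
    nutrients_supported: int = 0

    @property
    def identity(self) -> tuple[str, str]:
        return self.cfr.identity


def _label_servings(best_servings: Mapping[str, float], params: ModelParameters,
                    level: str, label: str) -> float:
    members = params.members(level, label)
    ids = params.food_ids()
    return float(sum(best_servings.get(ids[i], 0.0) for i in members))


def _label_portion(params: ModelParameters, level: str, label: str) -> float:
    """Representative serving size for a group/subgroup: the median of its
    member foods' consumer portions."""
    members = params.members(level, label)
    return float(np.median([params.foods[i].portion_g for i in members]))


def recommended_servings(best_servings: float, upper_bound: float) -> float:
    """Freeze a candidate's recommended servings/week: best-diet servings
    rounded half-up to an integer, clamped to [1, label upper bound]."""
    v = float(round_half_up(best_servings))
    v = max(v, min(1.0, upper_bound))
    return min(v, upper_bound)


def generate_candidates(
    analysis: GroupAnalysis, params: ModelParameters
) -> list[CandidateCFR]:
    """Union of pattern-rule group candidates and source-rule subgroup
    candidates; when a flagged subgroup's parent group also fires, the
    subgroup wins and the group candidate is dropped."""
    best = analysis.best_diet
    candidates: list[CandidateCFR] = []

    source_subgroups = [
        c for c in analysis.best_sources
        if c.flagged and c.subgroup_id != BREAST_MILK_SUBGROUP
    ]
    covered_groups = set()
    for call in source_subgroups:
        sg = call.subgroup_id
        if sg not in params.subgroup_bounds:
            continue
        for f in params.food_ids():
            if params.composition[f].subgroup_id == sg:
                covered_groups.add(params.composition[f].group_id)
        servings = _label_servings(best.servings, params, "subgroup", sg)
        rec = recommended_servings(servings, params.subgroup_bounds[sg][1])
        candidates.append(
            CandidateCFR(
                cfr=CFR("subgroup", sg, rec, _label_portion(params, "subgroup", sg)),
                provenance="source_rule",
                best_diet_servings=servings,
                observed_median=params.observed_median_subgroup_servings.get(sg, 0.0),
                nutrients_supported=call.n_nutrients_supported,
            )
        )

    for g in sorted(params.group_bounds):
        if g in covered_groups:
            continue  # subgroup wins over its parent group
        servings = _label_servings(best.servings, params, "group", g)
        med = params.observed_median_group_servings.get(g, 0.0)
        if servings <= med + 1e-9:
            continue  # strict >: equal-to-median patterns carry no benefit
        rec = recommended_servings(servings, params.group_bounds[g][1])
        candidates.append(
            CandidateCFR(
                cfr=CFR("group", g, rec, _label_portion(params, "group", g)),
                provenance="pattern_rule",
                best_diet_servings=servings,
                observed_median=med,
            )
        )

    candidates.sort(key=lambda c: c.identity)
    if not candidates:
        logger.warning("no CFR candidates for %s", params.target_group.id)
    return candidates


def evaluate_cfr_set(
    cfr_set: Sequence[CFR],
    params: ModelParameters,
    adequacy_cutoff: float = 65.0,
    prices: Optional[Mapping[str, float]] = None,
    energy_slack: float = 0.0,
) -> CFRSetResult:
    """Worst-case adequacy of a CFR set: per target micronutrient, the %RNI of
    the minimized 7-day diet with all CFR lower bounds active.

    Infeasibility (the energy equality cannot hold under the recommended
    servings) is a result, reported as NF, never an error.
    """
    try:
        lp = build_diet_lp(params, cfr_set, energy_slack=energy_slack)
    except ValueError as exc:
        logger.info("CFR set structurally infeasible: %s", exc)
        return CFRSetResult(list(cfr_set), {}, None, False)
    micros = _target_micros(params)
    minimized: dict[str, float] = {}
    for n in micros:
        sol = solve_nutrient_extreme(lp, n, "min")
        if not sol.optimal:
            return CFRSetResult(list(cfr_set), {}, None, False)
        minimized[n] = sol.pct_rni[n]
    n_adequate = sum(1 for n in micros if minimized[n] >= adequacy_cutoff)
    cost = None
    if prices is not None:
        cost = _min_diet_cost(lp, prices)
    return CFRSetResult(list(cfr_set), minimized, n_adequate, True, cost)


def _min_diet_cost(lp, prices: Mapping[str, float]) -> Optional[float]:
    """Cheapest feasible weekly diet under the set's constraints."""
    from .lp import DEFAULT_SOLVER, _base_constraints

    missing = [f for f in lp.food_ids if f not in prices]
    if missing:
        logger.warning("price table missing %d foods; cost skipped", len(missing))
        return None
    c = np.array(
        [prices[f] * pf.portion_g / 100.0 for f, pf in zip(lp.food_ids, lp.params.foods)]
    )
    A_ub, b_ub, A_eq, b_eq = _base_constraints(lp)
    ok, x, _ = DEFAULT_SOLVER(c, A_ub, b_ub, A_eq, b_eq, lp.var_bounds)
    return float(c @ x) if ok else None


def screen_candidates(
    candidates: Sequence[CandidateCFR],
    params: ModelParameters,
    keep_k: int = 8,
    adequacy_cutoff: float = 65.0,
    energy_slack: float = 0.0,
) -> list[CandidateCFR]:
    """Screen candidates in worst-case mode to the subset most likely, in
    combination, to lift all target micronutrients.

    Each candidate is evaluated alone (its per-nutrient minimized diets); the
    union of the top-2 candidates per nutrient is kept, truncated to
    ``keep_k`` by total worst-case adequacy.  Candidates that are infeasible
    alone are dropped with a log entry.  Deterministic output order.
    """
    if not candidates:
        return []
    results: dict[tuple[str, str], CFRSetResult] = {}
    kept: list[CandidateCFR] = []
    for cand in candidates:
        res = evaluate_cfr_set([cand.cfr], params, adequacy_cutoff,
                               energy_slack=energy_slack)
        if not res.feasible:
            logger.info("candidate %s infeasible alone; dropped", cand.identity)
            continue
        results[cand.identity] = res
        kept.append(cand)
    if len(kept) <= 1:
        return kept

    micros = _target_micros(params)
    selected: set[tuple[str, str]] = set()
    for n in micros:
        ranked = sorted(
            kept,
            key=lambda c: (-results[c.identity].minimized_pct_rni[n], c.identity),
        )
        selected.update(c.identity for c in ranked[:2])

    def total_adequacy(c: CandidateCFR) -> float:
        return sum(results[c.identity].minimized_pct_rni.values())

    chosen = [c for c in kept if c.identity in selected]
    chosen.sort(key=lambda c: (-total_adequacy(c), c.identity))
    if len(chosen) > keep_k:
        logger.info("screening truncated %d -> %d candidates", len(chosen), keep_k)
        chosen = chosen[:keep_k]
    return chosen


def systematic_search(
    screened: Sequence[CandidateCFR],
    params: ModelParameters,
    max_set_size: int = 5,
    adequacy_cutoff: float = 65.0,
    prices: Optional[Mapping[str, float]] = None,
    energy_slack: float = 0.0,
) -> list[CFRSetResult]:
    """Evaluate every non-empty combination of the screened candidates up to
    ``max_set_size`` and return the full ranked table.

    Ranking: (1) adequate-micronutrient count, descending (NF sets last);
    (2) set size, ascending (parsimony); (3) summed minimized %RNI,
    descending; (4) minimum diet cost, ascending, when prices are supplied;
    (5) lexicographic identity order.  Infeasible sets are retained, flagged
    NF.
    """
    ordered = sorted(screened, key=lambda c: c.identity)
    table: list[CFRSetResult] = []
    for k in range(1, min(len(ordered), max_set_size) + 1):
        for combo in combinations(ordered, k):
            res = evaluate_cfr_set(
                [c.cfr for c in combo], params, adequacy_cutoff, prices,
                energy_slack=energy_slack,
            )
            table.append(res)

    def key(res: CFRSetResult):
        return (
            -(res.n_adequate if res.feasible else -1),
            len(res.cfr_set),
            -(sum(res.minimized_pct_rni.values()) if res.feasible else 0.0),
            res.diet_cost if res.diet_cost is not None else float("inf"),
            res.member_ids,
        )

    table.sort(key=key)
    return table


@dataclass
class CFRPipelineResult:
    """Full CFR stage output for one target group."""

    target_group_id: str
    candidates: list[CandidateCFR]
    screened: list[CandidateCFR]
    search_table: list[CFRSetResult]
    selected: Optional[CFRSetResult]
    baseline: CFRSetResult = None  # empty-set worst-case profile


def run_cfr_pipeline(
    analysis: GroupAnalysis,
    params: ModelParameters,
    keep_k: int = 8,
    max_set_size: int = 5,
    adequacy_cutoff: float = 65.0,
    prices: Optional[Mapping[str, float]] = None,
    energy_slack: float = 0.0,
) -> CFRPipelineResult:
    baseline = evaluate_cfr_set([], params, adequacy_cutoff, energy_slack=energy_slack)
    candidates = generate_candidates(analysis, params)
    screened = screen_candidates(candidates, params, keep_k, adequacy_cutoff,
                                 energy_slack=energy_slack)
    table = systematic_search(screened, params, max_set_size, adequacy_cutoff,
                              prices, energy_slack=energy_slack)
    selected = table[0] if table else None
    return CFRPipelineResult(
        target_group_id=params.target_group.id,
        candidates=candidates,
        screened=screened,
        search_table=table,
        selected=selected,
        baseline=baseline,
    )
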