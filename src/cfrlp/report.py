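"""One-command orchestration of the full analysis and paper-style outputs.

``run_study`` executes, for every target group: recall processing (model
parameters), the best-diet / maximized-diet suite with problem-nutrient
classification and best-source identification, CFR candidate generation,
screening and the systematic combination search; then consolidates the
selected CFR sets across age bands within each livelihood group.  The result
is a ``StudyReport`` that serializes to deterministic JSON (byte-identical
across reruns of the same inputs) and renders to CSV/markdown tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .cfr import CFRPipelineResult, run_cfr_pipeline
from .consolidate import ConsolidationResult, apply_consolidated, consolidate_identities
from .model import (
    AGE_BANDS,
    CFR,
    CFRSetResult,
    CompositionTable,
    DietSolution,
    ModelParameters,
    RecallSet,
    StudyConfig,
)
from .nutrients import GroupAnalysis, run_group_analysis
from .recall import build_model_parameters, parameters_to_dict

logger = logging.getLogger(__name__)

OBJECTIVE_NOTE = (
    "nutritionally best diet objective: maximize sum over target "
    "micronutrients of min(1, intake/RNI), with a lexicographic tie-break "
    "minimizing deviation of group servings from observed medians"
)


@dataclass
class GroupReport:
    params: ModelParameters
    analysis: GroupAnalysis
    cfr: CFRPipelineResult


@dataclass
class StudyReport:
    config: StudyConfig
    groups: dict[str, GroupReport] = field(default_factory=dict)
    consolidations: dict[str, ConsolidationResult] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def run_study(
    composition: CompositionTable,
    recalls: RecallSet,
    config: StudyConfig,
    prices: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> StudyReport:
    """Run the full pipeline for every target group in the config."""
    th = config.thresholds
    report = StudyReport(config=config)
    report.provenance = {
        "solver": "highs (scipy.optimize.linprog)",
        "seed": seed,
        "notes": [OBJECTIVE_NOTE],
        "thresholds": {
            "adequacy_cutoff": th.adequacy_cutoff,
            "rni_cutoff": th.rni_cutoff,
            "source_share": th.source_share,
            "source_min_nutrients": th.source_min_nutrients,
            "p_lo": th.p_lo, "p_hi": th.p_hi,
            "keep_k": th.keep_k, "max_set_size": th.max_set_size,
        },
    }
    if prices is None:
        logger.info("no price table supplied; diet-cost tie-break skipped")

    for tg in config.target_groups:
        if recalls.for_group(tg.id).empty:
            logger.warning("no recalls for target group %s; skipped", tg.id)
            continue
        params = build_model_parameters(recalls, composition, config, tg)
        analysis = run_group_analysis(
            params, th.rni_cutoff, th.source_share, th.source_min_nutrients
        )
        cfr = run_cfr_pipeline(
            analysis, params, th.keep_k, th.max_set_size, th.adequacy_cutoff,
            prices, energy_slack=th.energy_slack,
        )
        report.groups[tg.id] = GroupReport(params, analysis, cfr)

    by_livelihood: dict[str, dict[str, str]] = {}
    for tg in config.target_groups:
        if tg.id in report.groups:
            by_livelihood.setdefault(tg.livelihood, {})[tg.age_band] = tg.id
    for livelihood, bands in sorted(by_livelihood.items()):
        if set(bands) != set(AGE_BANDS):
            logger.warning(
                "livelihood %s lacks all three age bands; consolidation skipped",
                livelihood,
            )
            continue
        selected_sets = {}
        params_by_band = {}
        best_by_band = {}
        age_n_adequate = {}
        for band, gid in bands.items():
            gr = report.groups[gid]
            sel = gr.cfr.selected
            selected_sets[band] = list(sel.cfr_set) if sel and sel.feasible else []
            params_by_band[band] = gr.params
            best_by_band[band] = gr.analysis.best_diet
            age_n_adequate[band] = sel.n_adequate if sel else None
        identities = consolidate_identities(selected_sets)
        report.consolidations[livelihood] = apply_consolidated(
            identities, params_by_band, best_by_band, selected_sets,
            livelihood=livelihood,
            adequacy_cutoff=th.adequacy_cutoff,
            age_specific_n_adequate=age_n_adequate,
            energy_slack=th.energy_slack,
        )
    return report


# ---------------------------------------------------------------------------
# JSON serialization (deterministic)


def _round(x, nd=9):
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in sorted(x.items())}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    return x


def _diet_dict(sol: DietSolution) -> dict:
    if not sol.optimal:
        return {"status": "infeasible", "diagnosis": sol.diagnosis}
    return {
        "status": "optimal",
        "objective": sol.objective_value,
        "servings_per_week": sol.servings,
        "nutrient_amounts_per_day": sol.nutrient_totals,
        "pct_rni": sol.pct_rni,
    }


def _cfr_dict(c: CFR) -> dict:
    return {
        "level": c.level, "target": c.target_id,
        "servings_per_week": c.servings_per_week, "portion_g": c.portion_g,
    }


def _setresult_dict(res: CFRSetResult) -> dict:
    out = {
        "members": [_cfr_dict(c) for c in sorted(res.cfr_set, key=lambda c: c.identity)],
        "feasible": res.feasible,
    }
    if res.feasible:
        out["minimized_pct_rni"] = res.minimized_pct_rni
        out["n_adequate"] = res.n_adequate
        if res.diet_cost is not None:
            out["diet_cost"] = res.diet_cost
    else:
        out["n_adequate"] = "NF"
    return out


def report_to_dict(report: StudyReport) -> dict:
    groups = {}
    for gid, gr in report.groups.items():
        groups[gid] = {
            "parameters": parameters_to_dict(gr.params),
            "best_diet": _diet_dict(gr.analysis.best_diet),
            "problem_nutrients": [
                {"nutrient": c.nutrient_id, "class": c.klass,
                 "best_pct_rni": c.best_pct_rni, "max_pct_rni": c.max_pct_rni}
                for c in gr.analysis.problem_nutrients
            ],
            "best_sources": [
                {"subgroup": c.subgroup_id, "n_nutrients_supported": c.n_nutrients_supported,
                 "flagged": c.flagged, "shares_pct": c.shares}
                for c in gr.analysis.best_sources
            ],
            "candidates": [
                {"cfr": _cfr_dict(c.cfr), "provenance": c.provenance,
                 "best_diet_servings": c.best_diet_servings,
                 "observed_median": c.observed_median,
                 "nutrients_supported": c.nutrients_supported}
                for c in gr.cfr.candidates
            ],
            "screened": [list(c.identity) for c in gr.cfr.screened],
            "baseline": _setresult_dict(gr.cfr.baseline),
            "search": [_setresult_dict(r) for r in gr.cfr.search_table],
            "selected": _setresult_dict(gr.cfr.selected) if gr.cfr.selected else None,
        }
    consolidations = {}
    for livelihood, cons in report.consolidations.items():
        consolidations[livelihood] = {
            "identities": [list(i) for i in cons.identities],
            "bands": {
                band: {
                    "applied": [_cfr_dict(c) for c in out.applied],
                    "not_applicable": [list(i) for i in out.not_applicable],
                    "newly_added": [list(i) for i in out.newly_added],
                    "result": _setresult_dict(out.result) if out.result else None,
                    "age_specific_n_adequate": out.age_specific_n_adequate,
                }
                for band, out in cons.bands.items()
            },
        }
    return _round({
        "provenance": report.provenance,
        "groups": groups,
        "consolidation": consolidations,
    })


def report_to_json(report: StudyReport) -> str:
    return json.dumps(report_to_dict(report), sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Table rendering (CSV + markdown mirrors)


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for r in rows:
        lines.append("| " + " | ".join(str(v) for v in r) + " |")
    return "\n".join(lines) + "\n"


def render_tables(report: StudyReport, out_dir) -> list[Path]:
    """Write CSV and markdown mirrors of the headline tables; infeasible
    cells render literally as ``NF``."""
    import pandas as pd

    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        p = tables / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)

    for gid, gr in report.groups.items():
        save(pd.DataFrame([
            {"nutrient": c.nutrient_id, "class": c.klass,
             "best_pct_rni": round(c.best_pct_rni, 1),
             "max_pct_rni": round(c.max_pct_rni, 1)}
            for c in gr.analysis.problem_nutrients
        ]), f"problem_nutrients_{gid}")
        save(pd.DataFrame([
            {"subgroup": c.subgroup_id,
             "n_nutrients_supported": c.n_nutrients_supported,
             "flagged": c.flagged,
             **{f"share_{n}": round(s, 1) for n, s in c.shares.items()}}
            for c in gr.analysis.best_sources
        ]), f"best_sources_{gid}")
        save(pd.DataFrame([
            {"level": c.cfr.level, "target": c.cfr.target_id,
             "servings_per_week": round(c.cfr.servings_per_week),
             "portion_g": round(c.cfr.portion_g, 1),
             "provenance": c.provenance,
             "best_diet_servings": round(c.best_diet_servings, 2),
             "observed_median": round(c.observed_median, 2)}
            for c in gr.cfr.candidates
        ]), f"cfr_candidates_{gid}")
        rows = []
        for r in gr.cfr.search_table:
            row = {
                "members": "+".join(f"{l}:{t}" for l, t in r.member_ids),
                "size": len(r.cfr_set),
                "feasible": r.feasible,
                "n_adequate": r.n_adequate if r.feasible else "NF",
            }
            if r.feasible:
                row.update({f"min_pct_{n}": round(v, 1)
                            for n, v in r.minimized_pct_rni.items()})
            if r.diet_cost is not None:
                row["diet_cost"] = round(r.diet_cost, 2)
            rows.append(row)
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame([{"members": "(no candidates)", "size": 0,
                                "feasible": "", "n_adequate": ""}])
        save(df, f"cfr_search_{gid}")

    # markdown CFR summary per group (selected set + worst-case profile)
    md = ["# Selected complementary feeding recommendations\n"]
    cutoff = report.config.thresholds.adequacy_cutoff
    for gid, gr in report.groups.items():
        md.append(f"## {gid}\n")
        sel = gr.cfr.selected
        if sel is None:
            md.append("No candidate CFR.\n")
            continue
        if not sel.feasible:
            md.append("Best set: NF\n")
            continue
        rows = [[c.target_id, c.level, round(c.servings_per_week),
                 round(c.portion_g)] for c in sel.cfr_set]
        md.append(_md_table(
            ["recommendation", "level", "servings/week", "portion (g)"], rows))
        rows = [[n, round(v, 1), "adequate" if v >= cutoff else "below cutoff"]
                for n, v in sorted(sel.minimized_pct_rni.items())]
        md.append(_md_table(["nutrient", "minimized %RNI", f"vs {cutoff:.0f}%"], rows))
        md.append(f"Adequate micronutrients: **{sel.n_adequate} of "
                  f"{len(sel.minimized_pct_rni)}**\n")
    p = tables / "cfr_summary.md"
    p.write_text("\n".join(md))
    written.append(p)

    for livelihood, cons in report.consolidations.items():
        rows = []
        for level, target in cons.identities:
            row = {"cfr": f"{level}:{target}"}
            for band, outb in cons.bands.items():
                applied = {c.identity: c for c in outb.applied}
                c = applied.get((level, target))
                row[band] = round(c.servings_per_week) if c else "not applicable"
            rows.append(row)
        band_row = {"cfr": "n_adequate (consolidated)"}
        spec_row = {"cfr": "n_adequate (age-specific)"}
        for band, outb in cons.bands.items():
            band_row[band] = (outb.result.n_adequate if outb.feasible else "NF")
            spec_row[band] = outb.age_specific_n_adequate
        rows.extend([band_row, spec_row])
        save(pd.DataFrame(rows), f"consolidated_{livelihood}")

    return written


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
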