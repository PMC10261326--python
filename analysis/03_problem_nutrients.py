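#!/usr/bin/env python
"""Identify problem nutrients and best food sources per target group.

For each group: solve the nutritionally best diet (Module-II-style capped
adequacy objective) and the eleven per-nutrient maximized diets; classify
each target micronutrient as an absolute problem (<100% RNI even when
maximized), a partial problem (<100% in the best diet but reachable alone),
or no problem; and flag food subgroups supplying >=5% of >=5 micronutrients.

Writes results/tables/problem_nutrients_<group>.csv and
best_sources_<group>.csv.
"""

import importlib.util
import logging
from pathlib import Path

import pandas as pd

from cfrlp.nutrients import run_group_analysis
from cfrlp.recall import build_model_parameters

ROOT = Path(__file__).resolve().parent.parent
_spec = importlib.util.spec_from_file_location(
    "build_params", ROOT / "analysis" / "02_build_parameters.py")
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main():
    logging.basicConfig(level=logging.WARNING)
    config, composition, recalls = _mod.load_inputs()
    out = ROOT / "results" / "tables"
    out.mkdir(parents=True, exist_ok=True)
    print(f"{'group':28s} problem nutrients (Abs=absolute, Par=partial)")
    for tg in config.target_groups:
        params = build_model_parameters(recalls, composition, config, tg)
        an = run_group_analysis(params)
        pd.DataFrame([
            {"nutrient": c.nutrient_id, "class": c.klass,
             "best_pct_rni": round(c.best_pct_rni, 1),
             "max_pct_rni": round(c.max_pct_rni, 1)}
            for c in an.problem_nutrients
        ]).to_csv(out / f"problem_nutrients_{tg.id}.csv", index=False)
        pd.DataFrame([
            {"subgroup": c.subgroup_id, "n_supported": c.n_nutrients_supported,
             "flagged": c.flagged,
             **{f"share_{n}": round(v, 1) for n, v in c.shares.items()}}
            for c in an.best_sources
        ]).to_csv(out / f"best_sources_{tg.id}.csv", index=False)
        marks = [f"{c.nutrient_id}[{'Abs' if c.klass == 'absolute' else 'Par'}]"
                 for c in an.problem_nutrients if c.klass != "none"]
        print(f"{tg.id:28s} {', '.join(marks) or '-'}")
    print(f"\nwrote problem-nutrient and best-source tables to {out}")


if __name__ == "__main__":
    main()
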