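#!/usr/bin/env python
"""Turn each target group's 24h recalls into LP model parameters.

Per group: median consumer portion per food, weekly item gram bounds
(10th-90th percentiles of daily grams x 7 over all children), weekly
group/subgroup serving bounds, the fixed breast-milk term, and the weekly
energy equality target.  Dumps parameters_<group>.json for audit under
results/parameters/.
"""

import logging
from pathlib import Path
import json
import sys

from cfrlp import io as cio
from cfrlp.recall import build_model_parameters, parameters_to_dict

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"


def load_inputs():
    if not (DATA / "study.yaml").exists():
        sys.exit("run analysis/01_simulate.py first")
    config = cio.load_study_config(DATA / "study.yaml")
    composition = cio.load_composition_table(
        DATA / "composition.csv", nutrient_ids=config.nutrient_ids())
    recalls = cio.load_recalls(DATA / "recalls.csv", composition,
                               config.exclusions)
    return config, composition, recalls


def main():
    logging.basicConfig(level=logging.WARNING)
    config, composition, recalls = load_inputs()
    out = ROOT / "results" / "parameters"
    out.mkdir(parents=True, exist_ok=True)
    print(f"{'group':28s} {'foods':>5s} {'E kcal/wk':>10s} {'bm kcal/wk':>10s}")
    for tg in config.target_groups:
        params = build_model_parameters(recalls, composition, config, tg)
        (out / f"parameters_{tg.id}.json").write_text(
            json.dumps(parameters_to_dict(params), indent=1, sort_keys=True))
        print(f"{tg.id:28s} {len(params.foods):5d} "
              f"{params.weekly_energy_target:10.0f} "
              f"{params.breast_milk_weekly('energy'):10.0f}")
    print(f"\nwrote parameter dumps to {out}")


if __name__ == "__main__":
    main()
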