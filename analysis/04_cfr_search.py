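#!/usr/bin/env python
"""Derive and systematically test complementary feeding recommendations.

Per target group: generate candidate CFR (food-group patterns above the
observed median; best-source subgroups), screen them in worst-case mode,
evaluate every combination of the screened candidates (up to 5), and select
the best set by worst-case adequacy (minimized %RNI >= 65 for as many of the
eleven micronutrients as possible), then parsimony.

Writes results/tables/cfr_candidates_<group>.csv, cfr_search_<group>.csv and
a human-readable cfr_summary.md; prints the selected sets.
"""

import importlib.util
import logging
from pathlib import Path

from cfrlp.report import render_tables, run_study

ROOT = Path(__file__).resolve().parent.parent
_spec = importlib.util.spec_from_file_location(
    "build_params", ROOT / "analysis" / "02_build_parameters.py")
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main():
    logging.basicConfig(level=logging.WARNING)
    config, composition, recalls = _mod.load_inputs()
    report = run_study(composition, recalls, config, seed=0)
    render_tables(report, ROOT / "results")
    print(f"{'group':28s} {'set':>3s} {'adequate':>8s}  members")
    for gid, gr in report.groups.items():
        sel = gr.cfr.selected
        if sel and sel.feasible:
            members = ", ".join(t for _, t in sel.member_ids)
            print(f"{gid:28s} {len(sel.cfr_set):3d} "
                  f"{sel.n_adequate:5d}/11  {members}")
        else:
            print(f"{gid:28s}   -      NF")
    print(f"\nwrote CFR tables to {ROOT / 'results' / 'tables'}")


if __name__ == "__main__":
    main()
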