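"""Consolidate age-specific CFR sets into one set per livelihood group.

The 2-of-3 rule: a CFR identity (group/subgroup label) proposed for at least
two of the three age bands is retained and applied to all bands — including a
band where it had not been identified — whereas an identity proposed for a
single band is eliminated.  Age-specific portion sizes and serving
frequencies are maintained: each band keeps its own recommended frequency
when the CFR was in its original set; a newly added CFR receives a frequency
derived from that band's own best diet by the shared rounding rule.  A band
whose complementary-energy budget cannot absorb the consolidated servings is
reported NF (not feasible), never silently relaxed.  No consolidation is
attempted across livelihood groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cfr import _label_portion, _label_servings, recommended_servings
from .model import CFR, CFRSetResult, DietSolution, ModelParameters

Identity = tuple[str, str]  # (level, target_id)


def consolidate_identities(
    sets_by_age: Mapping[str, Sequence[CFR]],
) -> list[Identity]:
    """Identities appearing in at least 2 of the 3 age-band sets.

    Order-invariant in the bands (multiplicity counting over de-duplicated
    per-band identity sets); output sorted lexicographically.
    """
    if len(sets_by_age) != 3:
        raise ValueError(f"expected exactly 3 age-band sets, got {len(sets_by_age)}")
    counts: Counter[Identity] = Counter()
    for cfr_set in sets_by_age.values():
        counts.update({c.identity for c in cfr_set})
    return sorted(ident for ident, k in counts.items() if k >= 2)


@dataclass
class BandOutcome:
    """Consolidated-set evaluation for one age band."""

    age_band: str
    applied: list[CFR]
    not_applicable: list[Identity]  # label absent from this band's food system
    newly_added: list[Identity]  # frequency derived from the band's best diet
    result: Optional[CFRSetResult]
    age_specific_n_adequate: Optional[int]

    @property
    def feasible(self) -> bool:
        return self.result is not None and self.result.feasible


@dataclass
class ConsolidationResult:
    livelihood: str
    identities: list[Identity]
    bands: dict[str, BandOutcome] = field(default_factory=dict)


def apply_consolidated(
    identities: Sequence[Identity],
    per_age_params: Mapping[str, ModelParameters],
    per_age_best_diets: Mapping[str, DietSolution],
    per_age_selected: Mapping[str, Sequence[CFR]],
    livelihood: str = "",
    adequacy_cutoff: float = 65.0,
    age_specific_n_adequate: Optional[Mapping[str, Optional[int]]] = None,
    energy_slack: float = 0.0,
) -> ConsolidationResult:
    """Apply a consolidated identity set to every age band and re-test it.

    For each band, each identity is instantiated with the band's own portion
    size and frequency; identities whose label is absent from a band's food
    system are flagged not-applicable for that band.  The set is then
    evaluated in worst-case mode; an infeasible band is reported NF and its
    adequacy count compared against the band's age-specific result.
    """
    from .cfr import evaluate_cfr_set

    out = ConsolidationResult(livelihood=livelihood, identities=sorted(identities))
    for band, params in per_age_params.items():
        own = {c.identity: c for c in per_age_selected.get(band, [])}
        best = per_age_best_diets[band]
        applied: list[CFR] = []
        not_applicable: list[Identity] = []
        newly_added: list[Identity] = []
        for ident in out.identities:
            level, label = ident
            bounds = params.group_bounds if level == "group" else params.subgroup_bounds
            if label not in bounds:
                not_applicable.append(ident)
                continue
            if ident in own:
                freq = own[ident].servings_per_week
            else:
                newly_added.append(ident)
                servings = _label_servings(best.servings, params, level, label)
                freq = recommended_servings(servings, bounds[label][1])
            applied.append(
                CFR(level, label, freq, _label_portion(params, level, label))
            )
        result = evaluate_cfr_set(applied, params, adequacy_cutoff,
                                  energy_slack=energy_slack)
        out.bands[band] = BandOutcome(
            age_band=band,
            applied=applied,
            not_applicable=not_applicable,
            newly_added=newly_added,
            result=result,
            age_specific_n_adequate=(
                age_specific_n_adequate.get(band)
                if age_specific_n_adequate is not None else None
            ),
        )
    return out
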