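# Methods

## The model

Diets are modelled per *target group* — an age band (6–8, 9–11, 12–23
months) crossed with a livelihood stratum — on a 7-day horizon. The decision
variables are continuous servings/week per food; breast milk is a fixed
constant, never a variable. Every modelled diet satisfies:

1. **Energy equality.** Complementary-food energy plus breast-milk energy
   equals 7 × the group's daily energy requirement. Breast-milk intake is an
   assumption, not a measurement: it supplies 67 / 55 / 39 % of the energy
   requirement by age band, equivalent to 570 / 520 / 420 g/day at
   0.66 kcal/g (2.76 kJ/g; kcal↔kJ uses 4.184 exactly, and kJ appears only
   at presentation — all internal arithmetic is kcal).
2. **Item bounds.** Each food's weekly grams lie between the 10th and 90th
   percentiles of the per-child distribution of daily grams × 7.
3. **Group/subgroup bounds.** Weekly servings per food group and subgroup
   (grams ÷ the food's median consumer portion) lie between the same
   percentiles of the per-child distribution.

Two optimization modes share this polytope:

- **Nutritionally best diet.** The published description of the software
  this emulates names but does not print its goal-programming objective, so
  the objective here is an explicit design choice: maximize
  Σₙ min(1, intakeₙ/RNIₙ) over the eleven target micronutrients (Ca, Fe, Zn,
  riboflavin, niacin, thiamin, folate, vitamins A, B6, B12, C), linearized
  with capped auxiliaries zₙ ∈ [0,1], zₙ ≤ intakeₙ/RNIₙ. This rewards
  adequacy on every nutrient without crediting surpluses. Downstream
  decision rules (problem-nutrient classification, CFR rules) depend only on
  whether nutrients reach their caps, which is robust to monotone
  reweighting of this objective. A second lexicographic pass holds the
  optimum and minimizes total absolute deviation of group servings from the
  observed medians, so reported diets are deterministic and resemble
  observed food patterns.
- **Per-nutrient extremes (worst-case analyses).** For one nutrient,
  minimize (or maximize) its intake over the same polytope, one LP per
  nutrient. Minimized diets define population-level adequacy: a nutrient is
  adequate under a recommendation set if even its minimized 7-day diet
  reaches ≥65 % of the RNI (inclusive).

All LPs are solved with HiGHS through `scipy.optimize.linprog` behind a
single pluggable solver interface; instances can be exported as CPLEX-LP
text for debugging. HiGHS is deterministic for a fixed instance, and report
serialization sorts keys and rounds floats, so a rerun from the same inputs
is byte-identical.

## Decision thresholds (defaults, % of RNI unless stated)

| parameter | default | role |
|---|---|---|
| `rni_cutoff` | 100 | problem-nutrient boundary; strict `<` (exactly 100.0 is not a problem) |
| `adequacy_cutoff` | 65 | minimized-diet adequacy; inclusive `≥` |
| `source_share` | 5 | best-source share threshold per nutrient |
| `source_min_nutrients` | 5 | nutrients needed to flag a subgroup |
| `p_lo`, `p_hi` | 10, 90 | percentiles for weekly bounds (linear interpolation between order statistics; configurable) |
| `keep_k` | 8 | candidates kept after screening |
| `max_set_size` | 5 | largest CFR combination tested |
| `energy_slack` | 0 | relative slack on the energy equality (exact by default; infeasibility is reported, never silently relaxed) |

Problem-nutrient classes are exhaustive and mutually exclusive: *absolute*
(best diet < cutoff and own maximized diet < cutoff), *partial* (best <
cutoff ≤ maximized), *none* (best ≥ cutoff). Zn and Fe bioavailability
levels (15 % / 5 %) are labels that record which RNI column the config
supplies — they are never applied as multipliers.

## Recall processing choices

- Serving sizes are median portions among *consumers* (per-child grams
  summed within the recall day first); bound distributions include
  non-consumers as zeros (a config switch restricts them to consumers), so
  rarely eaten foods get a genuinely attainable zero floor.
- A food reported by a single child stays in the model with bounds
  (0, 7 × its observed grams) rather than a degenerate percentile bound.
- One 24h recall per child is assumed; multi-day recalls are averaged per
  child before the ×7 scaling.
- Missing composition values load as zeros with a logged count — the LP must
  be conservative about nutrient credit, so nothing is imputed.

## The CFR pipeline

Candidates arise two ways: *pattern rule* — food groups whose best-diet
servings strictly exceed the observed median; *source rule* — subgroups
contributing ≥5 % of ≥5 micronutrients in the best diet (breast milk is
tracked as its own subgroup but never becomes a recommendation). When a
flagged subgroup's parent group also fires, the subgroup wins. A candidate's
recommended servings/week are frozen at generation time: best-diet servings
rounded half-up to an integer, clamped to [1, the label's upper serving
bound]; they are not re-optimized per subset, which keeps the search space
finite and the recommendations stable.

Screening evaluates each candidate alone (eleven minimized diets), keeps the
union of the top-2 candidates per nutrient, and truncates to `keep_k` by
total worst-case adequacy. The systematic search then evaluates **every**
non-empty combination up to `max_set_size` and ranks by: adequate-nutrient
count (desc; NF sets last), set size (asc — parsimony), summed minimized
%RNI (desc), minimum diet cost (asc, only when a price table is supplied;
otherwise skipped with a log note), and lexicographic identity order. The
ranking beyond the first two keys is a repository decision; infeasible
subsets are retained and flagged NF rather than dropped. CFR enter the LP as
lower bounds (≥), not equalities: a minimized diet sits on the bound anyway,
so worst-case results are identical while feasibility is maximal.

## Consolidation

Identities (a group/subgroup label) selected for ≥2 of the 3 age bands are
kept and applied to all bands; single-band identities are eliminated. Each
band keeps its own portion sizes and its own frequency when the CFR was in
its set; a newly added CFR receives a frequency derived from the receiving
band's *own* best diet by the same rounding rule (the source is flagged in
the output). Identities absent from a band's food system are marked
not-applicable. Bands where the consolidated servings exceed the
complementary-energy budget are reported NF. No consolidation is attempted
across livelihoods.

One property deserves care: the age-specific search optimum upper-bounds the
consolidated result *only when* the consolidated identities all lie in that
band's screened candidate pool and fit the size cap — then the search
provably evaluated exactly that set (frozen frequencies included). The 2-of-3
rule can inject an identity a band never generated itself, and such a set can
legitimately beat the band's own searched optimum; the test suite asserts the
bound on its valid domain.

## The synthetic study

The generator emulates the survey the analysis assumes: 9 target groups ×
95 children (configurable down to n = 10 for fast property tests), one 24h
recall per child, a 25-food catalog over 8 groups (dairy, grains, starchy
plants, legumes, fats/oils incl. added sugar, vegetables, fruit, meat) with
per-livelihood availability, skewed consumption probabilities, and lognormal
portions (dispersion σ = 0.4, consistent with a portion SD near 50 % of the
mean). Energy requirements default to 615 / 686 / 894 kcal/day by band; RNIs
are FAO/WHO-2004-like placeholder values (Fe at the 5 %, Zn at the 15 %
bioavailability column); the breast-milk composition vector is a documented
synthetic placeholder resembling mature human milk. Portion medians are
calibrated per (band, livelihood) so a child's expected complementary energy
matches the band's budget; each child's grams are then rescaled to the
budget × lognormal noise (σ = 0.12). Generated diets are dominated by
dairy + grains + fats/sugar (≥75 % of complementary energy, typically
78–91 %).

Planted truth is constructed, not tuned:

- **Gaps** (default iron, zinc): under the energy equality, any diet's
  intake of nutrient *n* is bounded by budget × max_f(d_{nf}/e_f) plus the
  breast-milk term, so each food's gap density is capped at
  (0.85 × RNI − breast-milk) × e_f / budget, minimized over bands. Even the
  maximized diet then stays below the RNI in every group — the nutrient is
  an absolute problem by construction.
- **Fixes** (default beans←folate, animal-milk←vitamin B12): the subgroup's
  density for the planted nutrient is raised to ≥3× the rest-of-system mean;
  fix subgroups are deliberately multi-nutrient-dense in the catalog so the
  ≥5 %/≥5-nutrient flag fires wherever they are available.
- **Unique winning CFR** (animal milk): vitamin B12 is carried almost
  exclusively by animal milk (breast milk supplies ~40 % of the infant RNI,
  meat is rare with tiny bounds). Milk consumption probabilities keep >10 %
  of children non-consumers, so the dairy floor is zero and the baseline
  minimized B12 sits below the adequacy cutoff; any recommended weekly level
  of milk lifts it above. Every top-ranked CFR set must therefore contain
  the animal-milk recommendation.

A single seeded generator with named substreams per stage makes the whole
study byte-reproducible; truth.json records the expectations for tests.

**What passing tests do and do not show.** The synthetic data share the
survey's *structure* (sampling design, portion skew, staple dominance,
planted scarcities) but not its food list, composition values, or reported
numbers — none of which are public. Green tests demonstrate that the
pipeline recovers known structure and that its optimization logic is exact
against brute-force enumeration; they do not certify the original study's
numeric tables, nor real-world nutrient adequacy.

## Problem sizes

Unit and property tests run on toy instances (≤4 foods, checked against
0.01-serving grid enumeration with an error bound that accounts for the
energy-substitution slope) and on small studies (one livelihood, 10–20
children). End-to-end checks use the default 9 × 95 study; determinism and
the 20-study consolidation sweep use one-livelihood studies with
keep_k = 5, max_set_size = 4. The full default study (≈2,500 LPs of ~25
variables) runs in under half a minute on one CPU.

## Known limitations

- Niacin is classified like every other nutrient; tryptophan→niacin
  conversion is not modelled (a config flag annotates reports accordingly).
- No usual-intake modelling (within-person variance), no recipe
  disaggregation, no retention/yield factors, no seasonality.
- Best-source shares use raw diet content, not content capped at 100 % RNI.
- Diet cost is only a tie-break hook; no price data are bundled.
- The Module-II-style objective is a documented stand-in for unpublished
  goal-programming weights (see above).
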