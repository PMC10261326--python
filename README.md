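# cfrlp — complementary feeding recommendations by linear programming

`cfrlp` is a diet-optimization pipeline for nutritionists and epidemiologists
working on infant-and-young-child (IYC) feeding. Given a food-composition
table, single 24-hour dietary recalls, and a study configuration (energy
requirements, breast-milk assumptions, FAO/WHO recommended nutrient intakes),
it answers three questions for each *target group* (an age band × livelihood
stratum):

1. **Which nutrients are problem nutrients?** Diets are modelled over 7 days
   with servings/week per food as continuous decision variables, subject to
   an energy equality and observed-pattern constraints (weekly item gram
   bounds and group/subgroup serving bounds at the 10th/90th percentiles of
   the recalls ×7). A nutrient is an *absolute* problem if it stays below
   100 % RNI even in the diet that maximizes it, and a *partial* problem if
   it is below 100 % in the nutritionally best diet but reachable on its own.
2. **Which food-based recommendations help most?** Candidate complementary
   feeding recommendations (CFR) — promoted weekly consumption levels of a
   food group or subgroup — come from food-group patterns modelled above the
   observed median and from subgroups supplying ≥5 % of ≥5 micronutrients in
   the best diet. Every combination of the screened candidates is tested in
   worst-case mode: a nutrient is population-adequate under a CFR set if its
   *minimized* 7-day diet still reaches ≥65 % RNI.
3. **Can recommendations be unified across ages?** CFR selected for at least
   two of the three age bands are consolidated and re-tested per band with
   age-specific portions and frequencies; bands whose energy budget cannot
   absorb the consolidated servings are reported NF (not feasible).

The core model, for target group with daily energy requirement $E$ and fixed
breast-milk intake $B$ grams/day at 0.66 kcal/g:

$$\max_{s \ge 0} \sum_{n} z_n,\quad z_n \le \frac{\text{intake}_n(s)}{\text{RNI}_n},\; z_n \le 1$$

subject to $\sum_f s_f\,p_f\,e_f/100 + 7 B \cdot 0.66 = 7E$ (energy
equality), $s_f\,p_f \in [\text{P10}, \text{P90}]$ weekly grams per food, and
P10–P90 serving bounds per food group/subgroup, where $p_f$ is the median
consumer portion (g/serving) and $e_f$, $d_{nf}$ are densities per 100 g.
Worst-case analyses minimize $\text{intake}_n(s)$ over the same polytope,
optionally with CFR lower bounds $\sum_{f \in G} s_f \ge r_G$. All LPs are
solved with HiGHS (via `scipy.optimize.linprog`).

Because the underlying survey data are not public, the package ships a
synthetic-data generator (`cfrlp.synthetic`) that emulates the survey design
— 9 target groups × 95 children, milk/grain/fat/sugar-dominated diets,
lognormal portions — with *planted ground truth* (nutrients made scarce,
subgroups made rich) so every stage can be validated end to end.

## Worked example

```bash
python analysis/01_simulate.py            # synthetic survey -> data/synthetic/
python analysis/03_problem_nutrients.py   # Module II/III classification
python analysis/04_cfr_search.py          # candidate CFR + exhaustive search
python analysis/05_consolidate.py         # 2-of-3 consolidation
```

`04_cfr_search.py` prints, for the default seed:

```
group                        set adequate  members
settled_m6_8                   3     8/11  vegetables, animal_milk, beans
settled_m9_11                  2     8/11  animal_milk, beans
pastoralist_m12_23             4     9/11  animal_milk, beans, red_meat, whole_grains
agro_pastoralist_m12_23        3     9/11  animal_milk, beans, whole_grains
...
```

Each row is one target group's best CFR set: its size, the number of the
eleven modelled micronutrients whose minimized 7-day diet reaches ≥65 % RNI
under the set, and the recommended groups/subgroups. The planted iron and
zinc gaps stay inadequate in every group — by construction no energy-feasible
diet can reach their RNIs — which is why counts top out below 11.
`05_consolidate.py` then shows where a unified message across age bands costs
adequacy relative to age-specific sets (e.g. settled 6–8 months: 7 vs 8).

The same pipeline runs on real inputs via the CLI:

```bash
cfrlp run --config study.yaml --composition composition.csv \
          --recalls recalls.csv --out results/
```

## Layout

- `src/cfrlp/` — library: `io` (CSV/YAML), `recall` (parameters from
  recalls), `lp` (diet LPs), `nutrients` (classification, best sources),
  `cfr` (candidates, screening, systematic search), `consolidate` (2-of-3
  rule), `synthetic` (generator + ground truth), `report`/`cli`
  (orchestration, tables, command line).
- `analysis/` — numbered narrative drivers reproducing the study flow.
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices, limitations.
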