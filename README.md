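# fiveaday

Diet-modeling pipeline for the UK "5-a-day" fruit-and-vegetable target:
linear-programming consumption pathways, life-table health impact
assessment, and environmental-footprint and cost accounting.

UK national-average fruit and vegetable intake (~88 g fruit + ~140 g
vegetables per person per day) falls well short of the recommended five
80-g portions (400 g/day). This package models four hypothetical
consumption pathways that close that gap and quantifies, for each, the
change in life expectancy, diet-related greenhouse-gas emissions (GHGE),
blue water footprint (WF) and diet cost. It is written for researchers in
nutritional epidemiology and food-systems modeling who want a reusable,
testable implementation of this kind of scenario analysis.

## The model

**Pathways.** Starting from a baseline diet vector *b* (g/person/day over
265 food groups), each pathway scales the intake of its eligible groups by
a common factor *s* ≥ 1, proportionate to current consumption, until the
counted fruit-and-vegetable total reaches 400 g:

> count(s) = F(s) + V(s) + min(L(s), 80)

where fruit juice and potatoes never count and legumes *L* count for at
most one 80-g portion. The four pathways differ in their eligible set:
**F&V-ALL** (all fruit + vegetables), **VEG-ALL** (vegetables only),
**F&V-UK** / **VEG-UK** (only varieties that could plausibly be grown to a
greater extent in the UK). The added fruit energy displaces sweet snacks
and the added vegetable energy displaces meat (red, processed, poultry) on
a per-kilocalorie basis; total dietary energy is constrained to its
baseline value (1744 kcal/day), and the remaining "free" foods minimize
the total relative deviation Σ|xᵢ−bᵢ|/bᵢ in a linear program (HiGHS).

**Health.** Exposure deltas Δ (fruit, vegetables, legumes, red and
processed meat) enter log-linear exposure–response relations
RR(Δ) = RR_unit^(Δ/unit) from the Global Burden of Disease study for six
outcomes (ischemic heart disease, ischemic stroke, type 2 diabetes,
colorectal, lung and esophageal cancer); multiple exposures on one disease
multiply. Effects phase in with S-shaped (normal-CDF) time lags — full
effect after 10 y for cardiometabolic outcomes, after 30 y for cancers with
no change in the first 10 y. Sex-specific multi-cohort life tables convert
the adjusted mortality rates into life-years gained and the change in life
expectancy at birth, with RR 95%-CI sensitivity bounds and the share of the
gain attributable to fruit and vegetables alone.

**Accounting.** Diet GHGE, blue WF and cost are intake-weighted sums of
per-kg factors (supply-weighted across origin countries via a trade-share
table); per-capita daily deltas aggregate to national annual totals
(Mt CO2eq/y, km³/y) for a population of 66.65 million.

Because the underlying survey microdata (NDNS diaries, per-food footprint
and price tables, ONS/GBD life-table inputs) are not redistributable, the
package ships a seedable synthetic generator that reproduces the published
*structure* of those inputs — group counts, heavy-tailed intakes, the
printed top-variety intakes and all six baseline whole-diet aggregates —
so the full pipeline runs and is testable out of the box.

## Worked example

```python
import fiveaday as fa

foods = fa.generate_food_table(fa.GeneratorConfig(seed=1))
pop = fa.generate_population(fa.GeneratorConfig(seed=1))
reports, results = fa.run_all_pathways(foods, pop)
for r in reports:
    print(r.pathway, round(r.ghge_kg, 2), round(r.cost_gbp, 2),
          None if r.delta_le_months is None else round(r.delta_le_months, 1))
```

prints (seed 1):

```
baseline 6.2 6.78 None
FV_ALL 5.81 7.35 6.6
VEG_ALL 5.41 7.15 6.4
FV_UK 5.84 7.43 5.8
VEG_UK 5.63 7.24 5.5
```

i.e. every pathway cuts diet emissions below the 6.2 kg CO2eq/person/day
baseline (the vegetable-prioritizing pathways most, because they displace
more meat), costs a few percent more than the £6.78 baseline, and gains
5–7 months of life expectancy, of which 75–85% is attributable to the extra
fruit and vegetables. The `examples/` scripts walk through each stage —
input generation, optimization, health impacts, reporting — and print a
line of interpretation with their output.

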