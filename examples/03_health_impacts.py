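"""Life-table health impacts of one pathway, with CI sensitivity bounds.

Converts the F&V-ALL dietary deltas into lagged relative risks, runs the
sex-specific life tables, and reports life expectancy gained, the share
attributable to fruit and vegetables, and the RR-CI sensitivity range.
"""

import fiveaday as fa

foods = fa.generate_food_table(fa.GeneratorConfig(seed=1))
pop = fa.generate_population(fa.GeneratorConfig(seed=1))
base = fa.baseline_diet(foods)

res = fa.build_and_solve_lp(base, foods, fa.PATHWAYS["FV_ALL"])
deltas = fa.delta_exposures(base, res.diet, foods)
print("exposure deltas (g/person/day):",
      {k: round(v, 1) for k, v in deltas.items()})

impact = fa.health_impact(deltas, pop)
print(f"baseline life expectancy at birth: "
      f"{impact.baseline_le_years['combined']:.1f} y")
print(f"change in life expectancy: {impact.delta_le_months['combined']:.1f} months")
print(f"life-years gained over {len(impact.life_years_gained_by_year)} y: "
      f"{impact.total_life_years_gained / 1e6:.1f} million person-years")

att = fa.attribution_fv(deltas, pop)
print(f"share attributable to fruit & vegetables: {100 * att:.0f}%")

sens = fa.sensitivity_bounds(deltas, pop)
lo, hi = sens["low"], sens["high"]
print(f"RR 95% CI sensitivity: {hi.delta_le_months['combined']:.1f} to "
      f"{lo.delta_le_months['combined']:.1f} months")
# A positive change of several months with ~80% attributed to fruit and
# vegetables; the 'low' RR scenario (stronger protection) bounds the gain
# from above, the 'high' scenario from below.
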