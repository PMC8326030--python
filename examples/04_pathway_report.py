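"""Full cross-pathway comparison table: footprints, cost, health, national scale.

Runs all four pathways end to end and renders the comparison table with
per-capita daily values, percent changes, national annual footprint deltas
(66.65 M population, 365-day year) and life-expectancy changes.
"""

import fiveaday as fa

foods = fa.generate_food_table(fa.GeneratorConfig(seed=1))
pop = fa.generate_population(fa.GeneratorConfig(seed=1))

reports, results = fa.run_all_pathways(foods, pop)

cols = ("pathway", "ghge_kg", "blue_wf_l", "cost_gbp",
        "national_ghge_mt_per_y", "delta_le_months", "attribution_fv_pct")
hdr = f"{'pathway':9s} {'kgCO2e/d':>9s} {'WF L/d':>8s} {'GBP/d':>6s} " \
      f"{'Mt/y':>7s} {'dLE mo':>7s} {'%F&V':>5s}"
print(hdr)
for r in reports:
    le = f"{r.delta_le_months:7.1f}" if r.delta_le_months is not None else "     NA"
    at = f"{r.attribution_fv_pct:5.0f}" if r.attribution_fv_pct is not None else "   NA"
    print(f"{r.pathway:9s} {r.ghge_kg:9.2f} {r.blue_wf_l:8.1f} {r.cost_gbp:6.2f} "
          f"{r.national_ghge_mt_per_y:7.2f} {le} {at}")

with open("pathway_report.csv", "w") as fh:
    fh.write(fa.render_report(reports, fmt="csv"))
print("\nwrote pathway_report.csv")
# Every pathway cuts emissions (VEG more than F&V) at a few percent higher
# diet cost, and gains months of life expectancy, mostly from the extra
# fruit and vegetables; national deltas aggregate the per-capita values.
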