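"""Generate random exposure scenarios and summarize their dose distribution.

The generator draws task-by-season work schedules from the qualitative
ranges growers report (1-17 h/day, 3-7 d/wk), attaches taxonomy-valid
factor modifiers at random, and picks a receptor profile.  Identical seeds
give identical scenarios, and every scenario round-trips through the YAML
configuration format.
"""

import statistics

from mesodose import (
    CascadeLevel,
    GeneratorConfig,
    generate_scenario,
    grid_to_config,
    run_level,
)

grid = generate_scenario(GeneratorConfig(seed=7))
print(f"generated {len(grid.tasks)} tasks x {len(grid.seasons)} seasons, "
      f"{len(grid.schedules)} active cells, {len(grid.modifiers)} grid modifiers, "
      f"receptor '{grid.receptor.label}'")

report = run_level(grid, CascadeLevel("plus_receptor", "ingestion"))
print(f"annual ingestion total: {report.annual_total:.3e} mg/kgBW/day")

totals = []
for seed in range(50):
    g = generate_scenario(GeneratorConfig(seed=seed))
    totals.append(run_level(g, CascadeLevel("plus_receptor", "ingestion")).annual_total)
print(f"50 random scenarios -> median {statistics.median(totals):.2e}, "
      f"min {min(totals):.2e}, max {max(totals):.2e} mg/kgBW/day")
print("The spread shows how strongly schedules and factor modifiers move the")
print("annual dose even with identical baseline soil and intake parameters.")

doc = grid_to_config(grid)
print(f"\nscenario serializes to a {len(doc['schedules'])}-cell config document "
      "(see `mesodose simulate --seed 7`)")
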