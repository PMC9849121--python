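"""Run the stepwise sensitivity cascade on the shipped benchmark scenarios.

Each cascade level adds one EAT-R factor class to the dose model: task
structure (meso-activity), then seasonal timing, then environmental
soil-condition effects, then grower-specific receptor factors.  The annual
totals show how much the traditional single-cell occupational model hides.
"""

from mesodose import CascadeLevel, benchmark, compare_levels, run_cascade, run_level

grid = benchmark("model_7").runs[0].grid  # 3 tasks x 4 seasons, env modifiers
result = run_cascade(grid, "ingestion")

print("ingestion cascade (annual totals, mg/kgBW/day):")
for report in result.reports:
    cmp = result.comparisons.get(report.level.level_id)
    note = f"  ({cmp.percent_difference:+.0f}% vs traditional)" if cmp else ""
    print(f"  {report.level.level_id:<18} {report.annual_total:.3e}{note}")

print()
print("per-season breakdown at the environment level:")
env = result.report("plus_environment")
for season, subtotal in env.seasonal_subtotals.items():
    print(f"  {season:<8} {subtotal:.3e}")

print()
grower_a = run_level(benchmark("grower_A").runs[1].grid, CascadeLevel("plus_receptor", "dermal"))
grower_b = run_level(benchmark("grower_B").runs[1].grid, CascadeLevel("plus_receptor", "dermal"))
gap = compare_levels(grower_b, grower_a)
print(f"dermal, Grower A (rarely gloved, lighter): {grower_a.annual_total:.2e} mg/kgBW/day")
print(f"dermal, Grower B (mechanized, gloved)    : {grower_b.annual_total:.2e} mg/kgBW/day")
print(f"-> receptor behavior alone separates the growers by {gap.magnitude_gap} orders of magnitude")
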