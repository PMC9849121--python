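# Methods

## Dose models

Both pathway models are deterministic exposure-factor products in the style
of standard contaminated-land risk guidance, evaluated per (task, season)
cell and averaged over one year.

**Ingestion.** `ADD = C · IR · EF / BW`. The exposure factor is the triple
product of calendar fractions `(h/24)·(d/7)·(wk/52)` from an explicit work
schedule; it is dimensionless, bounded in [0, 1] by the schedule invariants
(0–24 h/day, 0–7 d/wk, 0–52 wk/yr), and monotone in each schedule field.
Concentration is carried as mg contaminant per mg soil so the product is
directly mg/kgBW/day.

**Dermal.** The per-event absorbed dose `DA_event = C · CF · AF · ABS` is
scaled by exposed surface area, exposure frequency, exposure duration and
event frequency and divided by body weight times averaging time. The
equation deliberately carries frequency, duration *and* event frequency as
distinct terms; the unit convention that makes this dimensionally coherent
— `EFreq` in days/yr, `ED` in years, `EV` in events/day, `AT` in days — is
a documented package convention. Concentration stays in mg/kg with an
explicit kg/mg conversion factor rather than being silently pre-converted,
because the conversion term is a named symbol in the worksheets
practitioners use.

All parameter sets are validated pydantic models: negative values, zero
body weight or averaging time, and exposure or absorption fractions outside
[0, 1] are rejected at construction, so the dose arithmetic itself can
never divide by zero or produce a negative dose. Cells absent from a
grid's schedule list are true zero-exposure cells (exposure factor /
frequency zero), not missing values.

## The EAT-R modifier system

Ten qualitative factors in four classes (environmental: natural,
social/built; activity: crop type, growing practices, ergonomic
positioning; timing: season, day of week, time of day; receptor:
behavioral, biological) may each modify only a fixed set of quantitative
inputs — e.g. the natural environment may scale the intake rate or the
soil-to-skin adherence factor, while social/built conditions may only move
the exposure factor. No empirical magnitudes exist for these effects, so
modifiers carry user-supplied values (`multiply` or `override`) and the
factor→target mapping is enforced as a validation rule, never as a lookup
of magnitudes.

Resolution of a cell applies modifier classes in the fixed order
environmental → activity → timing → receptor. Within a class,
multiplications compose commutatively and an override applies after them;
at most one override per parameter per cell is allowed (a second is a
configuration error). Cross-factor interactions are representable only as
explicit per-cell modifiers — there is no automatic interaction algebra,
because no defensible one exists. A receptor profile's body weight
replaces the baseline body weight whenever the receptor class is active;
modifiers attached to a profile must be receptor-class. Resolution never
mutates the baseline and fails loudly (validation error) if a modified
parameter leaves its invariant range, e.g. an exposure factor pushed above 1.

Modifiers targeting a parameter the current pathway does not use (e.g.
adherence factor during ingestion resolution) are inert for that pathway,
mirroring how the factor table marks ingestion-only and dermal-only inputs.

## The sensitivity cascade

Five nested levels per pathway: *traditional* (single annual cell from the
baseline parameters, ignoring all task/season structure), *meso_activity*
(per-cell doses, activity-class modifiers), *plus_timing*, *plus_environment*
and *plus_receptor* (all classes; requires a receptor profile). Level k
differs from level k−1 exactly by one modifier class, so dropping the top
class reproduces the lower level bit-for-bit — a tested invariant.
Seasonal subtotals are exact sums of cells, the annual total an exact sum
of subtotals; rounding to three significant figures happens only at the
reporting surface, with a full-precision column serialized alongside.

Two reports are compared by percent difference `(A−B)/B·100`, ratio `A/B`
and order-of-magnitude gap `round(log10(A/B))`. Comparisons against a zero
total are flagged undefined in-band rather than raised or returned as
infinities, keeping reports serializable.

## Benchmark scenarios and inferred parameters

The shipped benchmarks (`model_1` … `model_10`, `grower_A`, `grower_B`)
encode the ten-model demonstration of the framework: three tasks across
four seasons, ingestion and dermal pathways, and two contrasting growers.
The published record prints the per-cell doses but not the underlying
parameter sets, so the benchmarks treat the printed doses as authoritative
expectations and carry an inferred, non-authoritative parameterization
chosen once to be mutually consistent with them:

| parameter | value | basis |
|---|---|---|
| body weight | 80 kg (baseline); 60 / 90 kg for Growers A / B | typical adult defaults |
| soil intake rate | 100 mg/day | occupational soil-ingestion default |
| soil concentration | ≈ 213 mg/kg | back-derived so the self-consistent 10 h/6 d/50 wk schedule (EF 0.343) reproduces the published modified-schedule dose |
| adherence factor | 0.07 mg/cm²·event, overridden to 0.2 in spring/fall | published default and wet-season value |
| absorption fraction | 0.001 | inorganic-contaminant order of magnitude |
| exposed skin | 990 cm² (both hands) | anthropometric default |
| dermal frequency | 250 days/yr (5 d/wk × 50 wk); 312 for the modified schedule | schedule arithmetic |
| averaging time | 365 days, duration 1 yr, 1 event/day | annual averaging throughout |

Per-cell exposure factors and frequencies, the seasonal intake-rate
multipliers and the per-cell receptor modifiers are back-fitted from the
printed cells (the published schedules do not pin them down otherwise), so
the cascade machinery genuinely recomputes the published tables rather than
replaying them. Supporting this inference, the back-fitted dermal
frequencies land on near-round day counts (120/60/108 and 36 days/yr).

Two printed inconsistencies are handled deliberately: the published base
schedule is stated to yield an exposure factor of 0.16 although the triple
product of its printed fractions is 0.229 — the baseline EF is therefore
carried as a back-fitted free parameter (0.165) and no agreement is forced;
and one grower dermal annual total is printed as 8.02×10⁻⁹ although its own
cells (and the accompanying prose) give 8.20×10⁻⁹ — the cell-sum value is
used. Regression tests compare at ≤2 % to absorb three-significant-figure
printed rounding; internal arithmetic is full precision.

## Scenario generation

The generator emulates the study conditions the framework describes rather
than any measured distribution: work schedules drawn uniformly from the
qualitative ranges growers reported (1–17 h/day, 3–7 d/wk) with up to a
13-week season of work per cell, each cell present with probability 0.85
(absences model tasks not done in a season), each factor present as a
multiplicative modifier with probability 0.25 and magnitude uniform in
[0.5, 2.0] — capped at [0.5, 1.2] for factors that may scale the exposure
factor, so a full stack of them cannot push any cell's exposure factor
above 1 — and a receptor drawn from a two-profile pool. One seeded NumPy
stream per grid with a fixed draw order (draws occur even for entries that
are then discarded) makes output identical across platforms and stable
under config extension.

Generated grids use the inferred baseline parameters above, always pass
modifier validation, resolve at every cascade level, and round-trip through
the YAML/JSON configuration format — all tested properties. What passing
these tests does *not* show: real schedules are not uniform or independent
across cells, factor effects are not independent multiplicative
perturbations, and real receptors correlate behavior across tasks; the
generator is a coverage tool for the machinery, not an empirical exposure
population.

## Numerical and design choices

* Display rounding: three significant figures, matching the published
  tables; full precision in all computation and in the
  `dose_full_precision` report column (round-trips via `repr`).
* Aggregation is plain left-to-right summation in grid season order;
  bit-identical reproducibility is tested against a brute-force double loop.
* The magnitude gap uses round-half-even only in the degenerate exact-half
  case (Python `round`); ratios of zero give an undefined gap.
* Receptor attire/PPE effects on dermal exposure are encoded as biological
  surface-area multipliers (the behavioral factor's permitted targets are
  intake rate and adherence factor); produce-sampling and equipment effects
  on ingestion as behavioral intake-rate multipliers.
* Cascade runs are labelled by level id and pathway; the demonstration's
  "sensitivity analysis" numbering conflates base and modified runs and is
  exposed only as the model-number mapping on `CascadeLevel`.
* CLI exit codes 0/1/2/3 (ok/usage/validation/regression) so pipelines can
  distinguish misuse from bad configs from genuine regressions.

## Known limitations

* Absolute doses depend on the inferred baseline; only the printed doses,
  their ratios and the structural invariants are authoritative.
* The inhalation pathway, toxicity/risk characterization (hazard quotients,
  slope factors) and probabilistic uncertainty propagation are out of scope.
* Factor magnitudes are user judgments; the package validates where a
  factor may act, not how strongly it does.
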