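"""Benchmark exposure scenarios from the ten-model framework demonstration.

The demonstration study reports per-cell average daily doses for a
hypothetical Maryland vegetable operation — three tasks (transplanting,
harvesting, watering) across four seasons, two pathways, and two hypothetical
growers — but its full input parameter sets live in supplementary tables that
are not part of the published record.  These benchmarks therefore encode the
*printed* per-cell doses as the authoritative expectations and carry an
inferred, non-authoritative parameterization constructed to be mutually
consistent with them:

* Ingestion baseline: body weight 80 kg, soil intake 100 mg/day, and a soil
  concentration back-derived so that the self-consistent modified work
  schedule (10 h/day, 6 d/wk, 50 wk/yr; exposure factor 0.343) reproduces
  the published modified-schedule dose of 9.13e-5 mg/kgBW/day.
* Dermal baseline: the same soil concentration, adherence 0.07 mg/cm^2-event,
  absorption fraction 0.001, 990 cm^2 of exposed skin (hands), one event per
  day over one year averaged over 365 days, 250 exposure days/yr
  (5 d/wk x 50 wk).  The per-cell exposure frequencies this implies land on
  near-round day counts (120/60/108 d/yr for the three tasks), supporting
  the inference.
* Per-cell exposure factors / frequencies and the environment and receptor
  modifier magnitudes are back-fitted from the printed cells, so running the
  cascade recomputes the published tables through the real machinery.

Grower A is a female grower in her 20s (60 kg here) who rarely wears gloves
and sometimes works in sandals; Grower B a male grower in his 40s (90 kg)
who mechanizes heavily and always wears gloves.  Their attire and equipment
effects are encoded as receptor-class modifiers (biological surface-area
multipliers for dermal exposure, behavioral intake-rate multipliers for
ingestion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .dose import DermalParameters, ExposureSchedule, IngestionParameters, exposure_factor
from .scenario import CellExposure, FactorModifier, ReceptorProfile, ScenarioGrid

__all__ = ["Benchmark", "BenchmarkRun", "ExpectedReport", "benchmark", "BENCHMARK_NAMES"]

TASKS = ("transplanting", "harvesting", "watering")
SEASONS = ("spring", "summer", "fall", "winter")

# ---------------------------------------------------------------------------
# published values (mg/kgBW/day unless noted)

ING_TRADITIONAL = 4.38e-5
ING_MODIFIED_SCHEDULE = 9.13e-5
DERM_TRADITIONAL = 1.26e-7
DERM_MODIFIED_SCHEDULE = 1.58e-7

MODIFIED_SCHEDULE = ExposureSchedule(hours_per_day=10, days_per_week=6, weeks_per_year=50)

ING_MESO = {"transplanting": 2.92e-5, "harvesting": 1.83e-5, "watering": 3.29e-6}
ING_MESO_TOTAL = 5.08e-5
DERM_MESO = {"transplanting": 6.06e-8, "harvesting": 3.03e-8, "watering": 5.45e-8}
DERM_MESO_TOTAL = 1.45e-7

ING_TIMING = {
    ("transplanting", "spring"): 1.46e-5,
    ("harvesting", "spring"): 1.83e-5,
    ("watering", "spring"): 1.10e-6,
    ("transplanting", "summer"): 1.46e-5,
    ("harvesting", "summer"): 1.83e-5,
    ("watering", "summer"): 1.10e-6,
    ("harvesting", "fall"): 1.83e-5,
    ("watering", "fall"): 1.10e-6,
}
ING_TIMING_SUBTOTALS = {"spring": 3.40e-5, "summer": 3.40e-5, "fall": 1.94e-5, "winter": 0.0}
ING_TIMING_TOTAL = 8.73e-5

ING_ENV = {
    ("transplanting", "spring"): 2.19e-5,
    ("harvesting", "spring"): 2.74e-5,
    ("watering", "spring"): 3.29e-7,
    ("transplanting", "summer"): 2.92e-5,
    ("harvesting", "summer"): 3.65e-5,
    ("watering", "summer"): 2.91e-6,
    ("harvesting", "fall"): 1.83e-5,
    ("watering", "fall"): 1.10e-6,
}
ING_ENV_SUBTOTALS = {"spring": 4.96e-5, "summer": 6.80e-5, "fall": 1.94e-5, "winter": 0.0}
ING_ENV_TOTAL = 1.37e-4

DERM_TIMING = {
    ("transplanting", "spring"): 3.03e-8,
    ("harvesting", "spring"): 3.03e-8,
    ("watering", "spring"): 1.82e-8,
    ("transplanting", "summer"): 3.03e-8,
    ("harvesting", "summer"): 3.03e-8,
    ("watering", "summer"): 1.82e-8,
    ("harvesting", "fall"): 1.82e-8,
    ("watering", "fall"): 1.82e-8,
}
DERM_TIMING_SUBTOTALS = {"spring": 7.88e-8, "summer": 7.88e-8, "fall": 3.64e-8, "winter": 0.0}
DERM_TIMING_TOTAL = 1.94e-7

#: Seasonal soil-moisture adjustment of the soil-to-skin adherence factor.
ADHERENCE_DEFAULT = 0.07
ADHERENCE_WET_SEASON = 0.2
WET_SEASONS = ("spring", "fall")

DERM_ENV = {
    ("transplanting", "spring"): 8.66e-8,
    ("harvesting", "spring"): 8.66e-8,
    ("watering", "spring"): 5.19e-8,
    ("transplanting", "summer"): 3.03e-8,
    ("harvesting", "summer"): 3.03e-8,
    ("watering", "summer"): 1.82e-8,
    ("harvesting", "fall"): 5.19e-8,
    ("watering", "fall"): 5.19e-8,
}
DERM_ENV_SUBTOTALS = {"spring": 2.25e-7, "summer": 7.88e-8, "fall": 1.04e-7, "winter": 0.0}
DERM_ENV_TOTAL = 4.08e-7

GROWER_A_ING = {
    ("transplanting", "spring"): 2.43e-5,
    ("harvesting", "spring"): 3.03e-5,
    ("watering", "spring"): 3.64e-7,
    ("transplanting", "summer"): 3.24e-5,
    ("harvesting", "summer"): 6.47e-5,
    ("watering", "summer"): 1.21e-7,
    ("harvesting", "fall"): 2.02e-5,
    ("watering", "fall"): 1.21e-6,
}
GROWER_A_ING_SUBTOTALS = {"spring": 5.50e-5, "summer": 9.72e-5, "fall": 2.14e-5, "winter": 0.0}
GROWER_A_ING_TOTAL = 1.74e-4

GROWER_B_ING = {
    ("transplanting", "spring"): 8.80e-6,
    ("harvesting", "spring"): 1.10e-5,
    ("watering", "spring"): 2.83e-7,
    ("transplanting", "summer"): 1.51e-5,
    ("harvesting", "summer"): 1.89e-5,
    ("watering", "summer"): 9.43e-8,
    ("harvesting", "fall"): 1.57e-5,
    ("watering", "fall"): 9.43e-7,
}
GROWER_B_ING_SUBTOTALS = {"spring": 2.01e-5, "summer": 3.40e-5, "fall": 1.67e-5, "winter": 0.0}
GROWER_B_ING_TOTAL = 7.08e-5

GROWER_A_DERM = {
    ("transplanting", "spring"): 1.37e-9,
    ("harvesting", "spring"): 1.62e-9,
    ("watering", "spring"): 9.74e-10,
    ("transplanting", "summer"): 1.16e-9,
    ("harvesting", "summer"): 1.16e-9,
    ("watering", "summer"): 6.94e-10,
    ("harvesting", "fall"): 6.12e-10,
    ("watering", "fall"): 6.12e-10,
}
GROWER_A_DERM_SUBTOTALS = {"spring": 3.97e-9, "summer": 3.01e-9, "fall": 1.22e-9, "winter": 0.0}
# The table prints 8.02e-9 for this total, inconsistent with both its own
# cells and the prose figure of 8.2e-9; the cell-sum value is used.
GROWER_A_DERM_TOTAL = 8.20e-9

GROWER_B_DERM = {
    ("transplanting", "spring"): 8.66e-8,
    ("harvesting", "spring"): 8.66e-8,
    ("watering", "spring"): 5.19e-8,
    ("transplanting", "summer"): 2.61e-8,
    ("harvesting", "summer"): 2.61e-8,
    ("watering", "summer"): 1.56e-8,
    ("harvesting", "fall"): 4.47e-8,
    ("watering", "fall"): 4.47e-8,
}
GROWER_B_DERM_SUBTOTALS = {"spring": 2.25e-7, "summer": 6.78e-8, "fall": 8.94e-8, "winter": 0.0}
GROWER_B_DERM_TOTAL = 3.82e-7

# ---------------------------------------------------------------------------
# inferred baseline parameterization (non-authoritative; see module docstring)

BODY_WEIGHT = 80.0  # kg
INTAKE_RATE = 100.0  # mg soil / day
#: mg contaminant / mg soil, back-derived from the modified-schedule dose.
SOIL_CONCENTRATION = ING_MODIFIED_SCHEDULE * BODY_WEIGHT / (
    INTAKE_RATE * exposure_factor(MODIFIED_SCHEDULE)
)
#: dose per unit exposure factor, mg/kgBW/day.
_K_ING = SOIL_CONCENTRATION * INTAKE_RATE / BODY_WEIGHT
#: baseline occupational exposure factor implied by the traditional dose.
BASE_EXPOSURE_FACTOR = ING_TRADITIONAL / _K_ING

DERMAL_BASELINE = dict(
    concentration=SOIL_CONCENTRATION * 1e6,  # mg/kg
    conversion_factor=1e-6,  # kg/mg
    adherence_factor=ADHERENCE_DEFAULT,
    absorption_fraction=0.001,
    surface_area=990.0,  # cm^2, both hands
    exposure_frequency=250.0,  # days/yr, 5 d/wk x 50 wk
    exposure_duration=1.0,  # yr
    event_frequency=1.0,  # events/day
    body_weight=BODY_WEIGHT,
    averaging_time=365.0,  # days
)
#: dermal dose per exposure day, mg/kgBW/day per (day/yr).
_K_DERM = (
    DERMAL_BASELINE["concentration"]
    * DERMAL_BASELINE["conversion_factor"]
    * DERMAL_BASELINE["adherence_factor"]
    * DERMAL_BASELINE["absorption_fraction"]
    * DERMAL_BASELINE["surface_area"]
    / (DERMAL_BASELINE["body_weight"] * DERMAL_BASELINE["averaging_time"])
)
#: exposure frequency of the 6 d/wk x 52 wk modified dermal schedule.
DERMAL_MODIFIED_FREQUENCY = 312.0

GROWER_A_BODY_WEIGHT = 60.0
GROWER_B_BODY_WEIGHT = 90.0

# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedReport:
    """Published per-cell doses, subtotals and total for one benchmark run."""

    cells: Mapping[tuple[str, str], float]
    seasonal_subtotals: Mapping[str, float]
    annual_total: float


@dataclass(frozen=True)
class BenchmarkRun:
    """One cascade evaluation with its published expectations."""

    label: str
    grid: ScenarioGrid
    pathway: str
    level_id: str
    expected: ExpectedReport


@dataclass(frozen=True)
class Benchmark:
    name: str
    description: str
    runs: tuple[BenchmarkRun, ...]


def _ingestion_baseline(exposure_factor_value: float) -> IngestionParameters:
    return IngestionParameters(
        concentration=SOIL_CONCENTRATION,
        intake_rate=INTAKE_RATE,
        exposure_factor=exposure_factor_value,
        body_weight=BODY_WEIGHT,
    )


def _dermal_baseline(frequency: float = DERMAL_BASELINE["exposure_frequency"]) -> DermalParameters:
    return DermalParameters(**{**DERMAL_BASELINE, "exposure_frequency": frequency})


def _ing_cells(doses: Mapping[tuple[str, str], float]) -> tuple[CellExposure, ...]:
    """Back-fit per-cell exposure factors from published ingestion doses."""
    return tuple(
        CellExposure(task=task, season=season, exposure_factor=dose / _K_ING)
        for (task, season), dose in doses.items()
    )


def _derm_cells(doses: Mapping[tuple[str, str], float]) -> tuple[CellExposure, ...]:
    """Back-fit per-cell exposure frequencies from published dermal doses."""
    return tuple(
        CellExposure(task=task, season=season, exposure_frequency=dose / _K_DERM)
        for (task, season), dose in doses.items()
    )


def _dual_cells(
    ing: Mapping[tuple[str, str], float], derm: Mapping[tuple[str, str], float]
) -> tuple[CellExposure, ...]:
    return tuple(
        CellExposure(
            task=task,
            season=season,
            exposure_factor=ing[(task, season)] / _K_ING,
            exposure_frequency=derm[(task, season)] / _K_DERM,
        )
        for (task, season) in ing
    )


def _env_intake_modifiers() -> tuple[FactorModifier, ...]:
    """Seasonal soil-condition multipliers on the ingestion intake rate."""
    mods = []
    for (task, season), env_dose in ING_ENV.items():
        ratio = env_dose / ING_TIMING[(task, season)]
        if ratio != 1.0:
            mods.append(
                FactorModifier(
                    factor="natural",
                    target_parameter="intake_rate",
                    action="multiply",
                    value=ratio,
                    scope=((task, season),),
                )
            )
    return tuple(mods)


def _env_adherence_modifier() -> FactorModifier:
    """Wet-season (spring/fall) override of the soil-to-skin adherence factor."""
    return FactorModifier(
        factor="natural",
        target_parameter="adherence_factor",
        action="override",
        value=ADHERENCE_WET_SEASON,
        scope=tuple((task, season) for task in TASKS for season in WET_SEASONS),
    )


def _env_dermal_dose(task: str, season: str) -> float:
    """Dermal dose at the environment level as the machinery computes it."""
    scale = ADHERENCE_WET_SEASON / ADHERENCE_DEFAULT if season in WET_SEASONS else 1.0
    return DERM_TIMING[(task, season)] * scale


def _receptor(
    label: str,
    age_band: str,
    sex: str,
    body_weight: float,
    ing_doses: Mapping[tuple[str, str], float],
    derm_doses: Mapping[tuple[str, str], float],
) -> ReceptorProfile:
    """Back-fit per-cell receptor modifiers from the published grower doses.

    Ingestion effects (sampling produce, tractor use, ...) become behavioral
    intake-rate multipliers; dermal attire/PPE effects become biological
    surface-area multipliers.  Each multiplier is the ratio of the published
    grower cell to the environment-level cell after the body-weight change.
    """
    bw_scale = BODY_WEIGHT / body_weight
    mods: list[FactorModifier] = []
    for (task, season), dose in ing_doses.items():
        mods.append(
            FactorModifier(
                factor="behavioral",
                target_parameter="intake_rate",
                action="multiply",
                value=dose / (ING_ENV[(task, season)] * bw_scale),
                scope=((task, season),),
            )
        )
    for (task, season), dose in derm_doses.items():
        mods.append(
            FactorModifier(
                factor="biological",
                target_parameter="surface_area",
                action="multiply",
                value=dose / (_env_dermal_dose(task, season) * bw_scale),
                scope=((task, season),),
            )
        )
    return ReceptorProfile(
        label=label,
        age_band=age_band,
        sex=sex,
        body_weight=body_weight,
        modifiers=tuple(mods),
    )


def _single_cell_expected(value: float) -> ExpectedReport:
    return ExpectedReport(
        cells={("all", "annual"): value},
        seasonal_subtotals={"annual": value},
        annual_total=value,
    )


def _annual_expected(doses: Mapping[str, float], total: float) -> ExpectedReport:
    return ExpectedReport(
        cells={(task, "annual"): dose for task, dose in doses.items()},
        seasonal_subtotals={"annual": sum(doses.values())},
        annual_total=total,
    )


def _seasonal_expected(
    doses: Mapping[tuple[str, str], float],
    subtotals: Mapping[str, float],
    total: float,
) -> ExpectedReport:
    cells = {
        (task, season): doses.get((task, season), 0.0)
        for task in TASKS
        for season in SEASONS
    }
    return ExpectedReport(cells=cells, seasonal_subtotals=subtotals, annual_total=total)


def _meso_grid_ing() -> ScenarioGrid:
    return ScenarioGrid(
        tasks=TASKS,
        seasons=("annual",),
        baseline_ingestion=_ingestion_baseline(BASE_EXPOSURE_FACTOR),
        schedules=_ing_cells({(t, "annual"): d for t, d in ING_MESO.items()}),
    )


def _meso_grid_derm() -> ScenarioGrid:
    return ScenarioGrid(
        tasks=TASKS,
        seasons=("annual",),
        baseline_dermal=_dermal_baseline(),
        schedules=_derm_cells({(t, "annual"): d for t, d in DERM_MESO.items()}),
    )


def _timing_grid_ing(env: bool = False) -> ScenarioGrid:
    return ScenarioGrid(
        tasks=TASKS,
        seasons=SEASONS,
        baseline_ingestion=_ingestion_baseline(BASE_EXPOSURE_FACTOR),
        schedules=_ing_cells(ING_TIMING),
        modifiers=_env_intake_modifiers() if env else (),
    )


def _timing_grid_derm(env: bool = False) -> ScenarioGrid:
    return ScenarioGrid(
        tasks=TASKS,
        seasons=SEASONS,
        baseline_dermal=_dermal_baseline(),
        schedules=_derm_cells(DERM_TIMING),
        modifiers=(_env_adherence_modifier(),) if env else (),
    )


def _grower_grid(which: str) -> ScenarioGrid:
    if which == "A":
        receptor = _receptor(
            "grower_A", "20s", "female", GROWER_A_BODY_WEIGHT, GROWER_A_ING, GROWER_A_DERM
        )
    else:
        receptor = _receptor(
            "grower_B", "40s", "male", GROWER_B_BODY_WEIGHT, GROWER_B_ING, GROWER_B_DERM
        )
    return ScenarioGrid(
        tasks=TASKS,
        seasons=SEASONS,
        baseline_ingestion=_ingestion_baseline(BASE_EXPOSURE_FACTOR),
        baseline_dermal=_dermal_baseline(),
        schedules=_dual_cells(ING_TIMING, DERM_TIMING),
        modifiers=_env_intake_modifiers() + (_env_adherence_modifier(),),
        receptor=receptor,
    )


def _grower_runs(which: str, pathway: Optional[str]) -> tuple[BenchmarkRun, ...]:
    grid = _grower_grid(which)
    expectations = {
        ("A", "ingestion"): _seasonal_expected(
            GROWER_A_ING, GROWER_A_ING_SUBTOTALS, GROWER_A_ING_TOTAL
        ),
        ("A", "dermal"): _seasonal_expected(
            GROWER_A_DERM, GROWER_A_DERM_SUBTOTALS, GROWER_A_DERM_TOTAL
        ),
        ("B", "ingestion"): _seasonal_expected(
            GROWER_B_ING, GROWER_B_ING_SUBTOTALS, GROWER_B_ING_TOTAL
        ),
        ("B", "dermal"): _seasonal_expected(
            GROWER_B_DERM, GROWER_B_DERM_SUBTOTALS, GROWER_B_DERM_TOTAL
        ),
    }
    pathways = [pathway] if pathway else ["ingestion", "dermal"]
    return tuple(
        BenchmarkRun(
            label=f"grower_{which}/{pw}",
            grid=grid,
            pathway=pw,
            level_id="plus_receptor",
            expected=expectations[(which, pw)],
        )
        for pw in pathways
    )


def _build(name: str) -> Benchmark:
    if name == "model_1":
        return Benchmark(
            name,
            "Traditional single-cell ingestion model (occupational defaults), "
            "plus the modified 10 h/6 d/50 wk work schedule.",
            (
                BenchmarkRun(
                    "default",
                    ScenarioGrid(
                        tasks=("field_work",),
                        seasons=("annual",),
                        baseline_ingestion=_ingestion_baseline(BASE_EXPOSURE_FACTOR),
                    ),
                    "ingestion",
                    "traditional",
                    _single_cell_expected(ING_TRADITIONAL),
                ),
                BenchmarkRun(
                    "modified_schedule",
                    ScenarioGrid(
                        tasks=("field_work",),
                        seasons=("annual",),
                        baseline_ingestion=_ingestion_baseline(
                            exposure_factor(MODIFIED_SCHEDULE)
                        ),
                    ),
                    "ingestion",
                    "traditional",
                    _single_cell_expected(ING_MODIFIED_SCHEDULE),
                ),
            ),
        )
    if name == "model_2":
        return Benchmark(
            name,
            "Traditional single-cell dermal model, plus the modified "
            "6 d/wk x 52 wk exposure frequency.",
            (
                BenchmarkRun(
                    "default",
                    ScenarioGrid(
                        tasks=("field_work",),
                        seasons=("annual",),
                        baseline_dermal=_dermal_baseline(),
                    ),
                    "dermal",
                    "traditional",
                    _single_cell_expected(DERM_TRADITIONAL),
                ),
                BenchmarkRun(
                    "modified_schedule",
                    ScenarioGrid(
                        tasks=("field_work",),
                        seasons=("annual",),
                        baseline_dermal=_dermal_baseline(DERMAL_MODIFIED_FREQUENCY),
                    ),
                    "dermal",
                    "traditional",
                    _single_cell_expected(DERM_MODIFIED_SCHEDULE),
                ),
            ),
        )
    if name == "model_3":
        return Benchmark(
            name,
            "Ingestion with task-specific exposure factors (3 tasks).",
            (
                BenchmarkRun(
                    "default",
                    _meso_grid_ing(),
                    "ingestion",
                    "meso_activity",
                    _annual_expected(ING_MESO, ING_MESO_TOTAL),
                ),
            ),
        )
    if name == "model_4":
        return Benchmark(
            name,
            "Dermal with task-specific exposure frequencies (3 tasks).",
            (
                BenchmarkRun(
                    "default",
                    _meso_grid_derm(),
                    "dermal",
                    "meso_activity",
                    _annual_expected(DERM_MESO, DERM_MESO_TOTAL),
                ),
            ),
        )
    if name == "model_5":
        return Benchmark(
            name,
            "Ingestion with task-by-season schedules (3 tasks x 4 seasons).",
            (
                BenchmarkRun(
                    "default",
                    _timing_grid_ing(),
                    "ingestion",
                    "plus_timing",
                    _seasonal_expected(ING_TIMING, ING_TIMING_SUBTOTALS, ING_TIMING_TOTAL),
                ),
            ),
        )
    if name == "model_6":
        return Benchmark(
            name,
            "Dermal with task-by-season schedules (3 tasks x 4 seasons).",
            (
                BenchmarkRun(
                    "default",
                    _timing_grid_derm(),
                    "dermal",
                    "plus_timing",
                    _seasonal_expected(
                        DERM_TIMING, DERM_TIMING_SUBTOTALS, DERM_TIMING_TOTAL
                    ),
                ),
            ),
        )
    if name == "model_7":
        return Benchmark(
            name,
            "Ingestion with season-varying intake rates (soil-condition "
            "multipliers on top of the timing grid).",
            (
                BenchmarkRun(
                    "default",
                    _timing_grid_ing(env=True),
                    "ingestion",
                    "plus_environment",
                    _seasonal_expected(ING_ENV, ING_ENV_SUBTOTALS, ING_ENV_TOTAL),
                ),
            ),
        )
    if name == "model_8":
        return Benchmark(
            name,
            "Dermal with the wet-season adherence factor raised from 0.07 "
            "to 0.2 (spring and fall).",
            (
                BenchmarkRun(
                    "default",
                    _timing_grid_derm(env=True),
                    "dermal",
                    "plus_environment",
                    _seasonal_expected(DERM_ENV, DERM_ENV_SUBTOTALS, DERM_ENV_TOTAL),
                ),
            ),
        )
    if name == "model_9":
        return Benchmark(
            name,
            "Ingestion with receptor factors for two hypothetical growers.",
            _grower_runs("A", "ingestion") + _grower_runs("B", "ingestion"),
        )
    if name == "model_10":
        return Benchmark(
            name,
            "Dermal with receptor factors for two hypothetical growers.",
            _grower_runs("A", "dermal") + _grower_runs("B", "dermal"),
        )
    if name == "grower_A":
        return Benchmark(
            name,
            "Both pathways for Grower A (female, 20s, 60 kg; samples produce, "
            "rarely gloves, sandals in warm seasons).",
            _grower_runs("A", None),
        )
    if name == "grower_B":
        return Benchmark(
            name,
            "Both pathways for Grower B (male, 40s, 90 kg; mechanized "
            "equipment, gloves at all times).",
            _grower_runs("B", None),
        )
    raise KeyError(name)


BENCHMARK_NAMES: tuple[str, ...] = tuple(
    [f"model_{i}" for i in range(1, 11)] + ["grower_A", "grower_B"]
)


def benchmark(name: str) -> Benchmark:
    """Return the benchmark scenario ``name`` with its published expectations.

    ``name`` is one of ``model_1`` ... ``model_10``, ``grower_A`` or
    ``grower_B``.  Unknown names raise ``KeyError`` listing the available
    benchmarks.
    """
    if name not in BENCHMARK_NAMES:
        raise KeyError(
            f"unknown benchmark '{name}'; available: {', '.join(BENCHMARK_NAMES)}"
        )
    return _build(name)
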