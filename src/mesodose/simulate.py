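"""Seeded random scenario generation.

The study behind the framework collected qualitative schedules only —
growers reported 1–17 h of work per day and 3–7 work days per week, with
strong seasonality — so the generator draws schedules uniformly from those
ranges (uniform defaults, not empirical distributions) over a task x season
grid, sprinkles factor modifiers that always respect the factor-target
taxonomy, and attaches a receptor profile from a small pool.  Each grid is
generated from one seeded NumPy stream with a fixed draw order, so a given
seed reproduces the same grid on any platform and the output is stable under
config extension.

Generated grids are guaranteed to round-trip through the configuration
document format and to resolve without validation errors at every cascade
level (default multiplier ranges for factors that may scale the exposure
factor are capped so a stack of them cannot push a cell's exposure factor
above 1).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import benchmarks
from .dose import DermalParameters, ExposureSchedule, IngestionParameters
from .scenario import (
    FACTOR_CLASSES,
    PERMITTED_TARGETS,
    CellExposure,
    FactorModifier,
    ReceptorProfile,
    ScenarioGrid,
)

__all__ = ["FieldRange", "ModifierSpec", "GeneratorConfig", "generate_scenario"]

_TASK_POOL = (
    "bed_preparation",
    "transplanting",
    "direct_seeding",
    "irrigation",
    "weeding",
    "harvesting",
    "mulching",
    "pest_management",
    "produce_handling",
    "cover_cropping",
)
_SEASON_POOL = ("spring", "summer", "fall", "winter")

_FACTOR_ORDER = tuple(FACTOR_CLASSES)  # fixed draw order

#: Factors allowed to scale the exposure factor; their default multiplier
#: range is capped at 1.2 so four stacked draws stay below 1/max-schedule-EF.
_EF_FACTORS = frozenset(
    f for f, targets in PERMITTED_TARGETS.items() if "exposure_factor" in targets
)


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class FieldRange(_Frozen):
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "FieldRange":
        if self.low > self.high:
            raise ValueError(f"infeasible range: low {self.low} > high {self.high}")
        return self


class ModifierSpec(_Frozen):
    """Presence probability and multiplier range for one factor."""

    probability: float = Field(ge=0.0, le=1.0)
    multiplier_range: FieldRange

    @model_validator(mode="after")
    def _positive(self) -> "ModifierSpec":
        if self.multiplier_range.low <= 0.0:
            raise ValueError("multiplier range must be strictly positive")
        return self


def _default_modifier_spec() -> dict[str, ModifierSpec]:
    spec = {}
    for factor in _FACTOR_ORDER:
        high = 1.2 if factor in _EF_FACTORS else 2.0
        spec[factor] = ModifierSpec(
            probability=0.25, multiplier_range=FieldRange(low=0.5, high=high)
        )
    return spec


def _default_receptor_pool() -> tuple[ReceptorProfile, ...]:
    return (
        ReceptorProfile(label="grower_A", age_band="20s", sex="female", body_weight=60.0),
        ReceptorProfile(label="grower_B", age_band="40s", sex="male", body_weight=90.0),
    )


class GeneratorConfig(_Frozen):
    """Reproducible configuration for random scenario generation.

    Schedule ranges default to the qualitative workday/work-week ranges the
    framework was derived from (1–17 h/day, 3–7 d/wk) with up to a full
    13-week season of work per cell.
    """

    seed: int = Field(ge=0, lt=2**31)
    n_tasks: int = Field(default=3, ge=0, le=len(_TASK_POOL) + 50)
    n_seasons: int = Field(default=4, ge=0, le=12)
    hours_per_day: FieldRange = FieldRange(low=1.0, high=17.0)
    days_per_week: FieldRange = FieldRange(low=3.0, high=7.0)
    weeks_per_season: FieldRange = FieldRange(low=4.0, high=13.0)
    cell_presence_probability: float = Field(default=0.85, ge=0.0, le=1.0)
    modifier_spec: dict[str, ModifierSpec] = Field(default_factory=_default_modifier_spec)
    receptor_pool: tuple[ReceptorProfile, ...] = Field(
        default_factory=_default_receptor_pool
    )

    @model_validator(mode="after")
    def _within_invariants(self) -> "GeneratorConfig":
        checks = [
            ("hours_per_day", self.hours_per_day, 0.0, 24.0),
            ("days_per_week", self.days_per_week, 0.0, 7.0),
            ("weeks_per_season", self.weeks_per_season, 0.0, 52.0),
        ]
        for name, rng, lo, hi in checks:
            if rng.low < lo or rng.high > hi:
                raise ValueError(
                    f"{name} range ({rng.low}, {rng.high}) outside [{lo}, {hi}]"
                )
        unknown = set(self.modifier_spec) - set(_FACTOR_ORDER)
        if unknown:
            raise ValueError(f"modifier_spec has unknown factors: {sorted(unknown)}")
        if not self.receptor_pool:
            raise ValueError("receptor_pool must not be empty")
        return self


def _names(pool: tuple[str, ...], prefix: str, n: int) -> tuple[str, ...]:
    names = list(pool[:n])
    names += [f"{prefix}_{i}" for i in range(len(names) + 1, n + 1)]
    return tuple(names)


def generate_scenario(config: GeneratorConfig) -> ScenarioGrid:
    """Draw one scenario grid from ``config``; identical seeds give identical grids."""
    rng = np.random.default_rng(config.seed)
    tasks = _names(_TASK_POOL, "task", config.n_tasks)
    seasons = _names(_SEASON_POOL, "season", config.n_seasons)

    cells: list[CellExposure] = []
    for task in tasks:
        for season in seasons:
            present = rng.random() < config.cell_presence_probability
            schedule = ExposureSchedule(
                hours_per_day=rng.uniform(
                    config.hours_per_day.low, config.hours_per_day.high
                ),
                days_per_week=rng.uniform(
                    config.days_per_week.low, config.days_per_week.high
                ),
                weeks_per_year=rng.uniform(
                    config.weeks_per_season.low, config.weeks_per_season.high
                ),
            )
            if present:  # draw first, keep conditionally: keeps the stream stable
                cells.append(CellExposure(task=task, season=season, schedule=schedule))

    grid_modifiers: list[FactorModifier] = []
    receptor_modifiers: list[FactorModifier] = []
    for factor in _FACTOR_ORDER:
        spec = config.modifier_spec.get(factor)
        if spec is None:
            continue
        present = rng.random() < spec.probability
        targets = sorted(PERMITTED_TARGETS[factor])
        target = targets[int(rng.integers(len(targets)))]
        value = rng.uniform(spec.multiplier_range.low, spec.multiplier_range.high)
        scope: Optional[tuple[tuple[str, str], ...]] = None
        if cells and rng.random() < 0.5:
            k = int(rng.integers(1, len(cells) + 1))
            idx = rng.choice(len(cells), size=k, replace=False)
            scope = tuple(sorted((cells[i].task, cells[i].season) for i in idx))
        if not present:
            continue
        modifier = FactorModifier(
            factor=factor,
            target_parameter=target,
            action="multiply",
            value=float(value),
            scope=scope,
        )
        if FACTOR_CLASSES[factor] == "receptor":
            receptor_modifiers.append(modifier)
        else:
            grid_modifiers.append(modifier)

    template = config.receptor_pool[int(rng.integers(len(config.receptor_pool)))]
    receptor = template.model_copy(
        update={"modifiers": template.modifiers + tuple(receptor_modifiers)}
    )

    return ScenarioGrid(
        tasks=tasks,
        seasons=seasons,
        baseline_ingestion=IngestionParameters(
            concentration=benchmarks.SOIL_CONCENTRATION,
            intake_rate=benchmarks.INTAKE_RATE,
            exposure_factor=benchmarks.BASE_EXPOSURE_FACTOR,
            body_weight=benchmarks.BODY_WEIGHT,
        ),
        baseline_dermal=DermalParameters(**benchmarks.DERMAL_BASELINE),
        schedules=tuple(cells),
        modifiers=tuple(grid_modifiers),
        receptor=receptor,
    )
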