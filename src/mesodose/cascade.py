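"""The stepwise sensitivity cascade over EAT-R factor classes.

The cascade evaluates one scenario grid at five nested levels of factor
integration, per pathway:

===================  =========================================  ==========
level                modifier classes applied                   model no.
                                                                (ing/derm)
===================  =========================================  ==========
``traditional``      none (single-cell occupational default)      1 / 2
``meso_activity``    activity                                     3 / 4
``plus_timing``      activity + timing                            5 / 6
``plus_environment`` activity + timing + environmental            7 / 8
``plus_receptor``    all four (requires a receptor profile)       9 / 10
===================  =========================================  ==========

The traditional level ignores the task/season structure entirely and
collapses to a single annual cell computed from the baseline parameters.
Every other level computes one average daily dose per (task, season) cell,
sums cells into seasonal subtotals and the subtotals into an annual total,
all at full precision.  Reports from two levels are compared by percent
difference, ratio and order-of-magnitude gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

from .dose import DoseResult, add_dermal, add_ingestion
from .scenario import ConfigurationError, Pathway, ScenarioGrid, resolve_cell

__all__ = [
    "LEVEL_ORDER",
    "LEVEL_CLASSES",
    "MODEL_NUMBERS",
    "LevelId",
    "CascadeLevel",
    "DoseReport",
    "LevelComparison",
    "CascadeResult",
    "run_level",
    "aggregate",
    "compare_levels",
    "run_cascade",
]

LevelId = Literal[
    "traditional", "meso_activity", "plus_timing", "plus_environment", "plus_receptor"
]

LEVEL_ORDER: tuple[LevelId, ...] = (
    "traditional",
    "meso_activity",
    "plus_timing",
    "plus_environment",
    "plus_receptor",
)

#: Modifier classes active at each cascade level.
LEVEL_CLASSES: dict[str, frozenset[str]] = {
    "traditional": frozenset(),
    "meso_activity": frozenset({"activity"}),
    "plus_timing": frozenset({"activity", "timing"}),
    "plus_environment": frozenset({"activity", "timing", "environmental"}),
    "plus_receptor": frozenset({"activity", "timing", "environmental", "receptor"}),
}

#: (level_id, pathway) -> model number in the ten-model demonstration.
MODEL_NUMBERS: dict[tuple[str, str], int] = {
    ("traditional", "ingestion"): 1,
    ("traditional", "dermal"): 2,
    ("meso_activity", "ingestion"): 3,
    ("meso_activity", "dermal"): 4,
    ("plus_timing", "ingestion"): 5,
    ("plus_timing", "dermal"): 6,
    ("plus_environment", "ingestion"): 7,
    ("plus_environment", "dermal"): 8,
    ("plus_receptor", "ingestion"): 9,
    ("plus_receptor", "dermal"): 10,
}


@dataclass(frozen=True)
class CascadeLevel:
    """One rung of the cascade: a level of factor integration plus a pathway."""

    level_id: LevelId
    pathway: Pathway

    @property
    def model_number(self) -> int:
        return MODEL_NUMBERS[(self.level_id, self.pathway)]

    @property
    def classes(self) -> frozenset[str]:
        return LEVEL_CLASSES[self.level_id]


@dataclass(frozen=True)
class DoseReport:
    """Per-cell doses with seasonal subtotals and the annual total.

    Invariants (enforced by construction through :func:`aggregate`): each
    seasonal subtotal is the exact sum of its cells, the annual total is the
    exact sum of the subtotals, and every entry is >= 0.
    """

    level: CascadeLevel
    cells: Mapping[tuple[str, str], DoseResult]
    seasonal_subtotals: Mapping[str, float]
    annual_total: float
    receptor_label: str = ""


@dataclass(frozen=True)
class LevelComparison:
    """Comparison of one report's annual total against a reference total.

    A comparison against a zero reference total is flagged ``defined=False``
    (never an exception or an infinity, to keep reports serializable).  The
    order-of-magnitude gap is ``log10(ratio)`` rounded to the nearest
    integer, and is ``None`` when the compared total is itself zero.
    """

    total_a: float
    total_b: float
    defined: bool
    percent_difference: Optional[float] = None
    ratio: Optional[float] = None
    magnitude_gap: Optional[int] = None


@dataclass(frozen=True)
class CascadeResult:
    """Ordered level reports plus each level's comparison to the traditional one."""

    pathway: Pathway
    reports: tuple[DoseReport, ...]
    comparisons: Mapping[str, LevelComparison] = field(default_factory=dict)

    def report(self, level_id: str) -> DoseReport:
        for rep in self.reports:
            if rep.level.level_id == level_id:
                return rep
        raise KeyError(level_id)


def aggregate(
    cells: Mapping[tuple[str, str], DoseResult],
    season_order: Optional[Sequence[str]] = None,
) -> tuple[dict[str, float], float]:
    """Sum per-cell doses into seasonal subtotals and an annual total.

    Sums are exact (full precision); display rounding is left to reporting.
    All cells must share one pathway.
    """
    pathways = {result.pathway for result in cells.values()}
    if len(pathways) > 1:
        raise ValueError(f"cells mix pathways: {sorted(pathways)}")
    if season_order is None:
        season_order = list(dict.fromkeys(season for (_, season) in cells))
    subtotals = {season: 0.0 for season in season_order}
    for (_, season), result in cells.items():
        subtotals[season] += result.value
    annual_total = sum(subtotals.values())
    return subtotals, annual_total


def run_level(
    grid: ScenarioGrid, level: CascadeLevel, label_prefix: str = ""
) -> DoseReport:
    """Evaluate one cascade level on a grid.

    The traditional level returns a single annual cell computed directly from
    the baseline parameters; all other levels resolve every (task, season)
    cell with the level's modifier classes and aggregate.
    """
    pathway = level.pathway
    dose_fn = add_ingestion if pathway == "ingestion" else add_dermal
    receptor_label = grid.receptor.label if grid.receptor is not None else ""

    if level.level_id == "traditional":
        baseline = (
            grid.baseline_ingestion if pathway == "ingestion" else grid.baseline_dermal
        )
        if baseline is None:
            raise ConfigurationError(f"grid has no baseline parameters for '{pathway}'")
        result = dose_fn(baseline, label=f"{label_prefix}all/annual/traditional")
        cells = {("all", "annual"): result}
        subtotals, annual_total = aggregate(cells, season_order=["annual"])
        return DoseReport(
            level=level,
            cells=cells,
            seasonal_subtotals=subtotals,
            annual_total=annual_total,
            receptor_label=receptor_label,
        )

    if level.level_id == "plus_receptor" and grid.receptor is None:
        raise ConfigurationError(
            "level 'plus_receptor' requires a receptor profile in the grid"
        )
    cells = {}
    for task in grid.tasks:
        for season in grid.seasons:
            params = resolve_cell(
                grid, task, season, pathway, classes=set(level.classes)
            )
            cells[(task, season)] = dose_fn(
                params, label=f"{label_prefix}{task}/{season}/{level.level_id}"
            )
    subtotals, annual_total = aggregate(cells, season_order=grid.seasons)
    return DoseReport(
        level=level,
        cells=cells,
        seasonal_subtotals=subtotals,
        annual_total=annual_total,
        receptor_label=receptor_label,
    )


def compare_levels(report_a: DoseReport, report_b: DoseReport) -> LevelComparison:
    """Compare annual totals of two same-pathway reports (a relative to b)."""
    if report_a.level.pathway != report_b.level.pathway:
        raise ValueError("cannot compare reports from different pathways")
    return _compare_totals(report_a.annual_total, report_b.annual_total)


def _compare_totals(total_a: float, total_b: float) -> LevelComparison:
    if total_b == 0.0:
        return LevelComparison(total_a=total_a, total_b=total_b, defined=False)
    ratio = total_a / total_b
    percent = (total_a - total_b) / total_b * 100.0
    gap = int(round(math.log10(ratio))) if ratio > 0.0 else None
    return LevelComparison(
        total_a=total_a,
        total_b=total_b,
        defined=True,
        percent_difference=percent,
        ratio=ratio,
        magnitude_gap=gap,
    )


def run_cascade(
    grid: ScenarioGrid,
    pathway: Pathway,
    levels: Optional[Sequence[LevelId]] = None,
) -> CascadeResult:
    """Run the full cascade for one pathway, in level order.

    ``levels`` defaults to every level the grid supports (``plus_receptor``
    is included only when the grid carries a receptor profile).  Each
    non-traditional level is compared against the traditional report.
    """
    if levels is None:
        levels = [
            lid
            for lid in LEVEL_ORDER
            if lid != "plus_receptor" or grid.receptor is not None
        ]
    else:
        unknown = set(levels) - set(LEVEL_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown cascade levels: {sorted(unknown)}")
        levels = [lid for lid in LEVEL_ORDER if lid in set(levels)]
    reports = tuple(run_level(grid, CascadeLevel(lid, pathway)) for lid in levels)
    comparisons: dict[str, LevelComparison] = {}
    baseline_report = next(
        (rep for rep in reports if rep.level.level_id == "traditional"), None
    )
    if baseline_report is not None:
        for rep in reports:
            if rep.level.level_id != "traditional":
                comparisons[rep.level.level_id] = compare_levels(rep, baseline_report)
    return CascadeResult(pathway=pathway, reports=reports, comparisons=comparisons)
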