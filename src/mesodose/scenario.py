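"""EAT-R factor taxonomy and scenario grids.

Soil exposure while farming is modified by ten qualitative factors grouped
into four classes — Environmental (natural, social/built), Activity (crop
type, growing practices, ergonomic positioning), Timing (season, day of week,
time of day) and Receptor (behavioral, biological).  Each factor is only
allowed to touch a fixed set of quantitative dose-model inputs (e.g. wetter
weather can raise the soil-to-skin adherence factor, a farm's labor structure
can only change the exposure factor).  This module enforces that mapping and
resolves a baseline parameter set into fully task- and season-specific
ingestion or dermal parameters.

Because no empirical magnitudes exist for the factors, modifiers carry
user-supplied values; the taxonomy is a validation rule, not a lookup table.
Modifiers are applied class by class in the order environmental -> activity
-> timing -> receptor; within a class multiplications compose commutatively
and an override (at most one per parameter per cell) is applied after the
multiplications of its class.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from .dose import (
    DermalParameters,
    ExposureSchedule,
    IngestionParameters,
    dermal_frequency,
    exposure_factor,
)

__all__ = [
    "FACTOR_CLASSES",
    "PERMITTED_TARGETS",
    "CLASS_ORDER",
    "ClassName",
    "FactorName",
    "Pathway",
    "ConfigurationError",
    "FactorModifier",
    "ModifierVerdict",
    "ReceptorProfile",
    "CellExposure",
    "ScenarioGrid",
    "validate_modifier",
    "resolve_cell",
    "build_grid_from_config",
    "grid_to_config",
]

ClassName = Literal["environmental", "activity", "timing", "receptor"]
FactorName = Literal[
    "natural",
    "social_built",
    "crop_type",
    "growing_practices",
    "ergonomic_positioning",
    "season",
    "day_of_week",
    "time_of_day",
    "behavioral",
    "biological",
]
Pathway = Literal["ingestion", "dermal"]

CLASS_ORDER: tuple[ClassName, ...] = ("environmental", "activity", "timing", "receptor")

#: Factor -> class taxonomy.
FACTOR_CLASSES: dict[str, ClassName] = {
    "natural": "environmental",
    "social_built": "environmental",
    "crop_type": "activity",
    "growing_practices": "activity",
    "ergonomic_positioning": "activity",
    "season": "timing",
    "day_of_week": "timing",
    "time_of_day": "timing",
    "behavioral": "receptor",
    "biological": "receptor",
}

#: Quantitative dose-model inputs each factor is permitted to modify.
PERMITTED_TARGETS: dict[str, frozenset[str]] = {
    "natural": frozenset({"intake_rate", "adherence_factor"}),
    "social_built": frozenset({"exposure_factor"}),
    "crop_type": frozenset(
        {"intake_rate", "exposure_factor", "exposure_frequency", "exposure_duration"}
    ),
    "growing_practices": frozenset(
        {"intake_rate", "exposure_frequency", "exposure_duration"}
    ),
    "ergonomic_positioning": frozenset({"intake_rate", "surface_area"}),
    "season": frozenset({"intake_rate", "exposure_factor", "averaging_time"}),
    "day_of_week": frozenset({"exposure_factor", "averaging_time"}),
    "time_of_day": frozenset({"intake_rate", "adherence_factor"}),
    "behavioral": frozenset({"intake_rate", "adherence_factor"}),
    "biological": frozenset({"intake_rate", "surface_area", "body_weight"}),
}

TargetParameter = Literal[
    "intake_rate",
    "adherence_factor",
    "exposure_factor",
    "exposure_frequency",
    "exposure_duration",
    "surface_area",
    "averaging_time",
    "body_weight",
]

_INGESTION_FIELDS = frozenset(IngestionParameters.model_fields)
_DERMAL_FIELDS = frozenset(DermalParameters.model_fields)


class ConfigurationError(ValueError):
    """A scenario configuration is structurally valid but semantically wrong."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class FactorModifier(_Frozen):
    """One qualitative factor translated into a quantitative adjustment.

    ``scope`` is the set of (task, season) cells the adjustment applies to;
    ``None`` means every cell in the grid.
    """

    factor: FactorName
    target_parameter: TargetParameter
    action: Literal["multiply", "override"]
    value: float = Field(ge=0.0)
    scope: Optional[tuple[tuple[str, str], ...]] = None

    @model_validator(mode="after")
    def _positive_multiplier(self) -> "FactorModifier":
        if self.action == "multiply" and self.value <= 0.0:
            raise ValueError("multiply modifiers require a value > 0")
        return self

    @property
    def class_name(self) -> ClassName:
        return FACTOR_CLASSES[self.factor]

    def applies_to(self, task: str, season: str) -> bool:
        return self.scope is None or (task, season) in self.scope


class ModifierVerdict(_Frozen):
    """Outcome of checking a modifier against the factor-target taxonomy."""

    accepted: bool
    factor: FactorName
    target_parameter: str
    permitted: frozenset[str]
    message: str = ""


def validate_modifier(modifier: FactorModifier) -> ModifierVerdict:
    """Accept a modifier iff its target is permitted for its factor.

    Rejections carry the factor's permitted target set so configuration
    errors can be reported with the allowed alternatives.
    """
    permitted = PERMITTED_TARGETS[modifier.factor]
    if modifier.target_parameter in permitted:
        return ModifierVerdict(
            accepted=True,
            factor=modifier.factor,
            target_parameter=modifier.target_parameter,
            permitted=permitted,
        )
    return ModifierVerdict(
        accepted=False,
        factor=modifier.factor,
        target_parameter=modifier.target_parameter,
        permitted=permitted,
        message=(
            f"factor '{modifier.factor}' may not modify "
            f"'{modifier.target_parameter}'; permitted targets: "
            f"{sorted(permitted)}"
        ),
    )


class ReceptorProfile(_Frozen):
    """The exposed person: biological attributes plus receptor-class modifiers.

    ``body_weight`` replaces the baseline body weight whenever receptor
    factors are in play; attached modifiers (biological and behavioral) carry
    person-specific effects such as PPE use or attire.
    """

    label: str
    age_band: str = ""
    sex: str = ""
    body_weight: float = Field(gt=0.0)
    modifiers: tuple[FactorModifier, ...] = ()

    @model_validator(mode="after")
    def _receptor_class_only(self) -> "ReceptorProfile":
        for mod in self.modifiers:
            if mod.class_name != "receptor":
                raise ValueError(
                    f"receptor profile '{self.label}' carries a non-receptor "
                    f"modifier (factor '{mod.factor}')"
                )
            verdict = validate_modifier(mod)
            if not verdict.accepted:
                raise ValueError(verdict.message)
        return self


class CellExposure(_Frozen):
    """Exposure intensity of one (task, season) cell.

    Either a full work schedule (from which both the ingestion exposure
    factor and the dermal exposure frequency are derived) or explicit
    pathway-specific values.  Cells not listed in a grid are zero-exposure.
    """

    task: str
    season: str
    schedule: Optional[ExposureSchedule] = None
    exposure_factor: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    exposure_frequency: Optional[float] = Field(default=None, ge=0.0)

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "CellExposure":
        explicit = self.exposure_factor is not None or self.exposure_frequency is not None
        if self.schedule is not None and explicit:
            raise ValueError(
                f"cell ({self.task}, {self.season}): give a schedule or "
                "explicit exposure values, not both"
            )
        if self.schedule is None and not explicit:
            raise ValueError(
                f"cell ({self.task}, {self.season}): needs a schedule or an "
                "exposure_factor / exposure_frequency"
            )
        return self

    def ingestion_exposure_factor(self) -> Optional[float]:
        if self.schedule is not None:
            return exposure_factor(self.schedule)
        return self.exposure_factor

    def dermal_exposure_frequency(self) -> Optional[float]:
        if self.schedule is not None:
            return dermal_frequency(self.schedule)
        return self.exposure_frequency


class ScenarioGrid(_Frozen):
    """A task x season exposure scenario: baselines, schedules and modifiers.

    This is the unit the sensitivity cascade evaluates.  Cells absent from
    ``schedules`` are zero-exposure (e.g. no transplanting in fall, no field
    work in winter).
    """

    tasks: tuple[str, ...]
    seasons: tuple[str, ...]
    baseline_ingestion: Optional[IngestionParameters] = None
    baseline_dermal: Optional[DermalParameters] = None
    schedules: tuple[CellExposure, ...] = ()
    modifiers: tuple[FactorModifier, ...] = ()
    receptor: Optional[ReceptorProfile] = None

    @model_validator(mode="after")
    def _internally_consistent(self) -> "ScenarioGrid":
        if len(set(self.tasks)) != len(self.tasks):
            raise ValueError("duplicate task names")
        if len(set(self.seasons)) != len(self.seasons):
            raise ValueError("duplicate season names")
        seen: set[tuple[str, str]] = set()
        for cell in self.schedules:
            key = (cell.task, cell.season)
            if cell.task not in self.tasks:
                raise ValueError(f"schedule entry references unknown task '{cell.task}'")
            if cell.season not in self.seasons:
                raise ValueError(
                    f"schedule entry references unknown season '{cell.season}'"
                )
            if key in seen:
                raise ValueError(f"duplicate schedule entry for cell {key}")
            seen.add(key)
        for i, mod in enumerate(self.modifiers):
            verdict = validate_modifier(mod)
            if not verdict.accepted:
                raise ValueError(f"modifiers[{i}]: {verdict.message}")
            for task, season in mod.scope or ():
                if task not in self.tasks or season not in self.seasons:
                    raise ValueError(
                        f"modifiers[{i}] (factor '{mod.factor}') scope entry "
                        f"({task}, {season}) references an unknown task/season"
                    )
        return self

    def cell(self, task: str, season: str) -> Optional[CellExposure]:
        for entry in self.schedules:
            if entry.task == task and entry.season == season:
                return entry
        return None


def _apply_modifiers(
    values: dict[str, float],
    modifiers: list[FactorModifier],
    task: str,
    season: str,
) -> dict[str, float]:
    """Apply modifiers class by class; returns a new parameter dict."""
    out = dict(values)
    overridden: set[str] = set()
    for cls in CLASS_ORDER:
        class_mods = [m for m in modifiers if m.class_name == cls]
        for mod in class_mods:
            if mod.action == "multiply" and mod.target_parameter in out:
                out[mod.target_parameter] *= mod.value
        for mod in class_mods:
            if mod.action == "override" and mod.target_parameter in out:
                if mod.target_parameter in overridden:
                    raise ConfigurationError(
                        f"cell ({task}, {season}): two overrides on "
                        f"'{mod.target_parameter}'"
                    )
                overridden.add(mod.target_parameter)
                out[mod.target_parameter] = mod.value
    return out


def resolve_cell(
    grid: ScenarioGrid,
    task: str,
    season: str,
    pathway: Pathway,
    classes: Optional[set[str]] = None,
):
    """Resolve the fully modified parameter set for one grid cell.

    Starts from the grid's baseline for ``pathway``, sets the cell's exposure
    intensity from its schedule, then applies the modifiers of the active
    ``classes`` (default: all four) in taxonomy order.  The baseline is never
    mutated; resolving twice yields identical parameters.  Zero-exposure
    cells resolve to a zero exposure factor / frequency and skip modifiers.

    Returns :class:`IngestionParameters` or :class:`DermalParameters`.
    Raises :class:`ConfigurationError` for unknown cells, missing baselines
    or conflicting overrides, and :class:`pydantic.ValidationError` if the
    modified parameters violate a dose-model invariant (e.g. an exposure
    factor pushed above 1).
    """
    if task not in grid.tasks or season not in grid.seasons:
        raise ConfigurationError(f"cell ({task}, {season}) is not in the grid")
    if classes is None:
        classes = set(CLASS_ORDER)

    if pathway == "ingestion":
        baseline = grid.baseline_ingestion
        intensity_field = "exposure_factor"
    else:
        baseline = grid.baseline_dermal
        intensity_field = "exposure_frequency"
    if baseline is None:
        raise ConfigurationError(f"grid has no baseline parameters for '{pathway}'")

    values = {name: getattr(baseline, name) for name in type(baseline).model_fields}
    cell = grid.cell(task, season)
    if cell is None:
        values[intensity_field] = 0.0
        return type(baseline)(**values)
    intensity = (
        cell.ingestion_exposure_factor()
        if pathway == "ingestion"
        else cell.dermal_exposure_frequency()
    )
    if intensity is None:
        raise ConfigurationError(
            f"cell ({task}, {season}) has no {intensity_field} for '{pathway}'"
        )
    values[intensity_field] = intensity

    active = [
        m
        for m in grid.modifiers
        if m.class_name in classes and m.applies_to(task, season)
    ]
    if grid.receptor is not None and "receptor" in classes:
        values["body_weight"] = grid.receptor.body_weight
        active += [
            m for m in grid.receptor.modifiers if m.applies_to(task, season)
        ]
    values = _apply_modifiers(values, active, task, season)
    return type(baseline)(**{k: v for k, v in values.items()})


# ---------------------------------------------------------------------------
# configuration documents


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for item in err.errors():
        path = ".".join(str(p) for p in item["loc"]) or "<root>"
        lines.append(f"{path}: {item['msg']}")
    return "; ".join(lines)


def build_grid_from_config(document: dict) -> ScenarioGrid:
    """Build a validated :class:`ScenarioGrid` from a plain configuration dict.

    The document uses top-level keys ``tasks``, ``seasons``, ``baselines``
    (``ingestion`` / ``dermal``), ``schedules``, ``modifiers`` and
    ``receptor``; see ``mesodose/data/scenario.schema.json`` for the full
    schema.  Errors carry a path to the offending entry.
    """
    if not isinstance(document, dict):
        raise ConfigurationError("scenario document must be a mapping")
    known = {"tasks", "seasons", "baselines", "schedules", "modifiers", "receptor"}
    unknown = set(document) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
    baselines = document.get("baselines") or {}
    if not isinstance(baselines, dict) or set(baselines) - {"ingestion", "dermal"}:
        raise ConfigurationError(
            "baselines: expected a mapping with keys 'ingestion' and/or 'dermal'"
        )

    def _scope(raw):
        if raw in (None, "all"):
            return None
        return tuple((entry[0], entry[1]) for entry in raw)

    try:
        modifiers = tuple(
            FactorModifier(**{**m, "scope": _scope(m.get("scope"))})
            for m in document.get("modifiers") or ()
        )
        receptor_doc = document.get("receptor")
        receptor = None
        if receptor_doc is not None:
            receptor = ReceptorProfile(
                **{
                    **receptor_doc,
                    "modifiers": tuple(
                        FactorModifier(**{**m, "scope": _scope(m.get("scope"))})
                        for m in receptor_doc.get("modifiers") or ()
                    ),
                }
            )
        grid = ScenarioGrid(
            tasks=tuple(document.get("tasks") or ()),
            seasons=tuple(document.get("seasons") or ()),
            baseline_ingestion=(
                IngestionParameters(**baselines["ingestion"])
                if "ingestion" in baselines
                else None
            ),
            baseline_dermal=(
                DermalParameters(**baselines["dermal"]) if "dermal" in baselines else None
            ),
            schedules=tuple(
                CellExposure(**cell) for cell in document.get("schedules") or ()
            ),
            modifiers=modifiers,
            receptor=receptor,
        )
    except ValidationError as err:
        raise ConfigurationError(_format_validation_error(err)) from err
    except (TypeError, KeyError, IndexError) as err:
        raise ConfigurationError(f"malformed scenario document: {err}") from err
    return grid


def _modifier_to_dict(mod: FactorModifier) -> dict:
    return {
        "factor": mod.factor,
        "target_parameter": mod.target_parameter,
        "action": mod.action,
        "value": mod.value,
        "scope": "all" if mod.scope is None else [list(pair) for pair in mod.scope],
    }


def grid_to_config(grid: ScenarioGrid) -> dict:
    """Serialize a grid to the plain-dict document format (round-trippable)."""
    doc: dict = {
        "tasks": list(grid.tasks),
        "seasons": list(grid.seasons),
        "baselines": {},
        "schedules": [],
        "modifiers": [_modifier_to_dict(m) for m in grid.modifiers],
    }
    if grid.baseline_ingestion is not None:
        doc["baselines"]["ingestion"] = grid.baseline_ingestion.model_dump()
    if grid.baseline_dermal is not None:
        doc["baselines"]["dermal"] = grid.baseline_dermal.model_dump()
    for cell in grid.schedules:
        entry: dict = {"task": cell.task, "season": cell.season}
        if cell.schedule is not None:
            entry["schedule"] = cell.schedule.model_dump()
        if cell.exposure_factor is not None:
            entry["exposure_factor"] = cell.exposure_factor
        if cell.exposure_frequency is not None:
            entry["exposure_frequency"] = cell.exposure_frequency
        doc["schedules"].append(entry)
    if grid.receptor is not None:
        doc["receptor"] = {
            "label": grid.receptor.label,
            "age_band": grid.receptor.age_band,
            "sex": grid.receptor.sex,
            "body_weight": grid.receptor.body_weight,
            "modifiers": [_modifier_to_dict(m) for m in grid.receptor.modifiers],
        }
    return doc
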