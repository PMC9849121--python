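"""Scenario-document parsing and dose-report serialization.

Scenario configurations are YAML or JSON documents (YAML is a superset, so
one loader handles both) validated into :class:`~mesodose.scenario.ScenarioGrid`.
Reports are written as one CSV per pathway — cell, subtotal and total rows,
each dose at three significant figures next to a full-precision column that
round-trips the float exactly — plus a JSON summary mirroring the report
structure.  A machine-readable JSON Schema for the document format ships in
``mesodose/data/scenario.schema.json`` and is regenerable via
:func:`scenario_schema`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import yaml

from .cascade import CascadeResult, DoseReport
from .dose import (
    DermalParameters,
    ExposureSchedule,
    IngestionParameters,
    round_sig,
)
from .scenario import (
    ConfigurationError,
    ScenarioGrid,
    build_grid_from_config,
    grid_to_config,
)

__all__ = [
    "ConfigParseError",
    "read_config",
    "write_config",
    "write_report",
    "scenario_schema",
]


class ConfigParseError(ValueError):
    """The configuration file is not parseable YAML/JSON."""


def read_config(path: Union[str, Path]) -> ScenarioGrid:
    """Read and fully validate a scenario document from ``path``.

    Raises ``FileNotFoundError`` for a missing file, :class:`ConfigParseError`
    for unparseable text and :class:`ConfigurationError` (with a path to the
    offending entry) for schema or semantic violations.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such configuration file: {p}")
    try:
        document = yaml.safe_load(p.read_text())
    except yaml.YAMLError as err:
        raise ConfigParseError(f"{p}: {err}") from err
    try:
        return build_grid_from_config(document)
    except ConfigurationError as err:
        raise ConfigurationError(f"{p}: {err}") from err


def write_config(grid: ScenarioGrid, path: Union[str, Path]) -> Path:
    """Serialize ``grid`` to ``path`` (JSON if the suffix is .json, else YAML).

    Output is deterministic: the same grid always produces identical bytes.
    """
    p = Path(path)
    document = grid_to_config(grid)
    if p.suffix == ".json":
        p.write_text(json.dumps(document, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(document, sort_keys=False))
    return p


def _full(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def _report_rows(report: DoseReport) -> Iterable[dict]:
    level = report.level
    base = {
        "model": level.model_number,
        "level": level.level_id,
        "pathway": level.pathway,
        "receptor": report.receptor_label,
    }
    for (task, season), result in report.cells.items():
        yield {
            **base,
            "row_type": "cell",
            "task": task,
            "season": season,
            "dose_mg_per_kgbw_day": round_sig(result.value),
            "dose_full_precision": _full(result.value),
        }
    for season, subtotal in report.seasonal_subtotals.items():
        yield {
            **base,
            "row_type": "subtotal",
            "task": "",
            "season": season,
            "dose_mg_per_kgbw_day": round_sig(subtotal),
            "dose_full_precision": _full(subtotal),
        }
    yield {
        **base,
        "row_type": "total",
        "task": "",
        "season": "",
        "dose_mg_per_kgbw_day": round_sig(report.annual_total),
        "dose_full_precision": _full(report.annual_total),
    }


_COLUMNS = [
    "model",
    "level",
    "pathway",
    "receptor",
    "row_type",
    "task",
    "season",
    "dose_mg_per_kgbw_day",
    "dose_full_precision",
]


def _summarize(report: DoseReport) -> dict:
    return {
        "model": report.level.model_number,
        "level": report.level.level_id,
        "pathway": report.level.pathway,
        "receptor": report.receptor_label,
        "cells": {
            f"{task}/{season}": result.value
            for (task, season), result in report.cells.items()
        },
        "seasonal_subtotals": dict(report.seasonal_subtotals),
        "annual_total": report.annual_total,
    }


def write_report(
    results: Union[CascadeResult, DoseReport, Iterable[Union[CascadeResult, DoseReport]]],
    destination: Union[str, Path],
) -> dict[str, Path]:
    """Write dose reports under ``destination``; overwrites are idempotent.

    Produces ``report_<pathway>.csv`` for every pathway present (header-only
    when a pathway has no reports was requested) and ``summary.json``.
    Returns a mapping of artifact name to written path.
    """
    if isinstance(results, (CascadeResult, DoseReport)):
        results = [results]
    reports: list[DoseReport] = []
    comparisons: list[dict] = []
    for item in results:
        if isinstance(item, CascadeResult):
            reports.extend(item.reports)
            for level_id, cmp in item.comparisons.items():
                comparisons.append(
                    {
                        "pathway": item.pathway,
                        "level": level_id,
                        "versus": "traditional",
                        "defined": cmp.defined,
                        "percent_difference": cmp.percent_difference,
                        "ratio": cmp.ratio,
                        "magnitude_gap": cmp.magnitude_gap,
                    }
                )
        else:
            reports.append(item)

    dest = Path(destination)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create report destination '{dest}': {err}") from err

    written: dict[str, Path] = {}
    for pathway in ("ingestion", "dermal"):
        pathway_reports = [r for r in reports if r.level.pathway == pathway]
        if not pathway_reports and not reports:
            pathway_reports = []
        if not pathway_reports and reports:
            continue
        rows = [row for rep in pathway_reports for row in _report_rows(rep)]
        frame = pd.DataFrame(rows, columns=_COLUMNS)
        path = dest / f"report_{pathway}.csv"
        frame.to_csv(path, index=False)
        written[f"report_{pathway}"] = path

    summary = {
        "reports": [_summarize(rep) for rep in reports],
        "comparisons": comparisons,
    }
    summary_path = dest / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    written["summary"] = summary_path
    return written


def _strip_titles(schema: dict) -> dict:
    schema = dict(schema)
    schema.pop("title", None)
    return schema


def scenario_schema() -> dict:
    """JSON Schema of the scenario document format (the published contract)."""
    scope_schema = {
        "oneOf": [
            {"const": "all"},
            {"type": "null"},
            {
                "type": "array",
                "items": {
                    "type": "array",
                    "prefixItems": [{"type": "string"}, {"type": "string"}],
                    "minItems": 2,
                    "maxItems": 2,
                },
            },
        ]
    }
    modifier_schema = {
        "type": "object",
        "properties": {
            "factor": {
                "enum": [
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
            },
            "target_parameter": {
                "enum": [
                    "intake_rate",
                    "adherence_factor",
                    "exposure_factor",
                    "exposure_frequency",
                    "exposure_duration",
                    "surface_area",
                    "averaging_time",
                    "body_weight",
                ]
            },
            "action": {"enum": ["multiply", "override"]},
            "value": {"type": "number", "minimum": 0},
            "scope": scope_schema,
        },
        "required": ["factor", "target_parameter", "action", "value"],
        "additionalProperties": False,
    }
    schedule_schema = _strip_titles(ExposureSchedule.model_json_schema())
    cell_schema = {
        "type": "object",
        "properties": {
            "task": {"type": "string"},
            "season": {"type": "string"},
            "schedule": schedule_schema,
            "exposure_factor": {"type": "number", "minimum": 0, "maximum": 1},
            "exposure_frequency": {"type": "number", "minimum": 0},
        },
        "required": ["task", "season"],
        "additionalProperties": False,
    }
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "mesodose scenario document",
        "type": "object",
        "properties": {
            "tasks": {"type": "array", "items": {"type": "string"}},
            "seasons": {"type": "array", "items": {"type": "string"}},
            "baselines": {
                "type": "object",
                "properties": {
                    "ingestion": _strip_titles(IngestionParameters.model_json_schema()),
                    "dermal": _strip_titles(DermalParameters.model_json_schema()),
                },
                "additionalProperties": False,
            },
            "schedules": {"type": "array", "items": cell_schema},
            "modifiers": {"type": "array", "items": modifier_schema},
            "receptor": {
                "type": "object",
                "properties": {
                    "label": {"type": "string"},
                    "age_band": {"type": "string"},
                    "sex": {"type": "string"},
                    "body_weight": {"type": "number", "exclusiveMinimum": 0},
                    "modifiers": {"type": "array", "items": modifier_schema},
                },
                "required": ["label", "body_weight"],
                "additionalProperties": False,
            },
        },
        "required": ["tasks", "seasons"],
        "additionalProperties": False,
    }
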