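"""Average-daily-dose equations for incidental soil ingestion and dermal contact.

The two dose models follow standard risk-guidance arithmetic for soil
contaminants.  Ingestion::

    ADD = C * IR * EF / BW          [mg contaminant / kg body weight / day]

where ``C`` is the contaminant concentration in soil (mg contaminant per mg
soil), ``IR`` the incidental soil intake rate (mg soil/day), ``EF`` a
dimensionless exposure factor in [0, 1] describing the fraction of time the
receptor is in contact with soil, and ``BW`` body weight (kg).

Dermal contact is computed per event and then averaged::

    DA_event = C * CF * AF * ABS    [mg / cm^2 / event]
    ADD      = DA_event * SA * EFreq * ED * EV / (BW * AT)

with ``C`` in mg contaminant per kg soil, ``CF`` a kg/mg unit conversion,
``AF`` the soil-to-skin adherence factor (mg soil / cm^2 / event), ``ABS``
the dermal absorption fraction, ``SA`` exposed skin surface area (cm^2),
``EFreq`` exposure frequency (days/yr), ``ED`` exposure duration (yr), ``EV``
event frequency (events/day), and ``AT`` the averaging time (days).  With
those units the product is dimensionally coherent and yields mg/kgBW/day.

The exposure factor is built from a work schedule as the product of three
fractions of the calendar: hours worked per 24-h day, days per 7-day week and
weeks per 52-week year.  Every quantity is validated at construction time so
the arithmetic itself can never divide by zero or produce a negative dose.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "ExposureSchedule",
    "IngestionParameters",
    "DermalParameters",
    "DoseResult",
    "exposure_factor",
    "dermal_frequency",
    "add_ingestion",
    "absorbed_dose_event",
    "add_dermal",
    "round_sig",
]

HOURS_PER_DAY = 24.0
DAYS_PER_WEEK = 7.0
WEEKS_PER_YEAR = 52.0


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class ExposureSchedule(_Frozen):
    """A work schedule: hours/day, days/week and weeks/year in contact with soil."""

    hours_per_day: float = Field(ge=0.0, le=24.0)
    days_per_week: float = Field(ge=0.0, le=7.0)
    weeks_per_year: float = Field(ge=0.0, le=52.0)


class IngestionParameters(_Frozen):
    """Inputs of the soil-ingestion dose equation for one task-season cell.

    ``concentration`` is expressed as mg contaminant per mg soil (a bulk
    concentration of 212.7 mg/kg is 2.127e-4 mg/mg).
    """

    concentration: float = Field(ge=0.0, description="mg contaminant / mg soil")
    intake_rate: float = Field(ge=0.0, description="mg soil ingested / day")
    exposure_factor: float = Field(ge=0.0, le=1.0, description="fraction of time in contact")
    body_weight: float = Field(gt=0.0, description="kg")


class DermalParameters(_Frozen):
    """Inputs of the dermal-contact dose equation for one task-season cell.

    ``concentration`` is kept in mg/kg with an explicit ``conversion_factor``
    (kg/mg) rather than pre-converted, mirroring how the conversion term is
    carried as a distinct symbol in risk-guidance worksheets.
    """

    concentration: float = Field(ge=0.0, description="mg contaminant / kg soil")
    conversion_factor: float = Field(ge=0.0, description="kg/mg unit conversion")
    adherence_factor: float = Field(ge=0.0, description="mg soil / cm^2 / event")
    absorption_fraction: float = Field(ge=0.0, le=1.0, description="dimensionless")
    surface_area: float = Field(ge=0.0, description="exposed skin, cm^2")
    exposure_frequency: float = Field(ge=0.0, description="days / year")
    exposure_duration: float = Field(ge=0.0, description="years")
    event_frequency: float = Field(ge=0.0, description="events / day")
    body_weight: float = Field(gt=0.0, description="kg")
    averaging_time: float = Field(gt=0.0, description="days")


class DoseResult(_Frozen):
    """One computed average daily dose with its provenance label."""

    value: float = Field(ge=0.0, description="mg/kgBW/day")
    pathway: Literal["ingestion", "dermal"]
    label: str = ""


def exposure_factor(schedule: ExposureSchedule) -> float:
    """Fraction of the calendar a receptor following ``schedule`` contacts soil.

    Computed as ``(h/24) * (d/7) * (wk/52)``; by the schedule invariants the
    result lies in [0, 1] and is monotone in each field.  A 10 h/6 d/50 wk
    schedule gives 0.343 (0.34 at two decimals).
    """
    return (
        (schedule.hours_per_day / HOURS_PER_DAY)
        * (schedule.days_per_week / DAYS_PER_WEEK)
        * (schedule.weeks_per_year / WEEKS_PER_YEAR)
    )


def dermal_frequency(schedule: ExposureSchedule) -> float:
    """Dermal exposure frequency (days/year) implied by a work schedule."""
    return schedule.days_per_week * schedule.weeks_per_year


def add_ingestion(params: IngestionParameters, label: str = "") -> DoseResult:
    """Average daily dose via incidental soil ingestion, mg/kgBW/day."""
    value = (
        params.concentration * params.intake_rate * params.exposure_factor
    ) / params.body_weight
    return DoseResult(value=value, pathway="ingestion", label=label)


def absorbed_dose_event(params: DermalParameters) -> float:
    """Contaminant mass absorbed per cm^2 of skin per contact event."""
    return (
        params.concentration
        * params.conversion_factor
        * params.adherence_factor
        * params.absorption_fraction
    )


def add_dermal(params: DermalParameters, label: str = "") -> DoseResult:
    """Average daily dose via dermal contact, mg/kgBW/day."""
    value = (
        absorbed_dose_event(params)
        * params.surface_area
        * params.exposure_frequency
        * params.exposure_duration
        * params.event_frequency
    ) / (params.body_weight * params.averaging_time)
    return DoseResult(value=value, pathway="dermal", label=label)


def round_sig(x: float, digits: int = 3) -> float:
    """Round ``x`` to ``digits`` significant figures (reporting precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
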