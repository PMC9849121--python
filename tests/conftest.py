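import pytest

from mesodose import (
    CellExposure,
    DermalParameters,
    FactorModifier,
    IngestionParameters,
    ScenarioGrid,
)


@pytest.fixture
def ingestion_baseline() -> IngestionParameters:
    return IngestionParameters(
        concentration=2.0e-4, intake_rate=100.0, exposure_factor=0.16, body_weight=80.0
    )


@pytest.fixture
def dermal_baseline() -> DermalParameters:
    return DermalParameters(
        concentration=200.0,
        conversion_factor=1e-6,
        adherence_factor=0.07,
        absorption_fraction=0.001,
        surface_area=990.0,
        exposure_frequency=250.0,
        exposure_duration=1.0,
        event_frequency=1.0,
        body_weight=80.0,
        averaging_time=365.0,
    )


@pytest.fixture
def small_grid(ingestion_baseline, dermal_baseline) -> ScenarioGrid:
    """Two tasks x two seasons; the (weeding, winter) cell is zero-exposure."""
    return ScenarioGrid(
        tasks=("weeding", "harvesting"),
        seasons=("summer", "winter"),
        baseline_ingestion=ingestion_baseline,
        baseline_dermal=dermal_baseline,
        schedules=(
            CellExposure(task="weeding", season="summer", exposure_factor=0.10, exposure_frequency=60.0),
            CellExposure(task="harvesting", season="summer", exposure_factor=0.05, exposure_frequency=40.0),
            CellExposure(task="harvesting", season="winter", exposure_factor=0.02, exposure_frequency=10.0),
        ),
        modifiers=(
            FactorModifier(
                factor="natural",
                target_parameter="intake_rate",
                action="multiply",
                value=1.5,
                scope=(("weeding", "summer"),),
            ),
        ),
    )
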