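"""Tests for the EAT-R factor taxonomy, modifier resolution and config parsing."""

import itertools

import pytest
from pydantic import ValidationError

from mesodose import (
    FACTOR_CLASSES,
    PERMITTED_TARGETS,
    CellExposure,
    ConfigurationError,
    FactorModifier,
    IngestionParameters,
    ReceptorProfile,
    ScenarioGrid,
    build_grid_from_config,
    grid_to_config,
    resolve_cell,
    validate_modifier,
)

ALL_TARGETS = (
    "intake_rate",
    "adherence_factor",
    "exposure_factor",
    "exposure_frequency",
    "exposure_duration",
    "surface_area",
    "averaging_time",
    "body_weight",
)


def mod(factor, target, action="multiply", value=1.5, scope=None) -> FactorModifier:
    return FactorModifier(
        factor=factor, target_parameter=target, action=action, value=value, scope=scope
    )


class TestValidateModifier:
    @pytest.mark.parametrize(
        ("factor", "target"),
        list(itertools.product(sorted(FACTOR_CLASSES), ALL_TARGETS)),
    )
    def test_full_factor_target_matrix(self, factor, target):
        verdict = validate_modifier(mod(factor, target))
        assert verdict.accepted == (target in PERMITTED_TARGETS[factor])

    def test_rejection_carries_permitted_set(self):
        verdict = validate_modifier(mod("social_built", "adherence_factor"))
        assert not verdict.accepted
        assert verdict.permitted == frozenset({"exposure_factor"})
        assert "exposure_factor" in verdict.message

    def test_wet_weather_may_raise_adherence(self):
        assert validate_modifier(mod("natural", "adherence_factor")).accepted

    def test_unknown_factor_name_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            mod("astrological", "intake_rate")

    def test_unknown_parameter_name_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            mod("natural", "shoe_size")

    def test_zero_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            mod("natural", "intake_rate", value=0.0)


class TestResolveCell:
    def test_no_modifiers_leaves_baseline_unchanged(self, small_grid):
        params = resolve_cell(small_grid, "harvesting", "summer", "ingestion")
        baseline = small_grid.baseline_ingestion
        assert params.concentration == baseline.concentration
        assert params.intake_rate == baseline.intake_rate
        assert params.body_weight == baseline.body_weight
        assert params.exposure_factor == 0.05  # from the cell, not the baseline

    def test_resolution_is_pure_and_repeatable(self, small_grid):
        first = resolve_cell(small_grid, "weeding", "summer", "ingestion")
        second = resolve_cell(small_grid, "weeding", "summer", "ingestion")
        assert first == second
        assert small_grid.baseline_ingestion.intake_rate == 100.0

    def test_scoped_multiplier_applies_only_in_scope(self, small_grid):
        in_scope = resolve_cell(small_grid, "weeding", "summer", "ingestion")
        out_of_scope = resolve_cell(small_grid, "harvesting", "summer", "ingestion")
        assert in_scope.intake_rate == pytest.approx(150.0)
        assert out_of_scope.intake_rate == pytest.approx(100.0)

    def test_absent_cell_is_zero_exposure(self, small_grid):
        ing = resolve_cell(small_grid, "weeding", "winter", "ingestion")
        derm = resolve_cell(small_grid, "weeding", "winter", "dermal")
        assert ing.exposure_factor == 0.0
        assert derm.exposure_frequency == 0.0

    def test_unknown_cell_raises(self, small_grid):
        with pytest.raises(ConfigurationError):
            resolve_cell(small_grid, "weeding", "monsoon", "ingestion")

    def test_multiplies_compose_commutatively(self, small_grid):
        mods = (
            mod("natural", "intake_rate", value=1.5),
            mod("behavioral", "intake_rate", value=2.0),
        )
        base = small_grid.model_copy(update={"modifiers": ()})
        forward = base.model_copy(update={"modifiers": mods})
        backward = base.model_copy(update={"modifiers": mods[::-1]})
        a = resolve_cell(forward, "weeding", "summer", "ingestion")
        b = resolve_cell(backward, "weeding", "summer", "ingestion")
        assert a.intake_rate == b.intake_rate == pytest.approx(300.0)

    def test_override_applies_after_multiplies_of_its_class(self, small_grid):
        mods = (
            mod("natural", "adherence_factor", action="override", value=0.2),
            mod("time_of_day", "adherence_factor", value=2.0),  # timing, applied later
        )
        grid = small_grid.model_copy(update={"modifiers": mods})
        params = resolve_cell(grid, "weeding", "summer", "dermal")
        assert params.adherence_factor == pytest.approx(0.4)

    def test_spring_style_adherence_override(self, small_grid):
        grid = small_grid.model_copy(
            update={"modifiers": (mod("natural", "adherence_factor", action="override", value=0.2),)}
        )
        params = resolve_cell(grid, "weeding", "summer", "dermal")
        assert params.adherence_factor == 0.2

    def test_conflicting_overrides_rejected(self, small_grid):
        mods = (
            mod("natural", "adherence_factor", action="override", value=0.2),
            mod("behavioral", "adherence_factor", action="override", value=0.05),
        )
        grid = small_grid.model_copy(update={"modifiers": mods})
        with pytest.raises(ConfigurationError, match="two overrides"):
            resolve_cell(grid, "weeding", "summer", "dermal")

    def test_identity_multiplier_is_noop(self, small_grid):
        grid = small_grid.model_copy(
            update={"modifiers": small_grid.modifiers + (mod("season", "intake_rate", value=1.0),)}
        )
        assert resolve_cell(grid, "weeding", "summer", "ingestion") == resolve_cell(
            small_grid, "weeding", "summer", "ingestion"
        )

    def test_invalid_resolved_parameters_fail_loudly(self, small_grid):
        grid = small_grid.model_copy(
            update={"modifiers": (mod("social_built", "exposure_factor", value=50.0),)}
        )
        with pytest.raises(ValidationError, match="exposure_factor"):
            resolve_cell(grid, "weeding", "summer", "ingestion")

    def test_receptor_body_weight_only_with_receptor_class(self, small_grid):
        grid = small_grid.model_copy(
            update={"receptor": ReceptorProfile(label="g", body_weight=60.0)}
        )
        with_receptor = resolve_cell(grid, "weeding", "summer", "ingestion")
        without = resolve_cell(
            grid, "weeding", "summer", "ingestion", classes={"environmental", "activity"}
        )
        assert with_receptor.body_weight == 60.0
        assert without.body_weight == 80.0


class TestGridAndConfig:
    def test_receptor_profile_rejects_non_receptor_modifiers(self):
        with pytest.raises(ValidationError, match="non-receptor"):
            ReceptorProfile(
                label="g", body_weight=70, modifiers=(mod("natural", "intake_rate"),)
            )

    def test_grid_rejects_modifier_scope_with_unknown_season(self, ingestion_baseline):
        with pytest.raises(ValidationError, match="sumer"):
            ScenarioGrid(
                tasks=("weeding",),
                seasons=("summer",),
                baseline_ingestion=ingestion_baseline,
                modifiers=(mod("natural", "intake_rate", scope=(("weeding", "sumer"),)),),
            )

    def test_grid_rejects_disallowed_factor_target(self, ingestion_baseline):
        with pytest.raises(ValidationError, match="permitted"):
            ScenarioGrid(
                tasks=("weeding",),
                seasons=("summer",),
                baseline_ingestion=ingestion_baseline,
                modifiers=(mod("social_built", "intake_rate"),),
            )

    def test_config_round_trip_deep_equal(self, small_grid):
        assert build_grid_from_config(grid_to_config(small_grid)) == small_grid

    def test_empty_tasks_gives_valid_empty_grid(self, ingestion_baseline):
        grid = build_grid_from_config(
            {
                "tasks": [],
                "seasons": ["summer"],
                "baselines": {"ingestion": ingestion_baseline.model_dump()},
            }
        )
        assert grid.tasks == ()

    def test_negative_body_weight_names_the_field(self):
        with pytest.raises(ConfigurationError, match="body_weight"):
            build_grid_from_config(
                {
                    "tasks": ["weeding"],
                    "seasons": ["summer"],
                    "baselines": {
                        "ingestion": {
                            "concentration": 1e-4,
                            "intake_rate": 100,
                            "exposure_factor": 0.2,
                            "body_weight": -5,
                        }
                    },
                }
            )

    def test_misspelled_scope_season_reported(self):
        with pytest.raises(ConfigurationError, match="sprang"):
            build_grid_from_config(
                {
                    "tasks": ["weeding"],
                    "seasons": ["spring"],
                    "baselines": {
                        "ingestion": {
                            "concentration": 1e-4,
                            "intake_rate": 100,
                            "exposure_factor": 0.2,
                            "body_weight": 80,
                        }
                    },
                    "modifiers": [
                        {
                            "factor": "natural",
                            "target_parameter": "intake_rate",
                            "action": "multiply",
                            "value": 1.5,
                            "scope": [["weeding", "sprang"]],
                        }
                    ],
                }
            )

    def test_unknown_top_level_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown top-level"):
            build_grid_from_config({"tasks": [], "seasons": [], "growers": []})

    def test_duplicate_cell_rejected(self, ingestion_baseline):
        cell = CellExposure(task="weeding", season="summer", exposure_factor=0.1)
        with pytest.raises(ValidationError, match="duplicate"):
            ScenarioGrid(
                tasks=("weeding",),
                seasons=("summer",),
                baseline_ingestion=ingestion_baseline,
                schedules=(cell, cell),
            )

    def test_ingestion_requires_exposure_factor_value(self, ingestion_baseline):
        grid = ScenarioGrid(
            tasks=("weeding",),
            seasons=("summer",),
            baseline_ingestion=ingestion_baseline,
            schedules=(CellExposure(task="weeding", season="summer", exposure_frequency=60.0),),
        )
        with pytest.raises(ConfigurationError, match="exposure_factor"):
            resolve_cell(grid, "weeding", "summer", "ingestion")
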