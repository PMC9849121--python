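"""Tests for cascade evaluation, aggregation and level comparison."""

import numpy as np
import pytest

from mesodose import (
    CascadeLevel,
    ConfigurationError,
    DoseResult,
    FactorModifier,
    ReceptorProfile,
    ScenarioGrid,
    aggregate,
    benchmark,
    compare_levels,
    run_cascade,
    run_level,
)


class TestAggregate:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        tasks = [f"task_{i}" for i in range(4)]
        seasons = ["spring", "summer", "fall", "winter"]
        cells = {
            (t, s): DoseResult(value=float(rng.uniform(0, 1e-4)), pathway="ingestion")
            for t in tasks
            for s in seasons
        }
        subtotals, total = aggregate(cells, season_order=seasons)
        for season in seasons:
            brute = 0.0
            for t in tasks:
                for s in seasons:
                    if s == season:
                        brute += cells[(t, s)].value
            assert subtotals[season] == brute  # bit-identical
        assert total == sum(subtotals.values())

    def test_empty_cell_map(self):
        subtotals, total = aggregate({})
        assert subtotals == {} and total == 0.0

    def test_mixed_pathways_rejected(self):
        cells = {
            ("a", "s"): DoseResult(value=1.0, pathway="ingestion"),
            ("b", "s"): DoseResult(value=1.0, pathway="dermal"),
        }
        with pytest.raises(ValueError, match="mix"):
            aggregate(cells)


class TestCompareLevels:
    def test_sixteen_percent_example(self):
        a = _report(5.08e-5)
        b = _report(4.38e-5)
        cmp = compare_levels(a, b)
        assert round(cmp.percent_difference) == 16

    def test_two_orders_of_magnitude_example(self):
        cmp = compare_levels(_report(3.82e-7), _report(8.2e-9))
        assert cmp.magnitude_gap == 2  # log10 ~ 1.67 rounds to 2

    def test_identical_reports(self):
        cmp = compare_levels(_report(1e-5), _report(1e-5))
        assert cmp.percent_difference == 0.0
        assert cmp.ratio == 1.0
        assert cmp.magnitude_gap == 0

    def test_zero_denominator_flagged_not_raised(self):
        cmp = compare_levels(_report(1e-5), _report(0.0))
        assert not cmp.defined
        assert cmp.percent_difference is None and cmp.ratio is None

    def test_different_pathways_rejected(self):
        with pytest.raises(ValueError):
            compare_levels(_report(1.0), _report(1.0, pathway="dermal"))


def _report(total, pathway="ingestion"):
    cells = {("all", "annual"): DoseResult(value=total, pathway=pathway)}
    subtotals, annual = aggregate(cells, season_order=["annual"])
    from mesodose.cascade import DoseReport

    return DoseReport(
        level=CascadeLevel("traditional", pathway),
        cells=cells,
        seasonal_subtotals=subtotals,
        annual_total=annual,
    )


class TestRunLevel:
    def test_traditional_collapses_to_single_baseline_cell(self, small_grid):
        report = run_level(small_grid, CascadeLevel("traditional", "ingestion"))
        assert set(report.cells) == {("all", "annual")}
        baseline = small_grid.baseline_ingestion
        expected = (
            baseline.concentration
            * baseline.intake_rate
            * baseline.exposure_factor
            / baseline.body_weight
        )
        assert report.annual_total == pytest.approx(expected, rel=1e-12)

    def test_all_zero_schedule_grid_totals_zero(self, ingestion_baseline):
        grid = ScenarioGrid(
            tasks=("weeding",), seasons=("summer",), baseline_ingestion=ingestion_baseline
        )
        for level_id in ("meso_activity", "plus_timing", "plus_environment"):
            report = run_level(grid, CascadeLevel(level_id, "ingestion"))
            assert report.annual_total == 0.0

    def test_receptor_level_requires_receptor(self, small_grid):
        with pytest.raises(ConfigurationError, match="receptor"):
            run_level(small_grid, CascadeLevel("plus_receptor", "ingestion"))

    def test_report_additivity_invariants(self, small_grid):
        report = run_level(small_grid, CascadeLevel("plus_environment", "ingestion"))
        for season in small_grid.seasons:
            cell_sum = sum(
                res.value for (t, s), res in report.cells.items() if s == season
            )
            assert report.seasonal_subtotals[season] == cell_sum
        assert report.annual_total == sum(report.seasonal_subtotals.values())

    def test_determinism(self, small_grid):
        r1 = run_level(small_grid, CascadeLevel("plus_environment", "dermal"))
        r2 = run_level(small_grid, CascadeLevel("plus_environment", "dermal"))
        assert r1.cells == r2.cells and r1.annual_total == r2.annual_total


class TestLevelNesting:
    def test_dropping_environment_reproduces_timing_level(self):
        env_grid = benchmark("model_7").runs[0].grid
        timing_grid = benchmark("model_5").runs[0].grid
        at_timing = run_level(env_grid, CascadeLevel("plus_timing", "ingestion"))
        reference = run_level(timing_grid, CascadeLevel("plus_timing", "ingestion"))
        assert at_timing.cells == reference.cells

    def test_dropping_receptor_reproduces_environment_level(self):
        grower_grid = benchmark("grower_A").runs[0].grid
        env_grid = benchmark("model_7").runs[0].grid
        at_env = run_level(grower_grid, CascadeLevel("plus_environment", "ingestion"))
        reference = run_level(env_grid, CascadeLevel("plus_environment", "ingestion"))
        assert at_env.annual_total == pytest.approx(reference.annual_total, rel=1e-12)

    def test_wet_season_adherence_ratio_across_tasks(self):
        report = run_level(
            benchmark("model_8").runs[0].grid, CascadeLevel("plus_environment", "dermal")
        )
        for task in ("transplanting", "harvesting", "watering"):
            spring = report.cells[(task, "spring")].value
            summer = report.cells[(task, "summer")].value
            if summer > 0:
                assert spring == pytest.approx(summer * 0.2 / 0.07, rel=1e-9)


class TestRunCascade:
    def test_reports_in_level_order_with_comparisons(self, small_grid):
        result = run_cascade(small_grid, "ingestion")
        level_ids = [r.level.level_id for r in result.reports]
        assert level_ids == ["traditional", "meso_activity", "plus_timing", "plus_environment"]
        assert set(result.comparisons) == {"meso_activity", "plus_timing", "plus_environment"}

    def test_receptor_level_included_when_receptor_present(self, small_grid):
        grid = small_grid.model_copy(
            update={"receptor": ReceptorProfile(label="g", body_weight=60.0)}
        )
        result = run_cascade(grid, "dermal")
        assert result.reports[-1].level.level_id == "plus_receptor"
        assert result.reports[-1].receptor_label == "g"

    def test_unknown_level_rejected(self, small_grid):
        with pytest.raises(ConfigurationError, match="unknown"):
            run_cascade(small_grid, "ingestion", levels=["micro_activity"])

    def test_monotone_under_amplifying_modifier(self, small_grid):
        amplifier = FactorModifier(
            factor="behavioral", target_parameter="intake_rate", action="multiply", value=1.7
        )
        boosted = small_grid.model_copy(
            update={"modifiers": small_grid.modifiers + (amplifier,)}
        )
        base = run_cascade(small_grid, "ingestion")
        more = run_cascade(boosted, "ingestion")
        for ref, amp in zip(base.reports, more.reports):
            assert amp.annual_total >= ref.annual_total

    def test_all_zero_dermal_cascade(self, dermal_baseline):
        zero_baseline = dermal_baseline.model_copy(update={"exposure_frequency": 0.0})
        grid = ScenarioGrid(
            tasks=("weeding",), seasons=("summer",), baseline_dermal=zero_baseline
        )
        result = run_cascade(grid, "dermal")
        assert all(r.annual_total == 0.0 for r in result.reports)
        assert all(not cmp.defined for cmp in result.comparisons.values())
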