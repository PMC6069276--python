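import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluokin.errors import ConfigurationError, DomainError
from fluokin.exposure import (
    ExposureScenario,
    ExposureSource,
    absorbed_intake,
    equivalent_water_concentration,
    intake_to_absorbed,
    load_reference_intakes,
    scenario_preset,
    source_contributions,
    to_infusion_rate,
    total_absorbed_tdfi,
)


def _scenario(sources, bw=16.0, age=4.0, label="test"):
    return ExposureScenario(label=label, age_years=age, body_weight=bw, sources=sources)


WATER_04 = ExposureSource("water", water_l_day=0.442, concentration_mg_l=0.7)


class TestEquivalentWaterConcentration:
    def test_ontario_population_mix(self):
        # 70% fluoridated at 0.7, the rest at the 0.05 detection limit
        assert equivalent_water_concentration(0.70, 0.7, 0.05) == pytest.approx(0.505)

    def test_full_coverage_returns_fluoridated(self):
        assert equivalent_water_concentration(1.0, 0.7, 0.05) == 0.7

    def test_sparse_coverage_mix(self):
        assert equivalent_water_concentration(0.025, 0.7, 0.05) == pytest.approx(0.06625)

    @pytest.mark.parametrize("coverage", [-0.01, 1.01])
    def test_coverage_domain(self, coverage):
        with pytest.raises(DomainError):
            equivalent_water_concentration(coverage, 0.7, 0.05)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
    )
    def test_bounded_by_extremes(self, coverage, hi, lo):
        value = equivalent_water_concentration(coverage, hi, lo)
        assert min(hi, lo) - 1e-12 <= value <= max(hi, lo) + 1e-12


class TestAbsorbedIntake:
    def test_toothpaste_fully_available(self):
        src = ExposureSource("toothpaste", intake_ug_kg_day=40.0)
        assert absorbed_intake(src, 16.0) == pytest.approx(40.0)

    def test_diet_forty_percent(self):
        src = ExposureSource("diet", intake_ug_kg_day=21.0)
        assert absorbed_intake(src, 16.0) == pytest.approx(8.4)

    def test_water_volume_times_concentration(self):
        # 0.442 L/day at 0.7 mg/L, 16 kg, bioavailability 0.83
        assert absorbed_intake(WATER_04, 16.0) == pytest.approx(16.050125)

    def test_water_missing_concentration_rejected(self):
        src = ExposureSource("water", water_l_day=0.5)
        with pytest.raises(ConfigurationError, match="concentration"):
            absorbed_intake(src, 16.0)

    def test_bioavailability_override(self):
        src = ExposureSource("diet", intake_ug_kg_day=10.0, bioavailability=1.0)
        assert absorbed_intake(src, 16.0) == pytest.approx(10.0)

    def test_absorbed_never_exceeds_ingested(self):
        for medium, intake in [("diet", 30.0), ("soil", 5.0), ("toothpaste", 40.0)]:
            src = ExposureSource(medium, intake_ug_kg_day=intake)
            assert absorbed_intake(src, 16.0) <= intake


class TestTotalAbsorbedTdfi:
    def test_reference_four_year_old(self):
        scenario = scenario_preset("ontario-s1", 4.0)
        assert total_absorbed_tdfi(scenario) == pytest.approx(64.936125)

    def test_zero_sources_zero_total(self):
        scenario = _scenario(
            (
                ExposureSource("diet", intake_ug_kg_day=0.0),
                ExposureSource("water", water_l_day=0.0, concentration_mg_l=0.0),
            )
        )
        assert total_absorbed_tdfi(scenario) == 0.0

    def test_linearity_under_uniform_doubling(self):
        scenario = scenario_preset("ontario-s1", 4.0)
        doubled = scenario.scaled({m: 2.0 for m in ("water", "diet", "toothpaste", "soil", "air")})
        assert total_absorbed_tdfi(doubled) == pytest.approx(
            2 * total_absorbed_tdfi(scenario)
        )


class TestSourceContributions:
    def test_water_share_quarter_at_fluoridated_tap(self):
        shares = source_contributions(scenario_preset("ontario-s1", 4.0))
        assert shares["water"] == pytest.approx(0.2472, abs=5e-4)
        assert round(shares["water"] * 100) == 25

    def test_shares_sum_to_one(self):
        shares = source_contributions(scenario_preset("quebec-s2", 8.0))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_source_gets_everything(self):
        scenario = _scenario(
            (
                ExposureSource("toothpaste", intake_ug_kg_day=40.0),
                ExposureSource("water", water_l_day=0.0, concentration_mg_l=0.0),
            )
        )
        shares = source_contributions(scenario)
        assert shares["toothpaste"] == pytest.approx(1.0)

    def test_invariant_under_uniform_scaling(self):
        scenario = scenario_preset("ontario-s1", 4.0)
        scaled = scenario.scaled({m: 3.0 for m in ("water", "diet", "toothpaste", "soil", "air")})
        a, b = source_contributions(scenario), source_contributions(scaled)
        for medium in a:
            assert a[medium] == pytest.approx(b[medium], rel=1e-12)

    def test_zero_total_undefined(self):
        scenario = _scenario(
            (ExposureSource("water", water_l_day=0.0, concentration_mg_l=0.0),)
        )
        with pytest.raises(DomainError, match="undefined"):
            source_contributions(scenario)


class TestIntakeToAbsorbed:
    @pytest.mark.parametrize(
        "intake, expected", [(0.05, 0.04), (0.1, 0.08), (0.2, 0.16)]
    )
    def test_aggregate_bioavailability(self, intake, expected):
        assert intake_to_absorbed(intake) == pytest.approx(expected)

    def test_identity_at_full_availability(self):
        assert intake_to_absorbed(0.123, 1.0) == pytest.approx(0.123)


class TestToInfusionRate:
    def test_reference_four_year_old_rate(self):
        assert to_infusion_rate(64.936125, 16.0) == pytest.approx(7.2151e-4, rel=1e-4)

    def test_zero_dose(self):
        assert to_infusion_rate(0.0, 16.0) == 0.0

    @given(
        st.floats(min_value=0.1, max_value=500),
        st.floats(min_value=5, max_value=80),
    )
    def test_round_trip(self, tdfi, bw):
        rate = to_infusion_rate(tdfi, bw)
        assert rate * 1440 * 1000 / bw == pytest.approx(tdfi, rel=1e-12)


class TestScenarioPresets:
    def test_scenario3_is_scenario2_without_diet(self):
        s2 = scenario_preset("quebec-s2", 4.0)
        s3 = scenario_preset("quebec-s3", 4.0)
        assert {s.medium for s in s2.sources} - {s.medium for s in s3.sources} == {"diet"}
        for medium in ("water", "toothpaste", "soil", "air"):
            a = next(s for s in s2.sources if s.medium == medium)
            b = next(s for s in s3.sources if s.medium == medium)
            assert a == b

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ConfigurationError, match="valid presets"):
            scenario_preset("atlantis", 4.0)

    def test_duplicate_media_rejected(self):
        with pytest.raises(ConfigurationError, match="more than once"):
            _scenario(
                (
                    ExposureSource("diet", intake_ug_kg_day=1.0),
                    ExposureSource("diet", intake_ug_kg_day=2.0),
                    WATER_04,
                )
            )

    def test_water_source_mandatory(self):
        with pytest.raises(ConfigurationError, match="water"):
            _scenario((ExposureSource("diet", intake_ug_kg_day=1.0),))

    def test_reference_intake_table_values(self):
        table = load_reference_intakes()
        row8 = table[table.age_years == 8].iloc[0]
        assert row8.water_l_day == pytest.approx(0.56)
        assert row8.toothpaste_ug_kg_day == pytest.approx(30.0)
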