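"""Domain types, validation and CSV round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import palytable as pt
from palytable import (
    AgeGroup,
    EconProfile,
    MortalitySchedule,
    PrevalenceRecord,
    SchemaError,
    ValidationError,
    annual_prob_from_band,
)
from palytable.io import load_econ, load_mortality, load_prevalence


class TestAgeGroup:
    def test_band_is_five_years_on_multiple_of_five(self):
        band = AgeGroup.from_lower(40)
        assert (band.lower, band.upper, band.midpoint) == (40, 44, 42)

    @pytest.mark.parametrize("lower,upper", [(40, 45), (41, 45), (43, 47)])
    def test_malformed_bands_rejected(self, lower, upper):
        with pytest.raises(ValidationError):
            AgeGroup(lower, upper)


class TestPrevalenceRecord:
    def test_missing_ci_defaults_to_point_estimate(self):
        rec = PrevalenceRecord("CHN", "upper_middle", AgeGroup(40, 44), 1000.0)
        assert rec.cases_lower == rec.cases_upper == 1000.0

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValidationError, match="lower <= point <= upper"):
            PrevalenceRecord(
                "CHN", "upper_middle", AgeGroup(40, 44), 1000.0, 1200.0, 800.0
            )

    def test_unknown_income_group_rejected(self):
        with pytest.raises(ValidationError, match="income group"):
            PrevalenceRecord("CHN", "high", AgeGroup(40, 44), 1000.0)

    def test_bounded_cases_selects_bound(self):
        rec = PrevalenceRecord(
            "CHN", "upper_middle", AgeGroup(40, 44), 1000.0, 800.0, 1200.0
        )
        assert rec.bounded_cases("point") == 1000.0
        assert rec.bounded_cases("lower") == 800.0
        assert rec.bounded_cases("upper") == 1200.0


class TestEconProfile:
    def test_employed_subset_of_active(self):
        EconProfile("X", 1000.0, 1e9, 0.62, 0.68)  # accepted
        with pytest.raises(ValidationError, match="exceeds"):
            EconProfile("X", 1000.0, 1e9, 0.70, 0.68)

    def test_nonpositive_gdp_rejected(self):
        with pytest.raises(ValidationError, match="gdp_per_capita"):
            EconProfile("X", 0.0, 1e9, 0.5, 0.6)


class TestLoaders:
    def test_prevalence_row_parses(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text(
            "country_id,income_group,age_lower,cases,cases_lower,cases_upper\n"
            "CHN,upper_middle,40,1000,800,1200\n"
        )
        (rec,) = load_prevalence(path)
        assert rec.age_group == AgeGroup(40, 44)
        assert rec.cases == 1000.0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text("country_id,age_lower,cases\nCHN,40,1000\n")
        with pytest.raises(SchemaError, match="income_group"):
            load_prevalence(path)

    def test_invalid_row_reports_row_index(self, tmp_path):
        path = tmp_path / "prev.csv"
        path.write_text(
            "country_id,income_group,age_lower,cases,cases_lower,cases_upper\n"
            "CHN,upper_middle,40,1000,800,1200\n"
            "IND,lower_middle,40,1000,1200,800\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            load_prevalence(path)

    def test_mortality_banded_layout_expands_to_annual(self, tmp_path):
        path = tmp_path / "mort.csv"
        path.write_text("country_id,age_lower,q5\nX,40,0.04879\n")
        (sched,) = load_mortality(path)
        assert set(sched.q) == set(range(40, 45))
        # solve 1 - (1-q)^5 = 0.04879
        assert sched.q[42] == pytest.approx(0.009953, rel=1e-3)

    def test_mortality_gap_names_missing_age(self, tmp_path):
        path = tmp_path / "mort.csv"
        rows = [f"X,{age},0.01" for age in range(40, 65) if age != 52]
        path.write_text("country_id,age,q\n" + "\n".join(rows) + "\n")
        with pytest.raises(ValidationError, match="52"):
            load_mortality(path, min_age=40)

    def test_mortality_probability_out_of_range(self, tmp_path):
        path = tmp_path / "mort.csv"
        path.write_text("country_id,age,q\nX,40,1.5\n")
        with pytest.raises(ValidationError, match="outside"):
            load_mortality(path)

    def test_zero_mortality_schedule_is_valid(self, tmp_path):
        path = tmp_path / "mort.csv"
        rows = [f"X,{age},0.0" for age in range(40, 65)]
        path.write_text("country_id,age,q\n" + "\n".join(rows) + "\n")
        (sched,) = load_mortality(path, min_age=40)
        assert all(v == 0.0 for v in sched.q.values())


class TestRoundTrips:
    def test_prevalence_roundtrip_identity(self, synth_ds, tmp_path):
        path = tmp_path / "prev.csv"
        pt.write_prevalence(synth_ds.prevalence, path)
        back = load_prevalence(path)
        assert len(back) == len(synth_ds.prevalence)
        for a, b in zip(synth_ds.prevalence, back):
            assert a.country_id == b.country_id
            assert a.age_group == b.age_group
            for f in ("cases", "cases_lower", "cases_upper"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)

    def test_econ_roundtrip_identity(self, synth_ds, tmp_path):
        path = tmp_path / "econ.csv"
        pt.write_econ(synth_ds.econ, path)
        back = load_econ(path)
        for a, b in zip(synth_ds.econ, back):
            assert a.country_id == b.country_id
            for f in (
                "gdp_per_capita",
                "gdp_total",
                "employment_ratio",
                "labor_participation",
            ):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)

    def test_mortality_roundtrip_identity(self, synth_ds, tmp_path):
        path = tmp_path / "mort.csv"
        pt.write_mortality(synth_ds.mortality, path)
        back = {s.country_id: s for s in load_mortality(path)}
        for sched in synth_ds.mortality:
            got = back[sched.country_id]
            assert set(got.q) == set(sched.q)
            for age, q in sched.q.items():
                assert got.q[age] == pytest.approx(q, rel=1e-12)


class TestAnnualProbFromBand:
    @pytest.mark.parametrize("q5,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_bands(self, q5, expected):
        assert annual_prob_from_band(q5, 5) == expected

    def test_solves_the_band_identity(self):
        q = annual_prob_from_band(0.05, 5)
        assert (1 - q) ** 5 == pytest.approx(0.95, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        q5=st.floats(min_value=0.0, max_value=0.999),
        width=st.integers(min_value=1, max_value=10),
    )
    def test_composition_recovers_band_probability(self, q5, width):
        q = annual_prob_from_band(q5, width)
        assert 1 - (1 - q) ** width == pytest.approx(q5, abs=1e-12)
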