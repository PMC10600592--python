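"""Annual-cycle engine: single-year arithmetic, full runs, and invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import draburden as d
from draburden.errors import ConfigurationError, DomainError
from draburden.uncertainty import round_half_up


def oracle_year(cases, inc_major, inc_minor, mort_amp, mort_nonamp):
    """Independent single-expression arithmetic oracle for one year."""
    return (
        cases * inc_major / 1e5,
        cases * inc_minor / 1e5,
        (cases * inc_major / 1e5 + cases * inc_minor / 1e5) * mort_amp / 1e3,
        (cases - (cases * inc_major / 1e5 + cases * inc_minor / 1e5)) * mort_nonamp / 1e3,
    )


rate_strategy = st.builds(
    d.TransitionRates,
    incidence_major=st.floats(min_value=0, max_value=500),
    incidence_minor=st.floats(min_value=0, max_value=500),
    mortality_amputee=st.floats(min_value=0, max_value=500),
    mortality_nonamputee=st.floats(min_value=0, max_value=500),
)


class TestProjectYear:
    def test_reference_base_year(self, rates):
        p = d.project_year(54805, rates, year=2022)
        assert round_half_up(p.incident_major) == 52
        assert round_half_up(p.incident_minor) == 77
        assert p.rounded_total_dra == 129
        assert round_half_up(p.deaths_amputee) == 11
        assert round_half_up(p.deaths_nonamputee) == 1302

    def test_reference_base_year_with_reduced_incidence(self, rates):
        reduced = d.TransitionRates(
            incidence_major=rates.incidence_major * 0.8,
            incidence_minor=rates.incidence_minor * 0.8,
            mortality_amputee=rates.mortality_amputee,
            mortality_nonamputee=rates.mortality_nonamputee,
        )
        p = d.project_year(54805, reduced, year=2022)
        assert round_half_up(p.incident_major) == 42
        assert round_half_up(p.incident_minor) == 61
        assert p.rounded_total_dra == 103
        assert round_half_up(p.deaths_amputee) == 9
        assert round_half_up(p.deaths_nonamputee) == 1302

    def test_zero_population(self, rates):
        p = d.project_year(0.0, rates)
        assert p.incident_major == p.incident_minor == 0
        assert p.deaths_amputee == p.deaths_nonamputee == 0

    def test_per_100k_definition(self, rates):
        p = d.project_year(100_000, rates)
        assert p.incident_major == pytest.approx(rates.incidence_major)
        assert p.incident_minor == pytest.approx(rates.incidence_minor)

    def test_negative_population_rejected(self, rates):
        with pytest.raises(DomainError):
            d.project_year(-1.0, rates)

    @given(cases=st.floats(min_value=0, max_value=1e7), rates=rate_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_conservation_exact(self, cases, rates):
        p = d.project_year(cases, rates)
        assert p.incident_major + p.incident_minor == p.total_dra
        assert p.total_dra + p.non_amputees == pytest.approx(cases, rel=1e-15, abs=0)

    @given(
        cases=st.floats(min_value=0, max_value=1e6),
        k=st.floats(min_value=0.1, max_value=10),
        rates=rate_strategy,
    )
    @settings(derandomize=True, max_examples=200)
    def test_homogeneity_in_population_size(self, cases, k, rates):
        p1, pk = d.project_year(cases, rates), d.project_year(k * cases, rates)
        for attr in ("incident_major", "incident_minor", "deaths_amputee", "deaths_nonamputee"):
            assert getattr(pk, attr) == pytest.approx(k * getattr(p1, attr), rel=1e-9)

    @given(cases=st.floats(min_value=0, max_value=1e7), rates=rate_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_oracle_equivalence_single_year(self, cases, rates):
        p = d.project_year(cases, rates)
        major, minor, d_amp, d_non = oracle_year(
            cases, rates.incidence_major, rates.incidence_minor,
            rates.mortality_amputee, rates.mortality_nonamputee,
        )
        assert p.incident_major == major
        assert p.incident_minor == minor
        assert p.deaths_amputee == d_amp
        assert p.deaths_nonamputee == d_non


class TestRunProjection:
    def test_constant_scenario_reference_totals(self, constant_projection):
        totals = {y: constant_projection.year(y).rounded_total_dra for y in (2022, 2030, 2045)}
        assert totals == {2022: 129, 2030: 169, 2045: 227}

    def test_decline_scenario_reference_totals(self, decline_projection):
        totals = {y: decline_projection.year(y).rounded_total_dra for y in (2022, 2030, 2045)}
        assert totals == {2022: 103, 2030: 91, 2045: 61}

    def test_zero_incidence_gives_only_background_mortality(self, case_series):
        rates = d.TransitionRates(0, 0, 86.8, 23.81)
        proj = d.run_projection(case_series, rates)
        for p in proj:
            assert p.total_dra == 0
            assert p.deaths_nonamputee == pytest.approx(p.cases * 23.81 / 1000)

    def test_monotone_under_constant_rates(self, constant_projection):
        cols = ("incident_major", "incident_minor", "deaths_amputee", "deaths_nonamputee")
        previous = None
        for p in constant_projection:
            if previous is not None:
                for attr in cols:
                    assert getattr(p, attr) >= getattr(previous, attr)
            previous = p

    def test_years_are_independent_cycles(self, case_series, rates):
        """Each year equals a standalone single-year run on its case count."""
        proj = d.run_projection(case_series, rates)
        for year, count in case_series:
            standalone = d.project_year(count, rates, year=year)
            assert proj.year(year) == standalone

    def test_oracle_equivalence_full_run(self, case_series, rates, alahsa_config):
        scenario = alahsa_config.scenarios["mixed-decline-annualized"]
        proj = d.run_projection(case_series, rates, scenario)
        for year, count in case_series:
            t = (year - 2022) / 3
            major, minor, d_amp, d_non = oracle_year(
                count,
                rates.incidence_major * 0.8 * 0.8**t,
                rates.incidence_minor * 0.8 * 0.9**t,
                rates.mortality_amputee,
                rates.mortality_nonamputee,
            )
            p = proj.year(year)
            assert p.incident_major == pytest.approx(major, rel=1e-13)
            assert p.incident_minor == pytest.approx(minor, rel=1e-13)
            assert p.deaths_amputee == pytest.approx(d_amp, rel=1e-13)
            assert p.deaths_nonamputee == pytest.approx(d_non, rel=1e-13)

    def test_non_consecutive_years_rejected(self, rates):
        years = (d.project_year(10, rates, year=2022), d.project_year(10, rates, year=2024))
        with pytest.raises(ConfigurationError):
            d.ProjectionSeries(years=years)


class TestTransitionRates:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"incidence_major": -1},
            {"incidence_minor": -1},
            {"mortality_amputee": -1},
            {"mortality_nonamputee": -1},
            {"incidence_major": 60_000, "incidence_minor": 60_000},
            {"mortality_amputee": 1_000},
        ],
    )
    def test_invalid_rates_rejected(self, kwargs):
        base = dict(incidence_major=94.82, incidence_minor=139.97,
                    mortality_amputee=86.8, mortality_nonamputee=23.81)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            d.TransitionRates(**base)
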