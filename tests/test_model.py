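"""The delayed-diagnosis mortality model: closed form, grids, tumor variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncodelay import (
    RiskParams,
    TumorSpec,
    build_schedule,
    datasets,
    excess_deaths_for_month,
    excess_deaths_series,
    death_rate_with_delay,
    scenario_grid,
    tumor_specific_excess,
)
from oncodelay.errors import ParameterError, ScenarioError, ScheduleError, ValidationError

UNIFORM = RiskParams(rd=0.41, hr=1.06)
RESOLUTION = (2020, 8)

#: Published monthly reduction fractions (March-July) and the matching
#: national missing counts at 31 833 new diagnoses/month.
FRACTIONS = datasets.PUBLISHED_DIP_PROFILE
NATIONAL_MISSING = {m: 31833 * f for m, f in FRACTIONS.items()}

risk_st = st.builds(
    RiskParams,
    rd=st.floats(0.01, 0.95),
    hr=st.floats(1.0, 1.5),
)


class TestDeathRateWithDelay:
    def test_no_delay_returns_baseline(self):
        assert death_rate_with_delay(RiskParams(rd=0.41, hr=1.27), 0) == pytest.approx(0.41)

    def test_unit_hazard_ratio_returns_baseline(self):
        assert death_rate_with_delay(RiskParams(rd=0.41, hr=1.0), 7) == pytest.approx(0.41)

    def test_three_month_delay_closed_form(self):
        # 1 - 0.59 ** (1.06 ** 3), evaluated independently to 5 decimals
        assert death_rate_with_delay(UNIFORM, 3) == pytest.approx(0.46657, abs=5e-6)

    def test_invalid_rd_rejected(self):
        with pytest.raises(ParameterError):
            RiskParams(rd=1.2, hr=1.06)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValidationError):
            death_rate_with_delay(UNIFORM, -1)

    @settings(derandomize=True, max_examples=60)
    @given(params=risk_st, n=st.floats(0, 24))
    def test_equals_survival_power_form(self, params, n):
        """RDdel = 1 - S**(HR**n) with S = 1 - RD, to machine precision."""
        expected = 1.0 - (1.0 - params.rd) ** (params.hr**n)
        assert death_rate_with_delay(params, n) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        params=st.builds(RiskParams, rd=st.floats(0.05, 0.9), hr=st.floats(1.001, 1.25)),
        n=st.floats(0.01, 8),
        dn=st.floats(0.1, 4),
    )
    def test_strictly_increasing_in_delay_and_hazard(self, params, n, dn):
        base = death_rate_with_delay(params, n)
        assert death_rate_with_delay(params, n + dn) > base
        steeper = RiskParams(rd=params.rd, hr=params.hr + 0.05)
        assert death_rate_with_delay(steeper, n) > base

    def test_approaches_one_for_long_delays(self):
        assert death_rate_with_delay(UNIFORM, 50) < 1.0
        assert death_rate_with_delay(UNIFORM, 200) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_bernoulli_agreement(self):
        """Closed form within 3 binomial SEs of a 1e5-draw simulation."""
        rng = np.random.default_rng(20200801)
        k = 100_000
        for n in (1, 3, 5):
            p = death_rate_with_delay(UNIFORM, n)
            deaths = rng.binomial(1, p, size=k).mean()
            se = math.sqrt(p * (1 - p) / k)
            assert abs(deaths - p) <= 3 * se


class TestExcessDeaths:
    def test_zero_missing_zero_excess(self):
        assert excess_deaths_for_month(0, UNIFORM, 4) == 0

    def test_may_shortfall_reproduces_published_value(self):
        n_missing = 31833 * 0.218
        assert excess_deaths_for_month(n_missing, UNIFORM, 3) == pytest.approx(393, abs=2)

    def test_single_month_delay_hand_value(self):
        # 1000 * (1 - 0.59 ** 1.06 - 0.41)
        assert excess_deaths_for_month(1000, UNIFORM, 1) == pytest.approx(18.4, abs=0.05)

    def test_negative_missing_rejected(self):
        with pytest.raises(ValidationError):
            excess_deaths_for_month(-5, UNIFORM, 1)

    @settings(derandomize=True, max_examples=40)
    @given(
        n_missing=st.floats(0, 1e5),
        scale=st.floats(0, 10),
        n=st.floats(0, 12),
        params=risk_st,
    )
    def test_linearity_in_missing_count(self, n_missing, scale, n, params):
        lhs = excess_deaths_for_month(scale * n_missing, params, n)
        rhs = scale * excess_deaths_for_month(n_missing, params, n)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestSchedule:
    def test_base_window_counts_back_from_resolution(self):
        schedule = build_schedule(NATIONAL_MISSING, RESOLUTION)
        assert [e.delay_months for e in schedule.entries] == [5, 4, 3, 2, 1]

    def test_extra_months_shift_uniformly(self):
        schedule = build_schedule(NATIONAL_MISSING, RESOLUTION, extra_months=2)
        assert [e.delay_months for e in schedule.entries] == [7, 6, 5, 4, 3]

    def test_single_month_before_resolution(self):
        schedule = build_schedule({(2020, 7): 100.0}, RESOLUTION)
        assert schedule.entries[0].delay_months == 1

    def test_resolution_before_window_rejected(self):
        with pytest.raises(ScheduleError):
            build_schedule(NATIONAL_MISSING, (2020, 6))

    def test_series_input_scaled_by_baseline(self, network_series):
        schedule = build_schedule(network_series, RESOLUTION, baseline=31833)
        assert schedule.total_missing == pytest.approx(
            sum(31833 * f for f in network_series.fractions)
        )


class TestExcessSeries:
    def test_national_per_month_and_total(self):
        est = excess_deaths_series(build_schedule(NATIONAL_MISSING, RESOLUTION), UNIFORM)
        values = [v for _, v in est.per_month]
        for got, published in zip(values, [42, 502, 393, 20, 67]):
            assert got == pytest.approx(published, abs=2)
        assert est.total == pytest.approx(1024, rel=0.015)

    def test_unit_hazard_ratio_gives_all_zeros(self):
        est = excess_deaths_series(
            build_schedule(NATIONAL_MISSING, RESOLUTION), RiskParams(rd=0.41, hr=1.0)
        )
        assert all(v == pytest.approx(0, abs=1e-9) for _, v in est.per_month)

    @pytest.mark.parametrize("hr,published", [(1.02, 338), (1.1, 1715)])
    def test_hazard_ratio_sweep_totals(self, hr, published):
        est = excess_deaths_series(
            build_schedule(NATIONAL_MISSING, RESOLUTION), RiskParams(rd=0.41, hr=hr)
        )
        assert est.total == pytest.approx(published, rel=0.015)

    def test_total_is_sum_of_months(self):
        est = excess_deaths_series(build_schedule(NATIONAL_MISSING, RESOLUTION), UNIFORM)
        assert est.total == pytest.approx(sum(v for _, v in est.per_month), rel=1e-12)


@pytest.fixture(scope="module")
def grids():
    return {
        hr: scenario_grid(FRACTIONS, RiskParams(rd=0.41, hr=hr), RESOLUTION,
                          baseline=31833)
        for hr in (1.02, 1.06, 1.1)
    }


@pytest.fixture(scope="module")
def weights(network_series):
    return {
        label: m / network_series.missing_total
        for label, m in zip(network_series.month_labels(), network_series.missing)
    }


class TestScenarioGrid:
    def test_base_cell_equals_series_total_exactly(self, grids):
        est = excess_deaths_series(build_schedule(NATIONAL_MISSING, RESOLUTION), UNIFORM)
        assert grids[1.06].cell(0, 0.0) == est.total

    @pytest.mark.parametrize(
        "a,p,published",
        [(1, 0.0, 1381), (0, 0.05, 1478), (4, 0.15, 5791)],
    )
    def test_published_cells(self, grids, a, p, published):
        assert grids[1.06].cell(a, p) == pytest.approx(published, rel=0.015)

    def test_monotone_along_both_axes_every_panel(self, grids):
        for grid in grids.values():
            assert np.all(np.diff(grid.cells, axis=0) >= 0)
            assert np.all(np.diff(grid.cells, axis=1) >= 0)

    def test_shifted_fraction_reaching_one_rejected(self):
        with pytest.raises(ScenarioError, match="2020"):
            scenario_grid({(2020, 4): 0.8}, UNIFORM, RESOLUTION,
                          p_values=(0.0, 0.25), baseline=31833)

    def test_net_increase_months_contribute_zero(self):
        grid = scenario_grid({(2020, 6): -0.05, (2020, 7): 0.10}, UNIFORM,
                             RESOLUTION, a_values=(0,), p_values=(0.0,),
                             baseline=1000)
        only_july = excess_deaths_series(
            build_schedule({(2020, 7): 100.0}, RESOLUTION), UNIFORM
        ).total
        assert grid.cell(0, 0.0) == pytest.approx(only_july)


class TestTumorSpecific:
    def test_rd_derived_from_national_rates(self):
        specs = {s.label: s for s in datasets.tumor_specs()}
        assert specs["lung"].rd == pytest.approx(10356 / 15132)
        assert specs["breast"].rd == pytest.approx(12146 / 58547)

    def test_breast_specific_estimate(self, weights):
        specs = [s for s in datasets.tumor_specs() if s.label == "breast"]
        comp = tumor_specific_excess(specs, weights, RESOLUTION)
        assert specs[0].missing == 1921
        assert comp.specific_total == pytest.approx(88, rel=0.05)

    def test_five_tumor_uniform_total(self, weights):
        comp = tumor_specific_excess(datasets.tumor_specs(), weights, RESOLUTION)
        assert comp.uniform_total == pytest.approx(132, rel=0.05)

    def test_lung_specific_in_documented_range_not_published_value(self, weights):
        """The published lung value (14) is unreachable under proportional
        monthly weighting; the computed value sits in [5, 10]."""
        comp = tumor_specific_excess(datasets.tumor_specs(), weights, RESOLUTION)
        lung = {row[0]: row[3] for row in comp.per_tumor}["lung"]
        assert 5 <= lung <= 10

    def test_unit_hazard_ratio_tumor_gives_zero(self, weights):
        spec = TumorSpec("x", 1000, 300, 1.0, 500, 400)
        comp = tumor_specific_excess([spec], weights, RESOLUTION)
        assert comp.specific_total == pytest.approx(0, abs=1e-9)

    def test_uniform_params_collapse_the_two_columns(self, weights):
        specs = [
            TumorSpec(f"t{i}", 1000, 410, 1.06, 600 + 50 * i, 400)
            for i in range(3)
        ]
        comp = tumor_specific_excess(specs, weights, RESOLUTION)
        assert comp.specific_total == comp.uniform_total
        for _, _, uni, tum in comp.per_tumor:
            assert uni == tum

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            tumor_specific_excess(datasets.tumor_specs(), {(2020, 4): 0.5}, RESOLUTION)
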