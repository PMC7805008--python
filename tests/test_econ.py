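import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from airburden import econ
from airburden.errors import DomainError, ValidationError
from airburden.types import EconomyParams, LifeTable


def geometric_pv(y0: float, g: float, r: float, T: int) -> float:
    """Independent closed form: y0 Σ_{t=0}^{T-1} ρ^t, ρ = (1+g)/(1+r)."""
    rho = (1.0 + g) / (1.0 + r)
    if rho == 1.0:
        return y0 * T
    return y0 * (1.0 - rho**T) / (1.0 - rho)


class TestOutputPerWorker:
    def test_direct_arithmetic(self, simple_economy):
        # 0.5 × 1000 M$ / 100 000 workers = 5000 $/worker-year
        assert econ.output_per_worker(simple_economy) == pytest.approx(5000.0)

    def test_linear_in_gdp(self, simple_economy):
        doubled = dataclasses.replace(simple_economy, gdp=2 * simple_economy.gdp)
        assert econ.output_per_worker(doubled) == pytest.approx(
            2 * econ.output_per_worker(simple_economy)
        )


class TestExpectedOutput:
    def test_full_employment_no_growth(self, simple_economy, full_employment):
        y0 = econ.output_per_worker(simple_economy)
        for t in (0, 5, 30):
            assert econ.expected_output(40, t, simple_economy, full_employment) == pytest.approx(y0)

    def test_nonmarket_share_when_not_working(self, simple_economy, grid, full_employment):
        from airburden.types import EmploymentProfile

        idle = EmploymentProfile(e=np.zeros(grid.n_groups), age_grid=grid)
        eco = dataclasses.replace(simple_economy, growth_rate=0.04)
        y0 = econ.output_per_worker(eco)
        got = econ.expected_output(40, 3, eco, idle)
        assert got == pytest.approx(0.3 * y0 * 1.04**3)

    def test_zero_below_working_age(self, simple_economy, full_employment):
        assert econ.expected_output(10, 0, simple_economy, full_employment) == 0.0

    def test_zero_at_horizon(self, simple_economy, full_employment):
        assert econ.expected_output(65, 0, simple_economy, full_employment) == 0.0

    def test_negative_t_rejected(self, simple_economy, full_employment):
        with pytest.raises(DomainError):
            econ.expected_output(40, -1, simple_economy, full_employment)

    def test_growth_applies_from_t1(self, simple_economy, full_employment):
        eco = dataclasses.replace(simple_economy, growth_rate=0.05)
        y0 = econ.output_per_worker(eco)
        assert econ.expected_output(40, 0, eco, full_employment) == pytest.approx(y0)
        assert econ.expected_output(40, 1, eco, full_employment) == pytest.approx(y0 * 1.05)


class TestOutputSchedule:
    def test_schedule_matches_pointwise(self, simple_economy, full_employment):
        sched = econ.build_output_schedule(simple_economy, full_employment)
        for age in (10, 17, 40, 64, 65, 80):
            for t in (0, 7):
                assert sched.expected(age, t) == pytest.approx(
                    econ.expected_output(age, t, simple_economy, full_employment)
                )


class TestSurvival:
    def test_t_zero(self, flat_life_table):
        assert econ.survival_probability(flat_life_table, 30, 0) == 1.0

    def test_ratio(self):
        l = np.linspace(100_000.0, 50_000.0, 101)
        lt = LifeTable(l=l)
        assert econ.survival_probability(lt, 0, 100) == pytest.approx(0.5)

    def test_flat_table_always_one(self, flat_life_table):
        for a in (0, 20, 64):
            assert econ.survival_probability(flat_life_table, a, 65 - a) == 1.0


class TestPvLostOutput:
    def test_two_undiscounted_worker_years(self, grid, full_employment, flat_life_table):
        eco = EconomyParams(
            gdp=1e-4, labour_share=0.5, employed_count=50.0, growth_rate=0.0,
            discount_rate=0.06, horizon_age=65,
        )
        # y0 = 0.5 * 100 $ / 50 = 1 $/worker-year
        assert econ.output_per_worker(eco) == pytest.approx(1.0)
        pv = econ.pv_lost_output(63, eco, full_employment, flat_life_table, discount_rate=0.0)
        assert pv == pytest.approx(2.0)

    def test_zero_at_and_beyond_horizon(self, simple_economy, full_employment, flat_life_table):
        assert econ.pv_lost_output(65, simple_economy, full_employment, flat_life_table) == 0.0
        assert econ.pv_lost_output(90, simple_economy, full_employment, flat_life_table) == 0.0

    def test_geometric_closed_form(self, full_employment, flat_life_table):
        eco = EconomyParams(
            gdp=20.0, labour_share=0.5, employed_count=100_000.0,
            growth_rate=0.05, discount_rate=0.06,
        )
        y0 = econ.output_per_worker(eco)
        a = 25
        pv = econ.pv_lost_output(a, eco, full_employment, flat_life_table)
        assert pv == pytest.approx(geometric_pv(y0, 0.05, 0.06, 65 - a), rel=1e-10)

    def test_child_death_carries_discounted_future_value(self, full_employment, flat_life_table, simple_economy):
        pv_child = econ.pv_lost_output(2, simple_economy, full_employment, flat_life_table)
        pv_entry = econ.pv_lost_output(15, simple_economy, full_employment, flat_life_table)
        assert 0 < pv_child < pv_entry
        # a child's PV is the at-entry PV discounted over the 13 years to working age
        r = simple_economy.discount_rate
        assert pv_child == pytest.approx(pv_entry / (1 + r) ** 13, rel=1e-10)

    def test_large_rate_limit_keeps_t0_term(self, full_employment, flat_life_table, simple_economy):
        pv = econ.pv_lost_output(40, simple_economy, full_employment, flat_life_table, discount_rate=1e6)
        t0 = econ.expected_output(40, 0, simple_economy, full_employment)
        assert pv == pytest.approx(t0, rel=1e-5)

    @settings(max_examples=60, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        r1=st.floats(0.01, 0.20), r2=st.floats(0.01, 0.20),
        g=st.floats(0.0, 0.10), a=st.integers(15, 63),
    )
    def test_pv_monotone_decreasing_in_rate(self, full_employment, flat_life_table, r1, r2, g, a):
        eco = EconomyParams(
            gdp=100.0, labour_share=0.5, employed_count=10_000.0,
            growth_rate=g, discount_rate=0.06,
        )
        lo, hi = sorted([r1, r2])
        pv_lo = econ.pv_lost_output(a, eco, full_employment, flat_life_table, discount_rate=lo)
        pv_hi = econ.pv_lost_output(a, eco, full_employment, flat_life_table, discount_rate=hi)
        assert pv_lo >= pv_hi - 1e-9 * max(pv_lo, 1.0)

    def test_pv_increasing_in_growth_and_horizon(self, full_employment, flat_life_table):
        base = EconomyParams(
            gdp=100.0, labour_share=0.5, employed_count=10_000.0,
            growth_rate=0.03, discount_rate=0.06,
        )
        faster = dataclasses.replace(base, growth_rate=0.06)
        longer = dataclasses.replace(base, horizon_age=70)
        pv = econ.pv_lost_output(40, base, full_employment, flat_life_table)
        assert econ.pv_lost_output(40, faster, full_employment, flat_life_table) > pv
        assert econ.pv_lost_output(40, longer, full_employment, flat_life_table) > pv


def _burden_rows(state="s1", risk="hap", age_start=40, deaths=100.0, yld=0.0):
    return pd.DataFrame(
        {
            "state_id": [state], "age_start": [age_start], "cause": ["copd"],
            "risk": [risk], "deaths": [deaths], "yll": [deaths * 20.0],
            "yld": [yld], "daly": [deaths * 20.0 + yld],
        }
    )


class TestMortalityLoss:
    def test_zero_deaths(self, simple_economy, full_employment, flat_life_table, grid):
        df = _burden_rows(deaths=0.0)
        assert econ.mortality_loss(df, simple_economy, full_employment, flat_life_table, grid) == 0.0

    def test_linearity(self, simple_economy, full_employment, flat_life_table, grid):
        one = econ.mortality_loss(_burden_rows(deaths=100.0), simple_economy, full_employment, flat_life_table, grid)
        two = econ.mortality_loss(_burden_rows(deaths=200.0), simple_economy, full_employment, flat_life_table, grid)
        assert two == pytest.approx(2 * one)

    def test_single_term_product_oracle(self, full_employment, flat_life_table, grid):
        # 100 deaths at one age with PV 5000 $ -> 0.5 M$
        eco = EconomyParams(
            gdp=1.0, labour_share=0.5, employed_count=100.0, growth_rate=0.0,
            discount_rate=0.06,
        )  # y0 = 5000 $
        df = _burden_rows(age_start=60, deaths=100.0)
        pv = econ.pv_lost_output(62, eco, full_employment, flat_life_table)
        got = econ.mortality_loss(df, eco, full_employment, flat_life_table, grid)
        assert got == pytest.approx(100.0 * pv / 1e6)
        # with r=0 that PV is exactly 3 years × 5000 $
        got0 = econ.mortality_loss(df, eco, full_employment, flat_life_table, grid, discount_rate=0.0)
        assert got0 == pytest.approx(100 * 3 * 5000 / 1e6)

    def test_mixed_states_rejected(self, simple_economy, full_employment, flat_life_table, grid):
        df = pd.concat([_burden_rows(state="a"), _burden_rows(state="b")])
        with pytest.raises(ValidationError):
            econ.mortality_loss(df, simple_economy, full_employment, flat_life_table, grid)


class TestMorbidityLoss:
    def test_one_yld_is_one_worker_year(self, simple_economy, full_employment, grid):
        df = _burden_rows(deaths=0.0, yld=1.0)
        got = econ.morbidity_loss(df, simple_economy, full_employment, grid)
        assert got == pytest.approx(econ.output_per_worker(simple_economy) / 1e6)

    def test_zero_yld(self, simple_economy, full_employment, grid):
        assert econ.morbidity_loss(_burden_rows(yld=0.0), simple_economy, full_employment, grid) == 0.0

    def test_product_oracle(self, full_employment, grid):
        # 1000 YLD at an age with expected output 2000 $ -> 2 M$
        eco = EconomyParams(
            gdp=0.4, labour_share=0.5, employed_count=100.0, growth_rate=0.0,
        )  # y0 = 2000 $
        df = _burden_rows(deaths=0.0, yld=1000.0)
        assert econ.morbidity_loss(df, eco, full_employment, grid) == pytest.approx(2.0)

    def test_invariant_to_discount_rate_and_life_table(self, panels, burden_table):
        p = panels[0]
        rows = burden_table.for_state_risk(p.state_id, "hap")
        a = econ.morbidity_loss(rows, p.economy, p.employment, p.age_grid)
        b_ = econ.morbidity_loss(rows, p.economy.with_rate(0.2), p.employment, p.age_grid)
        assert a == b_


class TestStateLossAndSensitivity:
    def test_total_is_sum_and_derived_fields(self, panels, burden_table):
        p = panels[0]
        res = econ.state_loss(p, burden_table, "ambient_pm")
        assert res.total_loss == pytest.approx(res.mortality_loss + res.morbidity_loss)
        assert res.pct_gdp == pytest.approx(res.total_loss / p.economy.gdp * 100)
        assert res.per_capita == pytest.approx(res.total_loss * 1e6 / p.total_population)

    def test_sensitivity_ordering(self, panels, burden_table):
        sens = econ.discount_sensitivity(panels, burden_table, [0.04, 0.06, 0.08])
        by_rate = sens.groupby("discount_rate")["mortality_loss"].sum()
        assert by_rate[0.04] > by_rate[0.06] > by_rate[0.08]
        morb = sens.groupby("discount_rate")["morbidity_loss"].sum()
        assert morb.nunique() == 1  # morbidity invariant to the rate

    def test_sensitivity_default_rate_matches_main_run(self, panels, burden_table):
        main = econ.losses_to_frame(econ.compute_losses(panels, burden_table, discount_rate=0.06))
        sens = econ.discount_sensitivity(panels, burden_table, [0.06]).drop(columns="discount_rate")
        pd.testing.assert_frame_equal(main, sens)

    def test_empty_rate_list_rejected(self, panels, burden_table):
        with pytest.raises(ValidationError):
            econ.discount_sensitivity(panels, burden_table, [])

    def test_rate_outside_unit_interval_rejected(self, panels, burden_table):
        with pytest.raises(DomainError):
            econ.discount_sensitivity(panels, burden_table, [1.5])

    def test_parameter_recovery_per_death_pv(self, panels, burden_table):
        """Dividing mortality loss by deaths recovers the PV schedule per age group."""
        p = panels[0]
        rows = burden_table.for_state_risk(p.state_id, "ambient_pm")
        sched = econ.pv_schedule(p)
        for age_start, group in rows.groupby("age_start"):
            deaths = group["deaths"].sum()
            if deaths <= 0:
                continue
            loss = econ.mortality_loss(group, p.economy, p.employment, p.life_table, p.age_grid)
            implied_pv = loss * 1e6 / deaths
            expected = sched[int(age_start)]
            assert implied_pv == pytest.approx(expected, rel=1e-9, abs=1e-12)
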