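"""Discounted cash-flow engine: REDD+ stances, yield curves, oil palm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from floodcarbon._util import round_half_away
from floodcarbon.economics import (
    HORIZON_YR,
    OilPalmModel,
    Scenario,
    annuity_factor,
    build_yield_curve,
    default_oilpalm_model,
    net_co2e_per_ha,
    npv,
    oilpalm_annual_npv,
    oilpalm_cashflows,
    redd_annual_npv,
    redd_cashflows,
)
from floodcarbon.plot_carbon import DomainError

COARSE_NET = (156 - 52) * 3.67  # landscape-average creditable CO2e/ha


class TestNpvCore:
    def test_matches_closed_form_annuity(self):
        ones = np.ones(25)
        for rate in (0.05, 0.08, 0.11, 0.14):
            assert npv(ones, rate) == pytest.approx(
                annuity_factor(rate, 25), rel=1e-9
            )

    def test_zero_rate_is_plain_sum(self):
        assert npv([3.0, 4.0, 5.0], 0.0) == pytest.approx(12.0)

    def test_single_payment_discounted_one_period(self):
        assert npv([110.0], 0.10) == pytest.approx(100.0)

    def test_empty_series_rejected(self):
        with pytest.raises(DomainError):
            npv([], 0.1)


class TestNetCo2e:
    def test_coarse_arithmetic(self):
        # class 3 mid-point vs full-capacity reference
        assert net_co2e_per_ha(3, 46.0) == pytest.approx(104 * 3.67)

    def test_negative_when_reference_exceeds_midpoint(self):
        assert net_co2e_per_ha(1, 46.0) < 0

    def test_zero_at_reference(self):
        assert net_co2e_per_ha(3, 150.0) == 0.0


class TestReddCashflows:
    def test_upfront_structure(self):
        sc = Scenario(carbon_price=3.0, stance="upfront")
        flows = redd_cashflows(COARSE_NET, sc)
        assert flows[0] == pytest.approx(COARSE_NET * 3.0 - 25.0)
        assert np.all(flows[1:] == -10.0)

    def test_staggered_zero_carbon_is_pure_cost(self):
        sc = Scenario(carbon_price=3.0, stance="staggered")
        flows = redd_cashflows(0.0, sc)
        assert flows[0] == -25.0
        assert np.all(flows[1:] == -10.0)

    def test_staggered_conserves_total_revenue(self):
        for stance in ("upfront", "staggered"):
            sc = Scenario(carbon_price=7.8, stance=stance)
            revenue = redd_cashflows(COARSE_NET, sc).sum() + 25 + 24 * 10
            assert revenue == pytest.approx(COARSE_NET * 7.8)

    @given(st.floats(1.0, 2000.0), st.floats(0.5, 50.0), st.floats(0.01, 0.3))
    def test_upfront_beats_staggered_for_positive_carbon(self, net, price, rate):
        up = redd_annual_npv(net, Scenario(price, "upfront", rate))
        stag = redd_annual_npv(net, Scenario(price, "staggered", rate))
        assert up > stag
        if stag > 0:
            assert 0 < stag / up < 1

    def test_linearity_in_price_with_zero_costs(self):
        sc1 = Scenario(carbon_price=5.0, establish_cost=0.0, run_cost=0.0)
        sc2 = Scenario(carbon_price=10.0, establish_cost=0.0, run_cost=0.0)
        assert redd_annual_npv(COARSE_NET, sc2) == pytest.approx(
            2 * redd_annual_npv(COARSE_NET, sc1), rel=1e-12
        )

    @given(st.floats(0.5, 50.0), st.floats(0.6, 50.0))
    def test_strictly_increasing_in_price(self, p1, dp):
        lo = redd_annual_npv(COARSE_NET, Scenario(p1))
        hi = redd_annual_npv(COARSE_NET, Scenario(p1 + dp))
        assert hi > lo

    def test_scenario_validation(self):
        with pytest.raises(DomainError):
            Scenario(carbon_price=-1.0)
        with pytest.raises(DomainError):
            Scenario(carbon_price=3.0, discount_rate=1.5)
        with pytest.raises(DomainError):
            Scenario(carbon_price=3.0, stance="quarterly")


class TestYieldCurve:
    @pytest.mark.parametrize(
        "capacity,mean", [(1.0, 21.92), (0.5, 10.96), (0.25, 5.48)]
    )
    def test_capacity_scaled_means(self, capacity, mean):
        curve = build_yield_curve(capacity)
        assert curve.mean() == pytest.approx(mean, abs=0.01)

    def test_shape_constraints(self):
        curve = build_yield_curve(1.0)
        assert curve.shape == (25,)
        assert np.all(curve[:2] == 0.0)  # immature years
        assert np.all(curve[7:11] == 30.0)  # peak plateau, years 8-11
        assert curve[-1] == pytest.approx(17.0)  # year 25
        assert np.all(np.diff(curve[10:]) < 0)  # post-peak decline

    def test_capacity_out_of_range(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(DomainError):
                build_yield_curve(bad)


class TestOilPalm:
    def test_zero_cost_constant_yield_closed_form(self):
        curve = tuple([10.0] * 25)
        model = OilPalmModel(
            capacity=1.0,
            yield_curve=curve,
            newplant_cost=0.0,
            general_charges=0.0,
            field_upkeep=0.0,
            harvest_cost_per_t=0.0,
        )
        expected = 10.0 * 178.0 * annuity_factor(0.11, 25) / 25
        assert oilpalm_annual_npv(model, 0.11) == pytest.approx(expected, rel=1e-12)

    def test_matches_hand_dcf_on_toy_schedule(self):
        """Engine output equals an independently coded year-by-year DCF."""
        curve = tuple([0.0, 5.0, 12.0, 20.0, 25.0] + [24.0] * 20)
        model = OilPalmModel(
            capacity=1.0,
            yield_curve=curve,
            newplant_cost=1000.0,
            general_charges=200.0,
            field_upkeep=300.0,
            harvest_cost_per_t=30.0,
            supplying_yr12=50.0,
        )
        rate = 0.09
        hand = 0.0
        for t, y in enumerate(curve, start=1):
            cash = y * 178.0 - 200.0 - 300.0 - 30.0 * y
            if t == 1:
                cash -= 1000.0 + 50.0
            if t == 2:
                cash -= 50.0
            hand += cash / (1 + rate) ** t
        assert oilpalm_annual_npv(model, rate) == pytest.approx(hand / 25, rel=1e-12)

    def test_wrong_length_curve_rejected(self):
        model = OilPalmModel(yield_curve=(1.0, 2.0, 3.0))
        with pytest.raises(DomainError):
            oilpalm_cashflows(model)

    @pytest.mark.parametrize(
        "capacity,expected", [(1.0, 594), (0.5, 129), (0.25, -109)]
    )
    def test_calibrated_defaults_reproduce_published_npvs(self, capacity, expected):
        model = default_oilpalm_model(capacity)
        assert round_half_away(oilpalm_annual_npv(model, 0.11)) == expected

    def test_quarter_capacity_unprofitable_at_all_rates(self):
        model = default_oilpalm_model(0.25)
        for rate in (0.05, 0.08, 0.11, 0.14):
            assert oilpalm_annual_npv(model, rate) < 0


def test_rounding_half_away_from_zero():
    assert round_half_away(408.72) == 409
    assert round_half_away(0.5) == 1
    assert round_half_away(-0.5) == -1
    assert round_half_away(416_123_500.5) == 416_123_501
    assert round_half_away(2.4999) == 2
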