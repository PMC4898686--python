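"""Discounted cash-flow models for REDD+ payments and oil-palm new plantings.

Both land uses are compared on annualized 25-year net present value
(NPV/25, USD per hectare per year).  Cash flows are end-of-year: the
year-1 flow is discounted by one full period, so

    NPV = sum_{t=1..T} a_t / (1+r)^t.

REDD+ revenue is the net creditable carbon (class mid-point minus the
oil-palm reference level, converted to CO2-equivalent at 3.67) times the
carbon price, paid either entirely upfront in year 1 or 50% upfront with
the remainder spread equally over years 2..25.  Costs are a year-1
establishment charge plus annual running costs.

Oil palm follows a new-planting schedule: land clearing in year 1, an
immature phase, yields peaking in years 8-11 and declining to year 25,
revenue from fresh fruit bunch (FFB) sales at a constant farm-gate
price, and estate cost components held constant across capacity classes
except for supplying (replacement of dead palms) in the first two years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .plot_carbon import CLASS_MIDPOINTS, DomainError

#: Molecular mass conversion from carbon to CO2-equivalent, as used in
#: carbon-market accounting (fixed at 3.67, not 44/12).
CO2E_FACTOR = 3.67

HORIZON_YR = 25

#: Carbon price scenarios, USD/MgCO2e: voluntary low / mid / high and a
#: compliance-market price.
DEFAULT_CARBON_PRICES = (3.0, 7.8, 15.0, 30.0)

#: Annual discount rates; 0.11 is the regional industry rate, the others
#: bracket it for sensitivity.
DEFAULT_DISCOUNT_RATES = (0.05, 0.08, 0.11, 0.14)

Stance = Literal["upfront", "staggered"]
STANCES: tuple[Stance, ...] = ("upfront", "staggered")


@dataclass(frozen=True)
class Scenario:
    """One REDD+ pricing/costing scenario.

    carbon_price   USD per MgCO2e
    stance         payment timing: all revenue in year 1 ("upfront") or
                   50% in year 1 with the rest equal over years 2..T
                   ("staggered")
    discount_rate  annual fraction
    establish_cost USD/ha, year 1 only
    run_cost       USD/ha, each of years 2..T
    """

    carbon_price: float
    stance: Stance = "upfront"
    discount_rate: float = 0.11
    horizon_yr: int = HORIZON_YR
    establish_cost: float = 25.0
    run_cost: float = 10.0
    co2e_factor: float = CO2E_FACTOR

    def __post_init__(self):
        if self.carbon_price <= 0:
            raise DomainError("carbon price must be positive")
        if not 0 < self.discount_rate < 1:
            raise DomainError("discount rate must be in (0, 1)")
        if self.horizon_yr < 1:
            raise DomainError("horizon must be at least one year")
        if self.stance not in STANCES:
            raise DomainError(f"unknown stance {self.stance!r}")


def npv(cashflows: Sequence[float], rate: float) -> float:
    """Present value of end-of-year cash flows indexed t = 1..T."""
    amounts = np.asarray(cashflows, dtype=float)
    if amounts.size == 0:
        raise DomainError("empty cash-flow series")
    if rate <= -1:
        raise DomainError("rate must exceed -1")
    t = np.arange(1, amounts.size + 1)
    return float(np.sum(amounts / (1.0 + rate) ** t))


def annuity_factor(rate: float, horizon_yr: int = HORIZON_YR) -> float:
    """Present value of 1 USD/yr for ``horizon_yr`` years: (1-(1+r)^-T)/r."""
    if rate == 0:
        return float(horizon_yr)
    return (1.0 - (1.0 + rate) ** -horizon_yr) / rate


def net_co2e_per_ha(carbon_class: int, reference_mgc_ha: float,
                    co2e_factor: float = CO2E_FACTOR) -> float:
    """Creditable CO2e per hectare: (class mid-point - reference) x 3.67.

    Negative when the forest class holds less carbon than the oil-palm
    baseline; such strata earn negative REDD+ revenue (no flooring).
    """
    try:
        mid = CLASS_MIDPOINTS[int(carbon_class)]
    except (KeyError, ValueError) as exc:
        raise DomainError(f"unknown carbon class {carbon_class!r}") from exc
    return (mid - reference_mgc_ha) * co2e_factor


def redd_cashflows(net_co2e: float, scenario: Scenario) -> np.ndarray:
    """Per-hectare REDD+ cash-flow series (USD, years 1..T)."""
    T = scenario.horizon_yr
    revenue_total = net_co2e * scenario.carbon_price
    flows = np.full(T, -scenario.run_cost, dtype=float)
    if scenario.stance == "upfront":
        flows[0] = revenue_total - scenario.establish_cost
    else:
        flows[0] = 0.5 * revenue_total - scenario.establish_cost
        if T > 1:
            flows[1:] += 0.5 * revenue_total / (T - 1)
    return flows


def redd_npv(net_co2e: float, scenario: Scenario) -> float:
    """25-year REDD+ NPV per hectare (USD), unrounded."""
    return npv(redd_cashflows(net_co2e, scenario), scenario.discount_rate)


def redd_annual_npv(net_co2e: float, scenario: Scenario) -> float:
    """Annualized REDD+ NPV (USD/ha/yr): NPV divided by the horizon.

    Reported figures round this to the nearest dollar (half away from
    zero); the return value itself is unrounded.
    """
    return redd_npv(net_co2e, scenario) / scenario.horizon_yr


# ---------------------------------------------------------------------------
# Oil palm
# ---------------------------------------------------------------------------

#: Full-stand FFB yield ramp for immature-to-peak years 3..7 (t/ha).
#: With zero yield in years 1-2, the 30 t/ha peak plateau in years 8-11
#: and a linear decline to 17 t/ha at year 25, the 25-year mean is
#: exactly 21.92 t/ha/yr.
_YIELD_RAMP_3_7 = (12.1, 18.0, 22.0, 25.4, 28.0)

PEAK_YIELD_T = 30.0
FINAL_YIELD_T = 17.0
FULL_STAND_MEAN_YIELD_T = 21.92

#: Default capacity fractions for the three suitability classes.
CAPACITY_BY_SUITABILITY = {"full_stand": 1.0, "under50": 0.5, "under25": 0.25}


def build_yield_curve(capacity: float) -> np.ndarray:
    """FFB yield curve (t/ha, years 1..25) for a palm-capacity fraction.

    The full-stand curve is scaled linearly by ``capacity`` (yield is
    assumed proportional to surviving palms per hectare).
    """
    if not 0 < capacity <= 1:
        raise DomainError("capacity must be in (0, 1]")
    decline = [PEAK_YIELD_T - k * (PEAK_YIELD_T - FINAL_YIELD_T) / 14.0
               for k in range(1, 15)]
    full = np.array([0.0, 0.0, *_YIELD_RAMP_3_7, *([PEAK_YIELD_T] * 4), *decline])
    return capacity * full


@dataclass(frozen=True)
class OilPalmModel:
    """A new-planting oil-palm estate model for one capacity class.

    The default cost schedule is calibrated (at the 11% industry
    discount rate) against published regional annualized NPVs for the
    three capacity classes; any component can be overridden.

    ffb_price          USD per t FFB, constant (2011 east-Sabah average)
    newplant_cost      felling + ground preparation, USD/ha, year 1
    general_charges    estate overheads, USD/ha/yr
    field_upkeep       weeding/manuring/pruning/infrastructure, USD/ha/yr
    harvest_cost_per_t harvesting + transport, USD per t FFB
    supplying_yr12     replacement of flood-killed palms, USD/ha in each
                       of years 1-2; grows with palm mortality, so it is
                       keyed by capacity class
    """

    capacity: float = 1.0
    ffb_price: float = 178.0
    newplant_cost: float = 1214.8
    general_charges: float = 250.0
    field_upkeep: float = 574.4741033154396
    harvest_cost_per_t: float = 35.0
    supplying_yr12: float = 0.0
    yield_curve: tuple[float, ...] | None = None

    def yields(self) -> np.ndarray:
        if self.yield_curve is not None:
            return np.asarray(self.yield_curve, dtype=float)
        return build_yield_curve(self.capacity)


#: Calibrated year-1/2 supplying costs (USD/ha/yr) per capacity class.
DEFAULT_SUPPLYING_YR12 = {1.0: 0.0, 0.5: 105.71394783754548, 0.25: 238.86179853356956}


def default_oilpalm_model(capacity: float) -> OilPalmModel:
    """The calibrated default model for a capacity fraction."""
    return OilPalmModel(
        capacity=capacity,
        supplying_yr12=DEFAULT_SUPPLYING_YR12.get(capacity, 0.0),
    )


def oilpalm_cashflows(model: OilPalmModel) -> np.ndarray:
    """Per-hectare oil-palm cash-flow series (USD, years 1..25)."""
    yields = model.yields()
    if yields.size != HORIZON_YR:
        raise DomainError(
            f"yield curve must cover {HORIZON_YR} years, got {yields.size}"
        )
    revenue = yields * model.ffb_price
    costs = np.full(HORIZON_YR, model.general_charges + model.field_upkeep)
    costs += yields * model.harvest_cost_per_t
    costs[0] += model.newplant_cost + model.supplying_yr12
    costs[1] += model.supplying_yr12
    return revenue - costs


def oilpalm_annual_npv(model: OilPalmModel, rate: float) -> float:
    """Annualized oil-palm NPV (USD/ha/yr), unrounded."""
    return npv(oilpalm_cashflows(model), rate) / HORIZON_YR


def oilpalm_npvs_by_suitability(
    rate: float = 0.11,
    capacities: dict[str, float] | None = None,
) -> dict[str, float]:
    """Annualized oil-palm NPV per suitability class under the defaults."""
    caps = capacities or CAPACITY_BY_SUITABILITY
    return {
        suit: oilpalm_annual_npv(default_oilpalm_model(cap), rate)
        for suit, cap in caps.items()
    }
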