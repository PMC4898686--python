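"""Per-stratum land-use allocation and landscape roll-ups.

For each stratum the annualized REDD+ NPV (from its carbon class,
suitability-specific reference level, and the scenario) is compared with
the annualized oil-palm NPV for its suitability class; ties go to REDD+
("equal or higher" wins).  Roll-ups over the REDD+-winning set report
extent, carbon stock, CO2-equivalent, and the total carbon-offset funds
needed over the project life (unrounded CO2e times price, rounded once).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_half_away
from .accounting import Stratum, strata_frame, stratum_carbon
from .economics import CO2E_FACTOR, Scenario, net_co2e_per_ha, redd_annual_npv
from .plot_carbon import DomainError
from .reference import DEFAULT_REFERENCE_MGC_HA


@dataclass
class AllocationResult:
    """Winner table plus roll-up for one scenario."""

    scenario: Scenario
    per_stratum: pd.DataFrame  # stratum_id, ..., redd_npv, oilpalm_npv, winner
    extent_ha: float
    pct_of_landscape: int
    total_mgc: float
    total_mgco2e: int
    funds_usd: int


def decide_stratum(
    stratum: Stratum,
    scenario: Scenario,
    references: Mapping[str, float] | None = None,
    oilpalm_npvs: Mapping[str, float] | None = None,
) -> str:
    """Winner ("redd" or "oilpalm") for one stratum; ties go to redd."""
    refs = references or DEFAULT_REFERENCE_MGC_HA
    if oilpalm_npvs is None:
        raise DomainError("oil-palm NPVs by suitability are required")
    if stratum.suitability not in refs or stratum.suitability not in oilpalm_npvs:
        raise DomainError(f"unknown suitability {stratum.suitability!r}")
    net = net_co2e_per_ha(stratum.carbon_class, refs[stratum.suitability],
                          scenario.co2e_factor)
    redd = redd_annual_npv(net, scenario)
    return "redd" if redd >= oilpalm_npvs[stratum.suitability] else "oilpalm"


def allocate(
    strata: Iterable[Stratum] | pd.DataFrame,
    scenario: Scenario,
    references: Mapping[str, float] | None = None,
    oilpalm_npvs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-stratum NPVs and winners for one scenario."""
    refs = references or DEFAULT_REFERENCE_MGC_HA
    if oilpalm_npvs is None:
        raise DomainError("oil-palm NPVs by suitability are required")
    df = strata_frame(strata)
    if df.empty:
        return df.assign(redd_npv=[], oilpalm_npv=[], winner=[])
    unknown = set(df["suitability"]) - set(refs) | set(df["suitability"]) - set(
        oilpalm_npvs
    )
    if unknown:
        raise DomainError(f"unknown suitability classes {sorted(unknown)}")
    redd_vals = [
        redd_annual_npv(
            net_co2e_per_ha(cls, refs[suit], scenario.co2e_factor), scenario
        )
        for cls, suit in zip(df["carbon_class"], df["suitability"])
    ]
    op_vals = [oilpalm_npvs[suit] for suit in df["suitability"]]
    out = df.assign(redd_npv=redd_vals, oilpalm_npv=op_vals)
    out["winner"] = [
        "redd" if r >= o else "oilpalm" for r, o in zip(out.redd_npv, out.oilpalm_npv)
    ]
    return out


def rollup(per_stratum: pd.DataFrame, scenario: Scenario) -> AllocationResult:
    """Landscape roll-up over the REDD+-winning strata.

    Funds are computed from the *unrounded* CO2e total and rounded once
    to the nearest dollar; the CO2e figure itself is reported rounded to
    the nearest ton.
    """
    total_extent = float(per_stratum["extent_ha"].sum())
    winners = per_stratum[per_stratum["winner"] == "redd"]
    extent = float(winners["extent_ha"].sum())
    mgc = float(
        sum(
            stratum_carbon(e, c)
            for e, c in zip(winners["extent_ha"], winners["carbon_class"])
        )
    )
    co2e_exact = mgc * scenario.co2e_factor
    pct = round_half_away(100.0 * extent / total_extent) if total_extent > 0 else 0
    return AllocationResult(
        scenario=scenario,
        per_stratum=per_stratum,
        extent_ha=extent,
        pct_of_landscape=pct,
        total_mgc=mgc,
        total_mgco2e=round_half_away(co2e_exact),
        funds_usd=round_half_away(co2e_exact * scenario.carbon_price),
    )


def fund_arithmetic(total_mgc: float, carbon_price: float,
                    co2e_factor: float = CO2E_FACTOR) -> tuple[int, int]:
    """(MgCO2e, funds USD) from a carbon stock at a price.

    The single-rounding rule used throughout reports: CO2e and funds are
    both rounded half-away-from-zero, funds from the unrounded CO2e.
    """
    co2e_exact = total_mgc * co2e_factor
    return round_half_away(co2e_exact), round_half_away(co2e_exact * carbon_price)


def allocation_table(
    strata: Iterable[Stratum] | pd.DataFrame,
    scenarios: Iterable[Scenario],
    references: Mapping[str, float] | None = None,
    oilpalm_npvs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Roll-up rows (one per scenario) for a scenario grid."""
    df = strata_frame(strata)
    rows = []
    for sc in scenarios:
        res = rollup(allocate(df, sc, references, oilpalm_npvs), sc)
        rows.append(
            {
                "stance": sc.stance,
                "carbon_price": sc.carbon_price,
                "discount_rate": sc.discount_rate,
                "extent_ha": res.extent_ha,
                "pct_of_landscape": res.pct_of_landscape,
                "total_mgc": res.total_mgc,
                "total_mgco2e": res.total_mgco2e,
                "funds_usd": res.funds_usd,
            }
        )
    return pd.DataFrame(rows)
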