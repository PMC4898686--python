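"""Per-stratum allocation, tie rule, roll-ups and fund arithmetic."""

import pandas as pd
import pytest

from floodcarbon.accounting import Stratum
from floodcarbon.allocation import (
    allocate,
    allocation_table,
    decide_stratum,
    fund_arithmetic,
    rollup,
)
from floodcarbon.economics import Scenario, npv
from floodcarbon.plot_carbon import CLASS_MIDPOINTS, DomainError
from floodcarbon.synth import SyntheticConfig, generate_landscape

PRINTED_OP_NPVS = {"full_stand": 594.0, "under50": 129.0, "under25": -109.0}
PRINTED_REFS = {"full_stand": 46.0, "under50": 20.0, "under25": 7.0}


def _scenario(price, stance="upfront", rate=0.11):
    return Scenario(carbon_price=price, stance=stance, discount_rate=rate)


class TestDecideStratum:
    @pytest.mark.parametrize("cls", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("price", [3.0, 7.8, 15.0, 30.0])
    def test_low_suitability_always_redd(self, cls, price):
        s = Stratum("s", 10.0, cls, "under25", "native_title")
        assert (
            decide_stratum(s, _scenario(price), PRINTED_REFS, PRINTED_OP_NPVS)
            == "redd"
        )

    def test_full_stand_low_carbon_goes_to_oilpalm(self):
        s = Stratum("s", 10.0, 1, "full_stand", "native_title")
        assert (
            decide_stratum(s, _scenario(30.0), PRINTED_REFS, PRINTED_OP_NPVS)
            == "oilpalm"
        )

    def test_tie_goes_to_redd(self):
        s = Stratum("s", 10.0, 3, "full_stand", "native_title")
        # force a tie by setting the oil-palm NPV to the redd NPV
        alloc = allocate([s], _scenario(15.0), PRINTED_REFS, PRINTED_OP_NPVS)
        tied = {"full_stand": float(alloc["redd_npv"].iloc[0])}
        assert decide_stratum(s, _scenario(15.0), PRINTED_REFS, tied) == "redd"

    def test_unknown_suitability_rejected(self):
        s = Stratum("s", 10.0, 3, "full_stand", "native_title")
        with pytest.raises(DomainError):
            decide_stratum(s, _scenario(3.0), PRINTED_REFS, {"under50": 1.0})


class TestRollup:
    def test_fund_cells_from_printed_carbon(self):
        co2e, funds = fund_arithmetic(2_495_980, 3.0)
        assert co2e == 9_160_247
        assert funds == 27_480_740

    def test_no_winners_all_zero(self):
        strata = [Stratum("s", 10.0, 1, "full_stand", "native_title")]
        res = rollup(allocate(strata, _scenario(3.0), PRINTED_REFS,
                              PRINTED_OP_NPVS), _scenario(3.0))
        assert res.extent_ha == 0
        assert res.total_mgc == 0
        assert res.total_mgco2e == 0
        assert res.funds_usd == 0

    def test_extent_partition(self):
        cfg = SyntheticConfig(seed=3)
        strata = generate_landscape(cfg)
        alloc = allocate(strata, _scenario(7.8), PRINTED_REFS, PRINTED_OP_NPVS)
        res = rollup(alloc, _scenario(7.8))
        op_extent = alloc.loc[alloc.winner == "oilpalm", "extent_ha"].sum()
        assert res.extent_ha + op_extent == pytest.approx(
            alloc["extent_ha"].sum(), rel=1e-12
        )


class TestMonotoneCoverage:
    def test_winning_set_grows_with_price(self):
        strata = generate_landscape(SyntheticConfig(seed=11))
        for stance in ("upfront", "staggered"):
            previous: set[str] = set()
            for price in (3.0, 7.8, 15.0, 30.0):
                alloc = allocate(
                    strata, _scenario(price, stance), PRINTED_REFS, PRINTED_OP_NPVS
                )
                winners = set(alloc.loc[alloc.winner == "redd", "stratum_id"])
                assert previous <= winners
                previous = winners

    def test_upfront_coverage_contains_staggered(self):
        strata = generate_landscape(SyntheticConfig(seed=11))
        for price in (3.0, 7.8, 15.0, 30.0):
            up = allocate(strata, _scenario(price, "upfront"), PRINTED_REFS,
                          PRINTED_OP_NPVS)
            st = allocate(strata, _scenario(price, "staggered"), PRINTED_REFS,
                          PRINTED_OP_NPVS)
            up_set = set(up.loc[up.winner == "redd", "stratum_id"])
            st_set = set(st.loc[st.winner == "redd", "stratum_id"])
            assert st_set <= up_set


def test_known_winner_recovery():
    """Allocation recovers the winner set computed by an independent DCF loop."""
    strata = generate_landscape(SyntheticConfig(seed=5))
    sc = _scenario(7.8, "staggered")
    alloc = allocate(strata, sc, PRINTED_REFS, PRINTED_OP_NPVS)
    for row in alloc.itertuples():
        net = (CLASS_MIDPOINTS[row.carbon_class] - PRINTED_REFS[row.suitability]) * 3.67
        total = net * sc.carbon_price
        flows = [0.5 * total - 25.0] + [0.5 * total / 24.0 - 10.0] * 24
        redd = npv(flows, 0.11) / 25.0
        expected = "redd" if redd >= PRINTED_OP_NPVS[row.suitability] else "oilpalm"
        assert row.winner == expected


def test_allocation_table_grid_shape():
    strata = generate_landscape(SyntheticConfig(seed=0))
    scenarios = [
        _scenario(p, s) for s in ("upfront", "staggered") for p in (3.0, 30.0)
    ]
    table = allocation_table(strata, scenarios, PRINTED_REFS, PRINTED_OP_NPVS)
    assert len(table) == 4
    assert set(table.columns) >= {
        "stance", "carbon_price", "extent_ha", "pct_of_landscape",
        "total_mgc", "total_mgco2e", "funds_usd",
    }
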