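"""Price bases, cost metrics, and the MRP-vs-wholesale sensitivity analysis."""

import math

import numpy as np
import pytest

from abxddd.cost import (
    MRP,
    BasisError,
    PriceBasis,
    add_costs,
    cost_per_ddd,
    per_capita_cost,
    record_cost,
    sensitivity_compare,
)
from abxddd.ingest import ProcurementRecord, SalesRecord
from abxddd.registry import Route, Unit


def _sale(mrp=100.0, wholesale=None, packs=10.0):
    return SalesRecord(
        product_id="P1", molecule_name="ceftriaxone", route=Route.INJECTABLE,
        strength_value=1000.0, strength_unit=Unit.MG, pack_size=1,
        packs_per_year=packs, mrp_per_pack=mrp, wholesale_per_pack=wholesale,
        year=2016, region="KL",
    )


def _proc(price=40.0, packs=10.0):
    return ProcurementRecord(
        molecule_name="ceftriaxone", route=Route.INJECTABLE,
        strength_value=1000.0, strength_unit=Unit.MG, pack_size=1,
        packs_per_year=packs, procurement_cost_per_pack=price,
        year=2016, region="KL",
    )


class TestRecordCost:
    def test_mrp_basis(self):
        assert record_cost(_sale(mrp=100.0, packs=10.0), MRP) == pytest.approx(1000.0)

    def test_wholesale_fallback_from_margin(self):
        basis = PriceBasis("wholesale", margin_fallback=0.20)
        assert record_cost(_sale(mrp=120.0, packs=1.0), basis) == pytest.approx(100.0)

    def test_observed_wholesale_beats_fallback(self):
        basis = PriceBasis("wholesale", margin_fallback=0.20)
        assert record_cost(_sale(mrp=120.0, wholesale=90.0, packs=1.0), basis) == 90.0

    def test_wholesale_without_fallback_errors(self):
        with pytest.raises(BasisError, match="margin_fallback"):
            record_cost(_sale(), PriceBasis("wholesale"))

    def test_procurement_basis_only_for_public(self):
        with pytest.raises(BasisError, match="public"):
            record_cost(_sale(), PriceBasis("procurement"))
        assert record_cost(_proc(40.0, 10.0), PriceBasis("procurement")) == 400.0

    def test_private_bases_invalid_for_public(self):
        with pytest.raises(BasisError):
            record_cost(_proc(), MRP)

    def test_per_atc3_margin_table(self):
        basis = PriceBasis("wholesale", margin_fallback={"J01D": 0.25})
        assert record_cost(_sale(mrp=125.0, packs=1.0), basis, atc3="J01D") == 100.0
        with pytest.raises(BasisError, match="J01X"):
            record_cost(_sale(), basis, atc3="J01X")

    def test_unknown_kind_rejected(self):
        with pytest.raises(BasisError):
            PriceBasis("retail")


class TestCostPerDdd:
    @pytest.mark.parametrize(
        "cost, ddds, expected",
        [
            # published ratios: a Watch-group total and a single cheap molecule
            (39.6e9, 133.7e6, 296.2),
            (661.2e6, 22.8e6, 29.0),
        ],
    )
    def test_reproduces_published_ratios(self, cost, ddds, expected):
        assert round(cost_per_ddd(cost, ddds), 1) == expected

    def test_zero_cost_is_zero(self):
        assert cost_per_ddd(0.0, 5.0) == 0.0

    def test_zero_ddds_is_undefined_not_infinite(self):
        assert math.isnan(cost_per_ddd(100.0, 0.0))


class TestPerCapitaCost:
    def test_reproduces_published_injectable_value(self):
        # 75.7 billion INR over a 1.31 billion population
        assert per_capita_cost(75.7e9, 1.31e6) == pytest.approx(57.7, rel=0.002)

    def test_zero_cost(self):
        assert per_capita_cost(0.0, 1000.0) == 0.0

    def test_inverse_linearity_in_population(self):
        assert per_capita_cost(100.0, 2000.0) == per_capita_cost(100.0, 1000.0) / 2

    def test_requires_positive_population(self):
        with pytest.raises(ValueError):
            per_capita_cost(100.0, 0.0)


def test_wholesale_total_never_exceeds_mrp_total(costed_10k):
    frame = costed_10k
    w = add_costs(frame, PriceBasis("wholesale", margin_fallback=0.20))
    for stratum in ("aware", "atc3", "sector", "route"):
        mrp_totals = frame.groupby(stratum)["cost"].sum()
        w_totals = w.groupby(stratum)["cost"].sum()
        assert (w_totals <= mrp_totals * (1 + 1e-12)).all()


def test_add_costs_procurement_rejects_private(costed_10k):
    with pytest.raises(BasisError):
        add_costs(costed_10k, PriceBasis("procurement"))


class TestSensitivityCompare:
    @staticmethod
    def _frame():
        # minimal 3-record two-sector frame with uniform 25% margin
        import pandas as pd

        return pd.DataFrame(
            {
                "sector": ["private", "private", "public"],
                "route": ["injectable"] * 3,
                "atc3": ["J01D"] * 3,
                "molecule": ["a", "b", "c"],
                "total_ddds": [10.0, 20.0, 30.0],
                "packs_per_year": [10.0, 20.0, 30.0],
                "mrp_per_pack": [100.0, 50.0, float("nan")],
                "wholesale_per_pack": [80.0, 40.0, float("nan")],
                "procurement_cost_per_pack": [float("nan")] * 2 + [20.0],
            }
        )

    def test_uniform_margin_shifts_share_toward_public(self):
        out = sensitivity_compare(
            self._frame(), (MRP, PriceBasis("wholesale")), group="sector"
        )
        out = out.set_index("sector")
        # private total falls 2000 -> 1600 while public (procurement) is fixed
        assert out.loc["private", "cost_mrp"] == pytest.approx(2000.0)
        assert out.loc["private", "cost_wholesale"] == pytest.approx(1600.0)
        assert out.loc["public", "cost_mrp"] == out.loc["public", "cost_wholesale"]
        assert out.loc["private", "diff_pp"] > 0
        assert out.loc["public", "diff_pp"] < 0
        # algebraic check: shares from the totals directly
        assert out.loc["private", "share_mrp_pct"] == pytest.approx(100 * 2000 / 2600)
        assert out.loc["private", "share_wholesale_pct"] == pytest.approx(100 * 1600 / 2200)

    def test_zero_margin_bases_coincide(self):
        frame = self._frame()
        frame["wholesale_per_pack"] = frame["mrp_per_pack"]
        out = sensitivity_compare(frame, (MRP, PriceBasis("wholesale")), group="sector")
        assert np.allclose(out["diff_pp"].to_numpy(), 0.0)

    def test_shares_sum_to_100_each_basis(self, costed_10k):
        out = sensitivity_compare(
            costed_10k, (MRP, PriceBasis("wholesale", 0.2)), group="sector"
        )
        assert out["share_mrp_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["share_wholesale_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_per_record_oracle(self, costed_10k, dataset_10k):
        """Sector cost totals equal an independent brute-force record loop."""
        out = sensitivity_compare(
            costed_10k, (MRP, PriceBasis("wholesale", 0.2)), group="sector"
        ).set_index("sector")
        gt = dataset_10k.ground_truth["by_sector_route"]
        for sector in ("private", "public"):
            oracle_primary = sum(
                v["cost"] for k, v in gt.items() if k.startswith(sector)
            )
            oracle_wholesale = sum(
                v["cost_wholesale"] for k, v in gt.items() if k.startswith(sector)
            )
            assert out.loc[sector, "cost_mrp"] == pytest.approx(oracle_primary, rel=1e-9)
            assert out.loc[sector, "cost_wholesale"] == pytest.approx(
                oracle_wholesale, rel=1e-9
            )


def test_stratum_costs_conserve_total(costed_10k):
    grand = costed_10k["cost"].sum()
    for partition in ("sector", "aware", "atc4", "molecule"):
        assert costed_10k.groupby(partition)["cost"].sum().sum() == pytest.approx(
            grand, rel=1e-9
        )
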