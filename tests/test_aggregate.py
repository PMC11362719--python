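"""Share tables, sector shares, formulation counts, top-n with remainder."""

import numpy as np
import pandas as pd
import pytest

from abxddd.aggregate import formulation_count, sector_share, share_table, top_n
from abxddd.datasets import load_published_table, table18_records_frame


@pytest.fixture(scope="module")
def t18_frame():
    return table18_records_frame()


@pytest.fixture(scope="module")
def t18_sector(t18_frame):
    return sector_share(t18_frame, "molecule").set_index("molecule")


class TestShareTable:
    def test_single_group_share_is_100(self):
        frame = pd.DataFrame(
            {"aware": ["Watch"], "total_ddds": [5.0], "cost": [50.0]}
        )
        t = share_table(frame, "aware")
        assert t.loc[0, "ddd_share_pct"] == pytest.approx(100.0)

    def test_totals_row_equals_column_sums(self, costed_10k):
        t = share_table(costed_10k, "aware")
        body = t[t["aware"] != "Total"]
        tot = t[t["aware"] == "Total"].iloc[0]
        assert tot["total_ddds"] == pytest.approx(body["total_ddds"].sum(), rel=1e-9)
        assert tot["total_cost"] == pytest.approx(body["total_cost"].sum(), rel=1e-9)
        assert body["ddd_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert body["cost_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_selection_gives_empty_table(self, costed_10k):
        t = share_table(costed_10k[costed_10k["region"] == "nowhere"], "aware")
        assert t.empty

    def test_matches_per_record_oracle(self, costed_10k, dataset_10k):
        t = share_table(costed_10k, "aware").set_index("aware")
        for cls, vals in dataset_10k.ground_truth["by_aware"].items():
            assert t.loc[cls, "total_ddds"] == pytest.approx(vals["ddds"], rel=1e-9)
            assert t.loc[cls, "total_cost"] == pytest.approx(vals["cost"], rel=1e-9)

    def test_rounding_is_display_only(self, costed_10k):
        t = share_table(costed_10k, "atc3")
        recomputed = 100.0 * t["total_ddds"] / t[t["atc3"] != "Total"]["total_ddds"].sum()
        body = t["atc3"] != "Total"
        assert np.allclose(t.loc[body, "ddd_share_pct"], recomputed[body], rtol=1e-12)


class TestSectorShare:
    def test_published_molecule_level_shares(self, t18_sector):
        # dominant third-generation cephalosporin vs high-cost carbapenem
        assert round(t18_sector.loc["Ceftriaxone", "private_ddd_pct"], 1) == 78.7
        assert round(t18_sector.loc["Meropenem", "private_cost_pct"], 1) == 99.2

    def test_published_route_level_shares(self):
        t6 = load_published_table("table06")
        rows = []
        for _, r in t6.iterrows():
            for sector in ("public", "private"):
                rows.append(
                    {
                        "route": r["route"],
                        "sector": sector,
                        "total_ddds": r[f"{sector}_ddds"],
                        "cost": r[f"{sector}_cost_inr"],
                    }
                )
        t = sector_share(pd.DataFrame(rows), "route").set_index("route")
        assert round(t.loc["Oral", "public_ddd_pct"], 1) == 39.8
        assert round(t.loc["Injectable", "private_cost_pct"], 1) == 93.7

    def test_shares_sum_to_100_per_group(self, t18_sector):
        volume = t18_sector["public_ddd_pct"] + t18_sector["private_ddd_pct"]
        cost = t18_sector["public_cost_pct"] + t18_sector["private_cost_pct"]
        assert np.allclose(volume, 100.0) and np.allclose(cost, 100.0)

    def test_single_sector_input(self):
        frame = pd.DataFrame(
            {
                "route": ["injectable"],
                "sector": ["public"],
                "total_ddds": [10.0],
                "cost": [100.0],
            }
        )
        t = sector_share(frame, "route").set_index("route")
        assert t.loc["injectable", "public_ddd_pct"] == 100.0
        assert t.loc["injectable", "private_ddd_pct"] == 0.0


class TestFormulationCount:
    def test_published_public_injectable_count(self, t18_frame):
        assert formulation_count(t18_frame, sector="public", route="injectable") == 21

    def test_empty_input(self):
        assert formulation_count(pd.DataFrame()) == 0

    def test_duplicates_count_once(self):
        frame = pd.DataFrame(
            {
                "molecule": ["ceftriaxone"] * 3,
                "sector": ["public"] * 3,
                "total_ddds": [1.0, 2.0, 3.0],
            }
        )
        assert formulation_count(frame, sector="public") == 1

    def test_zero_volume_molecules_not_counted(self, t18_frame):
        # benzylpenicillin and cloxacillin have no private volume
        private = formulation_count(t18_frame, sector="private", route="injectable")
        assert private == 21 - 2


class TestTopN:
    def test_published_remainder_share(self):
        t5 = load_published_table("table05")
        named = t5[t5["molecule"] != "all_other"]
        rest = t5[t5["molecule"] == "all_other"].iloc[0]
        rows = [
            {"molecule": r["molecule"], "total_ddds": r["ddds"], "cost": r["cost_inr"]}
            for _, r in named.iterrows()
        ]
        # the published table collapses everything beyond the top five into
        # one row; spread it over pseudo-molecules smaller than the 5th rank
        # so top_n has to fold them back into the remainder
        for i in range(8):
            rows.append(
                {
                    "molecule": f"other-{i}",
                    "total_ddds": rest["ddds"] / 8,
                    "cost": rest["cost_inr"] / 8,
                }
            )
        table = top_n(share_table(pd.DataFrame(rows), "molecule"), 5, by="total_ddds")
        rem = table[table["molecule"] == "All the other"].iloc[0]
        assert rem["total_ddds"] == pytest.approx(rest["ddds"], rel=1e-9)
        # printed share derives from unrounded source data; 0.5% relative slack
        assert rem["ddd_share_pct"] == pytest.approx(32.4, rel=0.005)

    def test_n_at_least_row_count_leaves_table_unchanged(self, costed_10k):
        t = share_table(costed_10k, "aware")
        assert top_n(t, 50).equals(t)

    def test_remainder_conserves_totals(self, costed_10k):
        t = share_table(costed_10k, "molecule")
        cut = top_n(t, 5, by="total_cost")
        body = t[t["molecule"] != "Total"]
        kept = cut[~cut["molecule"].isin(["Total"])]
        assert kept["total_ddds"].sum() == pytest.approx(
            body["total_ddds"].sum(), rel=1e-9
        )
        assert kept["total_cost"].sum() == pytest.approx(
            body["total_cost"].sum(), rel=1e-9
        )

    def test_deterministic_tie_break(self):
        frame = pd.DataFrame(
            {
                "molecule": ["b", "a", "c"],
                "total_ddds": [1.0, 1.0, 1.0],
                "cost": [1.0, 1.0, 1.0],
            }
        )
        t = top_n(share_table(frame, "molecule"), 2)
        assert list(t["molecule"][:2]) == ["a", "b"]

    def test_invalid_n(self, costed_10k):
        with pytest.raises(ValueError):
            top_n(share_table(costed_10k, "aware"), 0)


def test_atc_rollup_consistency(costed_10k):
    """ATC5 totals roll up exactly to ATC4, and ATC4 to ATC3."""
    by5 = costed_10k.groupby("atc5")[["total_ddds", "cost"]].sum()
    by4 = costed_10k.groupby("atc4")[["total_ddds", "cost"]].sum()
    by3 = costed_10k.groupby("atc3")[["total_ddds", "cost"]].sum()
    roll4 = by5.groupby(by5.index.str[:5]).sum()
    roll3 = by4.groupby(by4.index.str[:4]).sum()
    pd.testing.assert_frame_equal(roll4, by4, check_names=False, rtol=1e-9)
    pd.testing.assert_frame_equal(roll3, by3, check_names=False, rtol=1e-9)
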