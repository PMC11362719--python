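"""Report builders mirroring the published table layouts.

Each builder takes an annotated, costed record frame (plus the population
table where per-capita or DID columns are needed) and returns a tidy
DataFrame.  Totals spanning several years are reported as annual averages
(the multi-year convention used throughout: compute per year, average
across years).  Shares are computed on unrounded values; rounding to one
decimal (three for DID) happens only when a table is written to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .aggregate import sector_share, share_table, top_n
from .cost import per_capita_cost
from .ddd import DAYS_PER_YEAR
from .ingest import PopulationTable

__all__ = ["ReportError", "available_tables", "build_table", "write_tables"]


class ReportError(ValueError):
    """Unknown report id or unusable metrics input."""


_ONE_DP = ("ddd_share_pct", "cost_share_pct", "cost_per_ddd", "public_ddd_pct",
           "private_ddd_pct", "public_cost_pct", "private_cost_pct",
           "per_capita_cost", "share_mrp_pct", "share_wholesale_pct", "diff_pp")
_THREE_DP = ("public_did", "private_did", "did")


def _n_years(frame: pd.DataFrame) -> int:
    return max(int(frame["year"].nunique()), 1) if not frame.empty else 1


def _avg_population(frame: pd.DataFrame, population: PopulationTable, region: str) -> float:
    years = sorted(frame["year"].unique()) if not frame.empty else []
    if not years:
        raise ReportError("cannot compute per-capita metrics on an empty frame")
    return sum(population.get(region, int(y)) for y in years) / len(years)


def _annualize(table: pd.DataFrame, n_years: int, cols: Iterable[str]) -> pd.DataFrame:
    out = table.copy()
    for c in cols:
        if c in out.columns:
            out[c] = out[c] / n_years
    return out


def _table01(frame, population, region):
    n = _n_years(frame)
    t = share_table(frame, "route")
    t = _annualize(t, n, ("total_ddds", "total_cost"))
    pop = _avg_population(frame, population, region)
    t["per_capita_cost"] = [per_capita_cost(c, pop) for c in t["total_cost"]]
    return t


def _table02(frame, population, region):
    sub = frame[frame["route"] == "injectable"]
    return _annualize(share_table(sub, "aware"), _n_years(frame),
                      ("total_ddds", "total_cost"))


def _atc_top5(frame, group, label):
    sub = frame[frame["route"] == "injectable"]
    t = share_table(sub, group, label_col=label)
    return top_n(t, 5, by="total_ddds", remainder_label="All the other groups")


def _table03(frame, population, region):
    return _annualize(_atc_top5(frame, "atc3", "atc3_label"), _n_years(frame),
                      ("total_ddds", "total_cost"))


def _table04(frame, population, region):
    return _annualize(_atc_top5(frame, "atc4", "atc4_label"), _n_years(frame),
                      ("total_ddds", "total_cost"))


def _table05(frame, population, region):
    sub = frame[frame["route"] == "injectable"]
    t = top_n(share_table(sub, "molecule"), 5, by="total_ddds",
              remainder_label="All the other antibiotics")
    return _annualize(t, _n_years(frame), ("total_ddds", "total_cost"))


def _table06(frame, population, region):
    return _annualize(sector_share(frame, "route"), _n_years(frame),
                      ("public_ddds", "private_ddds", "total_ddds",
                       "public_cost", "private_cost", "total_cost"))


def _table08(frame, population, region):
    sub = frame[frame["route"] == "injectable"]
    t = sector_share(sub, "aware")
    n = _n_years(frame)
    t = _annualize(t, n, ("public_ddds", "private_ddds", "total_ddds",
                          "public_cost", "private_cost", "total_cost"))
    pop = _avg_population(frame, population, region)
    t["public_did"] = t["public_ddds"] / (pop * DAYS_PER_YEAR)
    t["private_did"] = t["private_ddds"] / (pop * DAYS_PER_YEAR)
    cols = ["aware", "public_ddds", "public_did", "public_ddd_pct",
            "private_ddds", "private_did", "private_ddd_pct", "total_ddds"]
    return t[cols]


def _table09(frame, population, region):
    sub = frame[frame["route"] == "injectable"]
    t = sector_share(sub, "aware")
    t = _annualize(t, _n_years(frame),
                   ("public_ddds", "private_ddds", "total_ddds",
                    "public_cost", "private_cost", "total_cost"))
    cols = ["aware", "public_cost", "public_cost_pct",
            "private_cost", "private_cost_pct", "total_cost"]
    return t[cols]


def _table18(frame, population, region):
    sub = frame[frame["route"] == "injectable"]
    # only molecules provided in the public sector, per the published layout
    public_mols = sorted(
        sub.loc[(sub["sector"] == "public") & (sub["total_ddds"] > 0), "molecule"].unique()
    )
    t = sector_share(sub[sub["molecule"].isin(public_mols)], "molecule")
    body = t[t["molecule"] != "Total"].sort_values("molecule", kind="mergesort")
    return pd.concat([body, t[t["molecule"] == "Total"]], ignore_index=True)


_BUILDERS = {
    "table01": _table01,
    "table02": _table02,
    "table03": _table03,
    "table04": _table04,
    "table05": _table05,
    "table06": _table06,
    "table08": _table08,
    "table09": _table09,
    "table18": _table18,
}

_DESCRIPTIONS = {
    "table01": "Consumption and cost by route (annual averages, with per-capita cost)",
    "table02": "Injectable consumption and cost across AWaRe groups",
    "table03": "Top five injectable ATC-3 groups with remainder",
    "table04": "Top five injectable ATC-4 subgroups with remainder",
    "table05": "Top five injectable molecules with remainder",
    "table06": "Public/private volume and cost shares by route",
    "table08": "Injectable volume and DID across AWaRe groups by sector",
    "table09": "Injectable cost across AWaRe groups by sector",
    "table18": "Molecule-level public/private split of injectables",
}


def available_tables() -> list[str]:
    return sorted(_BUILDERS)


def build_table(
    table_id: str,
    frame: pd.DataFrame,
    population: Optional[PopulationTable] = None,
    region: Optional[str] = None,
) -> pd.DataFrame:
    """Build one report table from an annotated, costed record frame."""
    try:
        builder = _BUILDERS[table_id]
    except KeyError:
        raise ReportError(
            f"unknown table id {table_id!r}; available: {available_tables()}"
        ) from None
    if table_id in ("table01", "table08") and (population is None or region is None):
        raise ReportError(f"{table_id} needs a population table and a region")
    return builder(frame, population, region)


def _display_round(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for c in out.columns:
        if c in _ONE_DP:
            out[c] = out[c].astype(float).round(1)
        elif c in _THREE_DP:
            out[c] = out[c].astype(float).round(3)
    return out


def write_tables(
    table_ids: Iterable[str],
    frame: pd.DataFrame,
    outdir: Union[str, Path],
    population: Optional[PopulationTable] = None,
    region: Optional[str] = None,
) -> dict[str, Path]:
    """Write the selected tables as CSVs plus a manifest JSON.

    Display rounding (one decimal for shares and cost per DDD, three for
    DID) is applied here only; builders return unrounded values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest = {}
    for tid in table_ids:
        table = build_table(tid, frame, population, region)
        path = outdir / f"{tid}.csv"
        _display_round(table).to_csv(path, index=False, float_format="%.10g")
        written[tid] = path
        manifest[tid] = {
            "file": path.name,
            "description": _DESCRIPTIONS[tid],
            "rows": int(len(table)),
        }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return written
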