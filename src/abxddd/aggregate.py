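"""Stratified share tables: volume and cost by route, sector, AWaRe, ATC.

All operations take a frame that carries at least ``total_ddds`` and
``cost`` columns (the output of :func:`abxddd.ddd.annotate` followed by
:func:`abxddd.cost.add_costs`, or any fixture frame of molecule-level
totals with the same columns).  Shares are always computed on unrounded
values; rounding to one decimal is a display concern handled by the
report writers.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "share_table",
    "sector_share",
    "formulation_count",
    "top_n",
    "TOTAL_LABEL",
]

TOTAL_LABEL = "Total"


def _require(frame: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise KeyError(f"frame is missing required columns {missing}")


def _shares(values: pd.Series) -> pd.Series:
    total = values.sum()
    if total <= 0:
        return values * np.nan
    return 100.0 * values / total


def share_table(
    frame: pd.DataFrame,
    group: str,
    label_col: Optional[str] = None,
    include_total: bool = True,
) -> pd.DataFrame:
    """One row per group with DDD and cost totals, shares and cost per DDD.

    ``group`` is a column of ``frame`` (aware, atc3, atc4, molecule, route,
    sector, ...).  ``label_col`` optionally carries a display label that is
    constant within each group (e.g. the ATC group name).  Rows are sorted
    by descending DDDs, ties broken alphabetically; an optional totals row
    is appended last.
    """
    _require(frame, [group, "total_ddds", "cost"])
    if frame.empty:
        cols = [group] + (["label"] if label_col else []) + [
            "total_ddds", "ddd_share_pct", "total_cost", "cost_share_pct", "cost_per_ddd",
        ]
        return pd.DataFrame(columns=cols)
    keys = [group] if label_col is None else [group, label_col]
    g = frame.groupby(keys, dropna=False)[["total_ddds", "cost"]].sum().reset_index()
    if label_col is not None:
        g = g.rename(columns={label_col: "label"})
    g = g.rename(columns={"cost": "total_cost"})
    g["ddd_share_pct"] = _shares(g["total_ddds"])
    g["cost_share_pct"] = _shares(g["total_cost"])
    with np.errstate(invalid="ignore", divide="ignore"):
        g["cost_per_ddd"] = np.where(
            g["total_ddds"] > 0, g["total_cost"] / g["total_ddds"], np.nan
        )
    g = g.sort_values(
        ["total_ddds", group], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if include_total:
        total_ddd = float(g["total_ddds"].sum())
        total_cost = float(g["total_cost"].sum())
        row = {
            group: TOTAL_LABEL,
            "total_ddds": total_ddd,
            "ddd_share_pct": 100.0 if total_ddd > 0 else np.nan,
            "total_cost": total_cost,
            "cost_share_pct": 100.0 if total_cost > 0 else np.nan,
            "cost_per_ddd": total_cost / total_ddd if total_ddd > 0 else np.nan,
        }
        if "label" in g.columns:
            row["label"] = TOTAL_LABEL
        g = pd.concat([g, pd.DataFrame([row])], ignore_index=True)
    ordered = [group] + (["label"] if "label" in g.columns else []) + [
        "total_ddds", "ddd_share_pct", "total_cost", "cost_share_pct", "cost_per_ddd",
    ]
    return g[ordered]


def sector_share(
    frame: pd.DataFrame, group: str, include_total: bool = True
) -> pd.DataFrame:
    """Public/private split of volume and cost per group.

    For every group, ``public_ddd_pct + private_ddd_pct == 100`` (ditto for
    cost) whenever the group has any volume (cost); an absent sector simply
    contributes zero.
    """
    _require(frame, [group, "sector", "total_ddds", "cost"])
    pt = frame.pivot_table(
        index=group,
        columns="sector",
        values=["total_ddds", "cost"],
        aggfunc="sum",
        fill_value=0.0,
    )
    for metric in ("total_ddds", "cost"):
        for sector in ("public", "private"):
            if (metric, sector) not in pt.columns:
                pt[(metric, sector)] = 0.0
    out = pd.DataFrame(
        {
            group: pt.index,
            "public_ddds": pt[("total_ddds", "public")].to_numpy(float),
            "private_ddds": pt[("total_ddds", "private")].to_numpy(float),
            "public_cost": pt[("cost", "public")].to_numpy(float),
            "private_cost": pt[("cost", "private")].to_numpy(float),
        }
    )
    out["total_ddds"] = out["public_ddds"] + out["private_ddds"]
    out["total_cost"] = out["public_cost"] + out["private_cost"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["public_ddd_pct"] = np.where(
            out["total_ddds"] > 0, 100.0 * out["public_ddds"] / out["total_ddds"], np.nan
        )
        out["public_cost_pct"] = np.where(
            out["total_cost"] > 0, 100.0 * out["public_cost"] / out["total_cost"], np.nan
        )
    out["private_ddd_pct"] = 100.0 - out["public_ddd_pct"]
    out["private_cost_pct"] = 100.0 - out["public_cost_pct"]
    out = out.sort_values(
        ["total_ddds", group], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if include_total:
        sums = {
            c: float(out[c].sum())
            for c in ("public_ddds", "private_ddds", "public_cost", "private_cost",
                      "total_ddds", "total_cost")
        }
        row = {group: TOTAL_LABEL, **sums}
        row["public_ddd_pct"] = (
            100.0 * sums["public_ddds"] / sums["total_ddds"]
            if sums["total_ddds"] > 0 else np.nan
        )
        row["private_ddd_pct"] = 100.0 - row["public_ddd_pct"]
        row["public_cost_pct"] = (
            100.0 * sums["public_cost"] / sums["total_cost"]
            if sums["total_cost"] > 0 else np.nan
        )
        row["private_cost_pct"] = 100.0 - row["public_cost_pct"]
        out = pd.concat([out, pd.DataFrame([row])], ignore_index=True)
    cols = [
        group,
        "public_ddds", "public_ddd_pct",
        "private_ddds", "private_ddd_pct",
        "total_ddds",
        "public_cost", "public_cost_pct",
        "private_cost", "private_cost_pct",
        "total_cost",
    ]
    return out[cols]


def formulation_count(
    frame: pd.DataFrame,
    sector: Optional[str] = None,
    route: Optional[str] = None,
) -> int:
    """Distinct molecules with positive DDD volume under the filters."""
    if frame.empty:
        return 0
    _require(frame, ["molecule", "total_ddds"])
    sub = frame
    if sector is not None:
        _require(frame, ["sector"])
        sub = sub[sub["sector"] == sector]
    if route is not None:
        _require(frame, ["route"])
        sub = sub[sub["route"] == route]
    volume = sub.groupby("molecule")["total_ddds"].sum()
    return int((volume > 0).sum())


def top_n(
    table: pd.DataFrame,
    n: int,
    by: str = "total_ddds",
    remainder_label: str = "All the other",
) -> pd.DataFrame:
    """Keep the n largest rows of a share table, fold the rest into one row.

    ``table`` is a :func:`share_table` output (a totals row, if present, is
    set aside and re-appended).  The remainder row's totals equal the grand
    totals minus the top-n sums, so conservation holds exactly; its shares
    and cost per DDD are recomputed from those unrounded totals.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if by not in ("total_ddds", "total_cost"):
        raise ValueError(f"can rank by total_ddds or total_cost, not {by!r}")
    group = table.columns[0]
    body = table[table[group] != TOTAL_LABEL].copy()
    total_row = table[table[group] == TOTAL_LABEL]
    body = body.sort_values(
        [by, group], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if n >= len(body):
        return table.copy()
    head = body.iloc[:n].copy()
    rest = body.iloc[n:]
    grand_ddd = float(body["total_ddds"].sum())
    grand_cost = float(body["total_cost"].sum())
    rem_ddd = float(rest["total_ddds"].sum())
    rem_cost = float(rest["total_cost"].sum())
    remainder = {
        group: remainder_label,
        "total_ddds": rem_ddd,
        "ddd_share_pct": 100.0 * rem_ddd / grand_ddd if grand_ddd > 0 else np.nan,
        "total_cost": rem_cost,
        "cost_share_pct": 100.0 * rem_cost / grand_cost if grand_cost > 0 else np.nan,
        "cost_per_ddd": rem_cost / rem_ddd if rem_ddd > 0 else np.nan,
    }
    if "label" in table.columns:
        remainder["label"] = remainder_label
    out = pd.concat([head, pd.DataFrame([remainder])], ignore_index=True)
    if not total_row.empty:
        out = pd.concat([out, total_row], ignore_index=True)
    return out[table.columns]
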