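"""Spending metrics under selectable price bases.

Private-sector records can be costed at MRP (the ceiling retail price
actually paid at the point of care) or at the wholesale price (MRP net of
the retail margin) for sensitivity analysis; public-sector records are
always costed at the procurement price.  When a record carries no
wholesale price, it can be derived from a configured margin ``m`` as
``wholesale = MRP / (1 + m)`` — globally or per ATC-3 group.

Derived metrics: total cost, cost per DDD (NaN-flagged when a stratum has
zero DDDs — never infinity) and per-capita cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "PriceBasis",
    "BasisError",
    "record_cost",
    "add_costs",
    "cost_per_ddd",
    "per_capita_cost",
    "sensitivity_compare",
]

_KINDS = ("mrp", "wholesale", "procurement")

#: default retail/hospital margin used to derive wholesale prices when a
#: record carries none (the sensitivity analysis reports results as a
#: function of this assumption).
DEFAULT_MARGIN = 0.20


class BasisError(ValueError):
    """Requested price basis is unavailable or invalid for a record."""


@dataclass(frozen=True)
class PriceBasis:
    """Which price column values a record's cost.

    ``margin_fallback`` may be a scalar margin or a mapping from ATC-3
    prefix to margin; it is only consulted for the wholesale basis when a
    record has no observed wholesale price.
    """

    kind: str
    margin_fallback: Union[float, Mapping[str, float], None] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise BasisError(f"unknown price basis {self.kind!r}; expected one of {_KINDS}")
        if isinstance(self.margin_fallback, (int, float)) and self.margin_fallback < 0:
            raise BasisError("margin_fallback must be >= 0")

    def margin_for(self, atc3: Optional[str]) -> Optional[float]:
        if self.margin_fallback is None:
            return None
        if isinstance(self.margin_fallback, (int, float)):
            return float(self.margin_fallback)
        if atc3 is None:
            raise BasisError("per-ATC3 margin table requires the record's ATC3 group")
        try:
            return float(self.margin_fallback[atc3])
        except KeyError:
            raise BasisError(f"no margin configured for ATC3 group {atc3!r}") from None


MRP = PriceBasis("mrp")
WHOLESALE = PriceBasis("wholesale", DEFAULT_MARGIN)
PROCUREMENT = PriceBasis("procurement")


def _unit_price(record, basis: PriceBasis, atc3: Optional[str]) -> float:
    sector = record.sector
    if basis.kind == "procurement":
        if sector != "public":
            raise BasisError("procurement basis is only valid for public-sector records")
        return record.procurement_cost_per_pack
    if sector != "private":
        raise BasisError(f"{basis.kind} basis is only valid for private-sector records")
    if basis.kind == "mrp":
        return record.mrp_per_pack
    # wholesale
    if record.wholesale_per_pack is not None:
        return record.wholesale_per_pack
    m = basis.margin_for(atc3)
    if m is None:
        raise BasisError(
            f"record {record.molecule_name!r} has no wholesale price and no "
            "margin_fallback is configured"
        )
    return record.mrp_per_pack / (1.0 + m)


def record_cost(record, basis: PriceBasis, atc3: Optional[str] = None) -> float:
    """Annual cost of one record: unit price under the basis x packs/year."""
    return _unit_price(record, basis, atc3) * record.packs_per_year


def add_costs(frame: pd.DataFrame, basis: PriceBasis) -> pd.DataFrame:
    """Return a copy of an annotated frame with a ``cost`` column.

    ``basis`` governs private rows; public rows are always costed at the
    procurement price (requesting the procurement basis directly is only
    valid when the frame holds no private rows).
    """
    out = frame.copy()
    if out.empty:
        out["cost"] = pd.Series(dtype=float)
        return out
    private = out["sector"] == "private"
    if basis.kind == "procurement" and bool(private.any()):
        raise BasisError("procurement basis is only valid for public-sector records")
    price = out["procurement_cost_per_pack"].astype(float).copy()
    if basis.kind == "mrp":
        price[private] = out.loc[private, "mrp_per_pack"].astype(float)
    elif basis.kind == "wholesale":
        wholesale = out.loc[private, "wholesale_per_pack"].astype(float)
        missing = wholesale.isna()
        if bool(missing.any()):
            if basis.margin_fallback is None:
                raise BasisError(
                    "some private records have no wholesale price and no "
                    "margin_fallback is configured"
                )
            if isinstance(basis.margin_fallback, (int, float)):
                margins = pd.Series(float(basis.margin_fallback), index=wholesale.index)
            else:
                margins = out.loc[private, "atc3"].map(basis.margin_fallback).astype(float)
                if bool(margins.isna().any()):
                    bad = sorted(out.loc[private, "atc3"][margins.isna()].unique())
                    raise BasisError(f"no margin configured for ATC3 groups {bad}")
            derived = out.loc[private, "mrp_per_pack"].astype(float) / (1.0 + margins)
            wholesale = wholesale.where(~missing, derived)
        price[private] = wholesale
    if bool(price.isna().any()):
        raise BasisError(f"missing {basis.kind} price on one or more records")
    out["cost"] = price * out["packs_per_year"].astype(float)
    return out


def cost_per_ddd(total_cost: float, total: float) -> float:
    """Cost per DDD; NaN (undefined) when there are no DDDs."""
    if total <= 0:
        return float("nan")
    return total_cost / total


def per_capita_cost(total_cost: float, population_thousands: float) -> float:
    """Cost per person (population given in thousands)."""
    if not population_thousands > 0:
        raise ValueError(f"population must be positive, got {population_thousands}")
    return total_cost / (population_thousands * 1000.0)


def sensitivity_compare(
    frame: pd.DataFrame,
    bases: tuple[PriceBasis, PriceBasis] = (MRP, WHOLESALE),
    group: str = "sector",
) -> pd.DataFrame:
    """Cost shares per stratum under two price bases, and their gap.

    One row per value of ``group``; columns ``cost_<kind>``,
    ``share_<kind>_pct`` for each basis and ``diff_pp`` (first basis share
    minus second, in percentage points).
    """
    b0, b1 = bases
    if b0.kind == b1.kind and b0 == b1:
        pass  # identical bases are allowed; the gap is then exactly 0
    pieces = []
    for basis in (b0, b1):
        costed = add_costs(frame, basis)
        totals = costed.groupby(group)["cost"].sum()
        share = 100.0 * totals / totals.sum() if totals.sum() > 0 else totals * np.nan
        pieces.append(
            pd.DataFrame(
                {f"cost_{basis.kind}": totals, f"share_{basis.kind}_pct": share}
            )
        )
    out = pd.concat(pieces, axis=1).reset_index()
    share_cols = [f"share_{b.kind}_pct" for b in (b0, b1)]
    out["diff_pp"] = out[share_cols[0]] - out[share_cols[1]]
    return out
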