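"""DDD conversion and population-normalized consumption rates.

The two core quantities of drug-utilization analysis:

* total DDDs of a product-year record::

      total_ddds = strength * pack_size * packs_per_year / DDD

  with strength and DDD reduced to the same canonical unit (mg, or MU
  for unit-dosed molecules such as benzylpenicillin — the two are never
  interconverted);

* DID, the consumption rate per 1000 population per day::

      did = total_ddds / (population_thousands * 365)

Multi-year results are computed per year and then averaged arithmetically,
not pooled.  Records whose molecule has no registry DDD are excluded from
totals but surfaced in a coverage report, never dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .ingest import PopulationTable, ProcurementRecord, SalesRecord, normalize_strength
from .registry import AwareClass, DddAssignment, Registry, Route

__all__ = [
    "DAYS_PER_YEAR",
    "DddResult",
    "DidValue",
    "UnitMismatchError",
    "RouteMismatchError",
    "MissingYearError",
    "ddd_per_pack",
    "ddds_for_record",
    "total_ddds",
    "did",
    "did_by_year",
    "multi_year_average",
    "annotate",
]

#: the formula's fixed year length; leap years are deliberately ignored.
DAYS_PER_YEAR = 365


class UnitMismatchError(ValueError):
    """Strength and DDD are in incompatible units (mass vs MU)."""


class RouteMismatchError(ValueError):
    """Record route differs from the DDD assignment's route."""


class MissingYearError(KeyError):
    """A requested year is absent from a yearly series."""


@dataclass(frozen=True)
class DddResult:
    ddd_per_pack: float
    total_ddds: float
    record: object = None


@dataclass(frozen=True)
class DidValue:
    total_ddds: float
    population_thousands: float
    days: int
    did: float


def ddd_per_pack(
    strength_value: float,
    strength_unit,
    pack_size: int,
    ddd_value: float,
    ddd_unit,
) -> float:
    """Number of DDDs contained in one pack."""
    sv, su = normalize_strength(strength_value, strength_unit)
    dv, du = normalize_strength(ddd_value, ddd_unit)
    if su is not du:
        raise UnitMismatchError(
            f"strength in {su.value} cannot be divided by a DDD in {du.value}"
        )
    return sv * pack_size / dv


def ddds_for_record(
    record: Union[SalesRecord, ProcurementRecord], assignment: DddAssignment
) -> DddResult:
    """Apply the DDD formula to one record under its registry assignment."""
    if assignment.route != record.route:
        raise RouteMismatchError(
            f"record route {record.route.value} != assignment route "
            f"{assignment.route.value} for {record.molecule_name!r}"
        )
    dpp = ddd_per_pack(
        record.strength_value,
        record.strength_unit,
        record.pack_size,
        assignment.ddd_value,
        assignment.ddd_unit,
    )
    return DddResult(dpp, dpp * record.packs_per_year, record)


def total_ddds(results, predicate=None) -> float:
    """Sum of total DDDs over results (DddResult iterable or annotated frame)."""
    if isinstance(results, pd.DataFrame):
        frame = results if predicate is None else results[results.apply(predicate, axis=1)]
        return float(frame["total_ddds"].sum())
    vals = (r.total_ddds for r in results if predicate is None or predicate(r))
    return math.fsum(vals)


def did(total: float, population_thousands: float, days: int = DAYS_PER_YEAR) -> DidValue:
    """DDD per 1000 population per day."""
    if not population_thousands > 0:
        raise ValueError(f"population must be positive, got {population_thousands}")
    return DidValue(total, population_thousands, days, total / (population_thousands * days))


def did_by_year(
    frame: pd.DataFrame, population: PopulationTable, region: str
) -> dict[int, DidValue]:
    """Per-year DID for one region from an annotated record frame."""
    out: dict[int, DidValue] = {}
    sub = frame[frame["region"] == region]
    for year, grp in sub.groupby("year"):
        out[int(year)] = did(float(grp["total_ddds"].sum()), population.get(region, int(year)))
    return out


def multi_year_average(
    yearly: Mapping[int, float], years: Optional[Iterable[int]] = None
) -> float:
    """Arithmetic mean of a yearly series over the requested years."""
    ys = sorted(yearly) if years is None else sorted(years)
    if not ys:
        raise MissingYearError("no years requested")
    missing = [y for y in ys if y not in yearly]
    if missing:
        raise MissingYearError(f"missing years {missing}")
    return math.fsum(yearly[y] for y in ys) / len(ys)


_COVERAGE_COLUMNS = ["molecule", "route", "reason", "packs", "spend"]


def annotate(
    records: Iterable[Union[SalesRecord, ProcurementRecord]], registry: Registry
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join records against the registry and apply the DDD formula.

    Returns ``(frame, coverage)``: the annotated per-record frame (one row
    per covered record, with ATC prefixes, AWaRe class, ddd_per_pack and
    total_ddds) and the coverage report of excluded records (molecule,
    route, reason, packs, spend).  The spend column uses MRP for private
    records and procurement cost for public ones.
    """
    rows: list[dict] = []
    excluded: list[dict] = []
    for rec in records:
        assignment = registry.lookup(rec.molecule_name, rec.route)
        spend_price = (
            rec.mrp_per_pack if rec.sector == "private" else rec.procurement_cost_per_pack
        )
        if assignment is None:
            excluded.append(
                {
                    "molecule": rec.molecule_name,
                    "route": rec.route.value,
                    "reason": "not_in_registry",
                    "packs": rec.packs_per_year,
                    "spend": spend_price * rec.packs_per_year,
                }
            )
            continue
        try:
            result = ddds_for_record(rec, assignment)
        except (UnitMismatchError, RouteMismatchError) as exc:
            reason = (
                "unit_mismatch" if isinstance(exc, UnitMismatchError) else "route_mismatch"
            )
            excluded.append(
                {
                    "molecule": rec.molecule_name,
                    "route": rec.route.value,
                    "reason": reason,
                    "packs": rec.packs_per_year,
                    "spend": spend_price * rec.packs_per_year,
                }
            )
            continue
        rows.append(
            {
                "sector": rec.sector,
                "region": rec.region,
                "year": rec.year,
                "route": rec.route.value,
                "molecule": rec.molecule_name,
                "aware": assignment.aware.value,
                "atc5": assignment.atc5.code,
                "atc4": assignment.atc5.prefix(4),
                "atc3": assignment.atc5.prefix(3),
                "atc4_label": registry.atc_labels.get(
                    assignment.atc5.prefix(4), assignment.atc5.prefix(4)
                ),
                "atc3_label": registry.atc_labels.get(
                    assignment.atc5.prefix(3), assignment.atc5.prefix(3)
                ),
                "is_fdc": assignment.is_fdc,
                "strength_value": rec.strength_value,
                "strength_unit": rec.strength_unit.value,
                "pack_size": rec.pack_size,
                "packs_per_year": rec.packs_per_year,
                "ddd_per_pack": result.ddd_per_pack,
                "total_ddds": result.total_ddds,
                "mrp_per_pack": getattr(rec, "mrp_per_pack", float("nan")),
                "wholesale_per_pack": (
                    float("nan")
                    if getattr(rec, "wholesale_per_pack", None) is None
                    else rec.wholesale_per_pack
                ),
                "procurement_cost_per_pack": getattr(
                    rec, "procurement_cost_per_pack", float("nan")
                ),
            }
        )
    frame = pd.DataFrame(rows)
    coverage = pd.DataFrame(excluded, columns=_COVERAGE_COLUMNS)
    if not coverage.empty:
        coverage = (
            coverage.groupby(["molecule", "route", "reason"], as_index=False)[
                ["packs", "spend"]
            ]
            .sum()
            .sort_values(["molecule", "route"], kind="mergesort")
            .reset_index(drop=True)
        )
    return frame, coverage
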