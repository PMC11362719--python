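"""Reading and validating sales, procurement and population inputs.

Private-sector sales records and public-sector procurement records are
normalized into a common internal shape tagged by sector, so the DDD and
cost engines never need to know which file a record came from.  Ingest is
lossless: every input row is either accepted or lands in a rejects report
with its row number and offending column — nothing is silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .registry import Route, Unit, normalize_name

__all__ = [
    "SalesRecord",
    "ProcurementRecord",
    "RejectedRow",
    "PopulationTable",
    "IngestError",
    "MissingPopulationError",
    "read_sales",
    "read_procurement",
    "write_sales",
    "write_procurement",
    "write_rejects",
    "normalize_strength",
    "records_to_frame",
]

#: float format used by every CSV writer; 10 significant digits round-trip
#: the generator's quantized values exactly.
FLOAT_FMT = "%.10g"


class IngestError(ValueError):
    """File-level ingest failure (missing columns, unreadable file)."""


class MissingPopulationError(KeyError):
    """No population row for the requested (region, year)."""


def normalize_strength(value: float, unit: Union[Unit, str]) -> tuple[float, Unit]:
    """Convert a strength to canonical units: g -> mg; mg and MU pass through.

    MU (million units) is deliberately never converted to mass.
    """
    unit = Unit(unit)
    if unit is Unit.G:
        return value * 1000.0, Unit.MG
    return float(value), unit


@dataclass(frozen=True)
class SalesRecord:
    """One private-sector product–pack–year observation."""

    product_id: str
    molecule_name: str
    route: Route
    strength_value: float
    strength_unit: Unit
    pack_size: int
    packs_per_year: float
    mrp_per_pack: float
    wholesale_per_pack: Optional[float]
    year: int
    region: str

    sector = "private"

    def __post_init__(self) -> None:
        _check_common(self)
        if self.mrp_per_pack < 0:
            raise ValueError("mrp_per_pack")
        if self.wholesale_per_pack is not None:
            if self.wholesale_per_pack < 0:
                raise ValueError("wholesale_per_pack")
            if self.wholesale_per_pack > self.mrp_per_pack:
                raise ValueError("wholesale_per_pack")
        object.__setattr__(self, "molecule_name", normalize_name(self.molecule_name))


@dataclass(frozen=True)
class ProcurementRecord:
    """One public-sector procurement observation."""

    molecule_name: str
    route: Route
    strength_value: float
    strength_unit: Unit
    pack_size: int
    packs_per_year: float
    procurement_cost_per_pack: float
    year: int
    region: str

    sector = "public"

    def __post_init__(self) -> None:
        _check_common(self)
        if self.procurement_cost_per_pack < 0:
            raise ValueError("procurement_cost_per_pack")
        object.__setattr__(self, "molecule_name", normalize_name(self.molecule_name))


def _check_common(rec) -> None:
    if not rec.strength_value > 0:
        raise ValueError("strength_value")
    if rec.pack_size < 1:
        raise ValueError("pack_size")
    if rec.packs_per_year < 0:
        raise ValueError("packs_per_year")


@dataclass(frozen=True)
class RejectedRow:
    row: int
    column: str
    reason: str


SALES_COLUMNS = (
    "product_id",
    "molecule",
    "route",
    "strength_value",
    "strength_unit",
    "pack_size",
    "packs_per_year",
    "mrp_per_pack",
    "wholesale_per_pack",
    "year",
    "region",
)

PROCUREMENT_COLUMNS = (
    "molecule",
    "route",
    "strength_value",
    "strength_unit",
    "pack_size",
    "packs_per_year",
    "procurement_cost_per_pack",
    "year",
    "region",
)


def _open_reader(path: Union[str, Path], required: Sequence[str]):
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        fh.close()
        raise IngestError(f"{path}: empty file, expected a header row")
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        fh.close()
        raise IngestError(f"{path}: missing mandatory columns {missing}")
    return fh, reader


def _parse(row: Mapping[str, str], column: str, kind):
    raw = (row.get(column) or "").strip()
    try:
        return kind(raw)
    except (ValueError, TypeError):
        raise ValueError(column) from None


def read_sales(path: Union[str, Path]) -> tuple[list[SalesRecord], list[RejectedRow]]:
    """Parse a sales CSV.  Returns (accepted records, rejected rows).

    accepted + rejected always equals the number of input rows; a hard
    :class:`IngestError` is raised only for file-level problems.
    """
    accepted: list[SalesRecord] = []
    rejected: list[RejectedRow] = []
    fh, reader = _open_reader(path, SALES_COLUMNS)
    with fh:
        for i, row in enumerate(reader, start=2):
            try:
                wholesale_raw = (row.get("wholesale_per_pack") or "").strip()
                rec = SalesRecord(
                    product_id=(row.get("product_id") or "").strip(),
                    molecule_name=_parse(row, "molecule", str),
                    route=_parse(row, "route", Route),
                    strength_value=_parse(row, "strength_value", float),
                    strength_unit=_parse(row, "strength_unit", Unit),
                    pack_size=_parse(row, "pack_size", int),
                    packs_per_year=_parse(row, "packs_per_year", float),
                    mrp_per_pack=_parse(row, "mrp_per_pack", float),
                    wholesale_per_pack=float(wholesale_raw) if wholesale_raw else None,
                    year=_parse(row, "year", int),
                    region=_parse(row, "region", str),
                )
            except ValueError as exc:
                col = str(exc) if str(exc) in SALES_COLUMNS + ("wholesale_per_pack",) else "row"
                rejected.append(RejectedRow(i, col, f"invalid {col}"))
                continue
            accepted.append(rec)
    return accepted, rejected


def read_procurement(
    path: Union[str, Path]
) -> tuple[list[ProcurementRecord], list[RejectedRow]]:
    """Parse a procurement CSV; same accept/reject contract as read_sales."""
    accepted: list[ProcurementRecord] = []
    rejected: list[RejectedRow] = []
    fh, reader = _open_reader(path, PROCUREMENT_COLUMNS)
    with fh:
        for i, row in enumerate(reader, start=2):
            try:
                rec = ProcurementRecord(
                    molecule_name=_parse(row, "molecule", str),
                    route=_parse(row, "route", Route),
                    strength_value=_parse(row, "strength_value", float),
                    strength_unit=_parse(row, "strength_unit", Unit),
                    pack_size=_parse(row, "pack_size", int),
                    packs_per_year=_parse(row, "packs_per_year", float),
                    procurement_cost_per_pack=_parse(row, "procurement_cost_per_pack", float),
                    year=_parse(row, "year", int),
                    region=_parse(row, "region", str),
                )
            except ValueError as exc:
                col = str(exc) if str(exc) in PROCUREMENT_COLUMNS else "row"
                rejected.append(RejectedRow(i, col, f"invalid {col}"))
                continue
            accepted.append(rec)
    return accepted, rejected


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return FLOAT_FMT % x
    return str(x)


def write_sales(records: Iterable[SalesRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SALES_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.product_id,
                    r.molecule_name,
                    r.route.value,
                    _fmt(r.strength_value),
                    r.strength_unit.value,
                    r.pack_size,
                    _fmt(r.packs_per_year),
                    _fmt(r.mrp_per_pack),
                    _fmt(r.wholesale_per_pack),
                    r.year,
                    r.region,
                ]
            )


def write_procurement(records: Iterable[ProcurementRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PROCUREMENT_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.molecule_name,
                    r.route.value,
                    _fmt(r.strength_value),
                    r.strength_unit.value,
                    r.pack_size,
                    _fmt(r.packs_per_year),
                    _fmt(r.procurement_cost_per_pack),
                    r.year,
                    r.region,
                ]
            )


def write_rejects(rejects: Iterable[RejectedRow], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "column", "reason"])
        for r in rejects:
            w.writerow([r.row, r.column, r.reason])


@dataclass
class PopulationTable:
    """Mid-year populations, in thousands, keyed by (region, year)."""

    _pop: dict[tuple[str, int], float]

    @classmethod
    def from_mapping(cls, mapping: Mapping[tuple[str, int], float]) -> "PopulationTable":
        tbl = cls({})
        for (region, year), value in mapping.items():
            tbl.add(region, int(year), float(value))
        return tbl

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "PopulationTable":
        tbl = cls({})
        fh, reader = _open_reader(path, ("region", "year", "population_thousands"))
        with fh:
            for i, row in enumerate(reader, start=2):
                try:
                    region = row["region"].strip()
                    year = int(row["year"])
                    pop = float(row["population_thousands"])
                except (ValueError, AttributeError):
                    raise IngestError(f"{path}: malformed population row {i}") from None
                tbl.add(region, year, pop)
        return tbl

    def add(self, region: str, year: int, population_thousands: float) -> None:
        if not population_thousands > 0:
            raise IngestError(
                f"population for ({region}, {year}) must be positive, "
                f"got {population_thousands}"
            )
        key = (region, year)
        if key in self._pop:
            raise IngestError(f"duplicate population row for ({region}, {year})")
        self._pop[key] = population_thousands

    def get(self, region: str, year: int) -> float:
        try:
            return self._pop[(region, int(year))]
        except KeyError:
            raise MissingPopulationError(
                f"no population for region {region!r}, year {year}"
            ) from None

    def years(self, region: str) -> list[int]:
        return sorted(y for (r, y) in self._pop if r == region)

    def write_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "year", "population_thousands"])
            for (region, year), pop in sorted(self._pop.items()):
                w.writerow([region, year, _fmt(pop)])

    def __len__(self) -> int:
        return len(self._pop)


def records_to_frame(
    records: Iterable[Union[SalesRecord, ProcurementRecord]]
) -> pd.DataFrame:
    """Stack mixed-sector records into one DataFrame (sector as a column)."""
    rows = []
    for r in records:
        row = {
            "sector": r.sector,
            "product_id": getattr(r, "product_id", ""),
            "molecule": r.molecule_name,
            "route": r.route.value,
            "strength_value": r.strength_value,
            "strength_unit": r.strength_unit.value,
            "pack_size": r.pack_size,
            "packs_per_year": r.packs_per_year,
            "mrp_per_pack": getattr(r, "mrp_per_pack", float("nan")),
            "wholesale_per_pack": (
                float("nan")
                if getattr(r, "wholesale_per_pack", None) is None
                else r.wholesale_per_pack
            ),
            "procurement_cost_per_pack": getattr(
                r, "procurement_cost_per_pack", float("nan")
            ),
            "year": r.year,
            "region": r.region,
        }
        rows.append(row)
    return pd.DataFrame(rows)
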