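"""ATC/DDD/AWaRe reference registry.

Every consumption metric downstream hangs on a single mapping: an
antibiotic molecule used by a given route (oral or injectable) has one
WHO defined daily dose (DDD), one position in the ATC hierarchy and one
AWaRe stewardship class (Access / Watch / Reserve, plus the WHO
"not recommended" fixed-dose combinations, carried here as Discouraged).
This module loads that mapping from a TSV registry, validates it, and
answers the three queries the pipeline needs:

* :func:`lookup_ddd` — the DDD assignment for a (molecule, route) pair;
* :func:`classify_aware` — the AWaRe class, with ``NotListed`` as the
  fallback for molecules absent from the registry;
* :func:`atc_group` — the ATC level-3/4/5 code prefix and display label.

Molecule names are folded to a canonical form (lower case, collapsed
whitespace, combination separators such as `` - `` or ``/`` folded to
``+``) so that e.g. ``"Ceftriaxone - sulbactam"`` and
``"ceftriaxone+sulbactam"`` address the same entry.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Route",
    "Unit",
    "AwareClass",
    "AtcCode",
    "DddAssignment",
    "Registry",
    "RegistryError",
    "normalize_name",
    "load_registry",
    "lookup_ddd",
    "classify_aware",
    "atc_group",
]


class Route(str, Enum):
    ORAL = "oral"
    INJECTABLE = "injectable"


class Unit(str, Enum):
    MG = "mg"
    G = "g"
    #: million international units (benzylpenicillin-style dosing);
    #: never convertible to mass units.
    MU = "MU"


class AwareClass(str, Enum):
    ACCESS = "Access"
    WATCH = "Watch"
    RESERVE = "Reserve"
    #: WHO "not recommended" fixed-dose combinations.
    DISCOURAGED = "Discouraged"
    #: fallback for molecules absent from the registry.
    NOT_LISTED = "NotListed"


class RegistryError(ValueError):
    """Invalid or internally inconsistent registry content."""


_WS = re.compile(r"\s+")
# Combination separators: "+", "/", or a hyphen/en-dash with whitespace on
# at least one side.  A tightly hyphenated single name is left alone.
_COMBO = re.compile(r"\s*\+\s*|\s*/\s*|\s+[-–]\s*|\s*[-–]\s+")


def normalize_name(name: str) -> str:
    """Fold a molecule name to canonical form (idempotent)."""
    s = _WS.sub(" ", name.strip().lower())
    return _COMBO.sub("+", s)


_PREFIX_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_LEN_LEVEL = {v: k for k, v in _PREFIX_LEN.items()}
_ATC5 = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


@dataclass(frozen=True)
class AtcCode:
    """An ATC code or code prefix (level 1–5)."""

    code: str

    def __post_init__(self) -> None:
        if len(self.code) not in _LEN_LEVEL:
            raise RegistryError(
                f"ATC code {self.code!r} has invalid length {len(self.code)}"
            )
        if len(self.code) == 7 and not _ATC5.match(self.code):
            raise RegistryError(f"malformed level-5 ATC code {self.code!r}")

    @property
    def level(self) -> int:
        return _LEN_LEVEL[len(self.code)]

    def prefix(self, level: int) -> str:
        """Truncate to the prefix that identifies ``level`` (3 -> 'J01D')."""
        if level not in _PREFIX_LEN:
            raise RegistryError(f"ATC level must be 1..5, got {level}")
        n = _PREFIX_LEN[level]
        if n > len(self.code):
            raise RegistryError(
                f"cannot truncate level-{self.level} code {self.code!r} to level {level}"
            )
        return self.code[:n]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass(frozen=True)
class DddAssignment:
    """One registry row: molecule + route -> DDD, ATC position, AWaRe class.

    ``ddd_value`` is expressed in ``ddd_unit`` (g, mg or MU).  Fixed-dose
    combinations (``is_fdc``) list their components; where the WHO index
    assigns no combination DDD the row carries the principal component's
    DDD and ``ddd_source == "principal_component"``.
    """

    molecule_name: str
    atc5: AtcCode
    route: Route
    ddd_value: float
    ddd_unit: Unit
    aware: AwareClass
    is_fdc: bool = False
    components: tuple[str, ...] = ()
    ddd_source: str = "who"

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecule_name", normalize_name(self.molecule_name))
        if not self.ddd_value > 0:
            raise RegistryError(
                f"DDD for {self.molecule_name!r} must be positive, got {self.ddd_value}"
            )
        if self.atc5.level != 5:
            raise RegistryError(
                f"entry {self.molecule_name!r} needs a full level-5 ATC code, got {self.atc5.code!r}"
            )
        if self.is_fdc and len(self.components) < 2:
            raise RegistryError(
                f"FDC entry {self.molecule_name!r} must list >=2 components"
            )

    @property
    def key(self) -> tuple[str, Route]:
        return (self.molecule_name, self.route)


@dataclass
class Registry:
    """Queryable collection of DDD assignments plus ATC display labels."""

    _entries: dict[tuple[str, Route], DddAssignment] = field(default_factory=dict)
    atc_labels: dict[str, str] = field(default_factory=dict)

    def add(self, entry: DddAssignment) -> None:
        if entry.key in self._entries:
            raise RegistryError(
                f"duplicate registry entry for ({entry.molecule_name!r}, {entry.route.value})"
            )
        self._entries[entry.key] = entry

    def lookup(self, molecule: str, route: Route | str) -> Optional[DddAssignment]:
        """Return the unique assignment for (molecule, route), or None.

        Never substitutes the other route's DDD.
        """
        route = Route(route)
        return self._entries.get((normalize_name(molecule), route))

    def classify_aware(self, molecule: str, route: Route | str) -> AwareClass:
        hit = self.lookup(molecule, route)
        return hit.aware if hit is not None else AwareClass.NOT_LISTED

    def atc_group(self, assignment: DddAssignment, level: int) -> tuple[str, str]:
        """(code prefix, display label) for ATC level 3, 4 or 5.

        The level-5 label is the molecule name itself.
        """
        if level not in (3, 4, 5):
            raise RegistryError(f"ATC grouping level must be 3, 4 or 5, got {level}")
        prefix = assignment.atc5.prefix(level)
        if level == 5:
            return prefix, assignment.molecule_name
        try:
            return prefix, self.atc_labels[prefix]
        except KeyError:
            raise RegistryError(f"no ATC label for prefix {prefix!r}") from None

    @property
    def entries(self) -> list[DddAssignment]:
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[DddAssignment]:
        return iter(self._entries.values())

    def validate_labels(self) -> None:
        """Every ATC-3/4 prefix reachable from the entries must be labelled."""
        for e in self:
            for level in (3, 4):
                prefix = e.atc5.prefix(level)
                if prefix not in self.atc_labels:
                    raise RegistryError(
                        f"label map misses prefix {prefix!r} (from {e.molecule_name!r})"
                    )


_REQUIRED_COLUMNS = (
    "molecule",
    "atc5",
    "route",
    "ddd_value",
    "ddd_unit",
    "aware",
    "is_fdc",
    "components",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _parse_bool(raw: str, row_no: int) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RegistryError(f"row {row_no}: cannot parse is_fdc value {raw!r}")


def load_registry(path: str | Path, labels_path: str | Path | None = None) -> Registry:
    """Load a registry TSV (and optionally an ATC label TSV).

    Registry columns: molecule, atc5, route, ddd_value, ddd_unit, aware,
    is_fdc, components (semicolon-separated), ddd_source (optional).
    Label columns: prefix, level, label.

    Raises :class:`RegistryError` on duplicate (molecule, route) pairs,
    non-positive DDDs, or unknown unit / route / class strings.
    """
    reg = Registry()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: empty file, expected a header row")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RegistryError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                ddd_value = float(row["ddd_value"])
            except ValueError:
                raise RegistryError(
                    f"row {i}: malformed ddd_value {row['ddd_value']!r}"
                ) from None
            try:
                unit = Unit(row["ddd_unit"].strip())
            except ValueError:
                raise RegistryError(
                    f"row {i}: unknown unit {row['ddd_unit']!r}"
                ) from None
            try:
                route = Route(row["route"].strip().lower())
                aware = AwareClass(row["aware"].strip())
            except ValueError as exc:
                raise RegistryError(f"row {i}: {exc}") from None
            components = tuple(
                normalize_name(c) for c in row["components"].split(";") if c.strip()
            )
            entry = DddAssignment(
                molecule_name=row["molecule"],
                atc5=AtcCode(row["atc5"].strip()),
                route=route,
                ddd_value=ddd_value,
                ddd_unit=unit,
                aware=aware,
                is_fdc=_parse_bool(row["is_fdc"], i),
                components=components,
                ddd_source=(row.get("ddd_source") or "who").strip(),
            )
            reg.add(entry)
    if labels_path is not None:
        reg.atc_labels.update(load_atc_labels(labels_path))
        reg.validate_labels()
    return reg


def load_atc_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            prefix = row["prefix"].strip()
            if prefix in labels:
                raise RegistryError(f"row {i}: duplicate label for prefix {prefix!r}")
            labels[prefix] = row["label"].strip()
    return labels


# -- thin functional façade ------------------------------------------------

def lookup_ddd(reg: Registry, molecule: str, route: Route | str) -> Optional[DddAssignment]:
    return reg.lookup(molecule, route)


def classify_aware(reg: Registry, molecule: str, route: Route | str) -> AwareClass:
    return reg.classify_aware(molecule, route)


def atc_group(reg: Registry, assignment: DddAssignment, level: int) -> tuple[str, str]:
    return reg.atc_group(assignment, level)
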