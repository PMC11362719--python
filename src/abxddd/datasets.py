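"""Bundled reference data and published-table fixtures.

Ships two kinds of data:

* the ATC/DDD/AWaRe registry fixture (``registry.tsv`` + ``atc_labels.tsv``),
  with DDD values transcribed from the WHO ATC/DDD index and AWaRe classes
  from the WHO 2021 list;
* molecule/group-level consumption and cost totals transcribed from the
  published national (India) and Kerala two-sector tables, used as test
  oracles and as small demo inputs.  DDD columns are absolute DDDs and
  cost columns absolute INR; ``printed_*`` columns carry the published
  display-rounded shares for comparison.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .registry import Registry, load_registry

__all__ = [
    "load_bundled_registry",
    "bundled_registry_path",
    "load_published_table",
    "national_population_thousands",
    "table18_records_frame",
]

_TABLES = ("table01", "table02", "table03", "table04", "table05",
           "table06", "table08", "table09", "table18")


def _data_path(*parts: str):
    return resources.files("abxddd").joinpath("data", *parts)


def bundled_registry_path() -> tuple[str, str]:
    """(registry TSV path, ATC label TSV path) of the bundled fixture."""
    return str(_data_path("registry.tsv")), str(_data_path("atc_labels.tsv"))


def load_bundled_registry() -> Registry:
    reg_path, labels_path = bundled_registry_path()
    return load_registry(reg_path, labels_path)


def load_published_table(name: str) -> pd.DataFrame:
    """Load a published-table fixture by id (e.g. ``"table02"``)."""
    if name not in _TABLES:
        raise KeyError(f"unknown table fixture {name!r}; available: {_TABLES}")
    with resources.as_file(_data_path("published_tables", f"{name}.csv")) as p:
        return pd.read_csv(p)


def national_population_thousands() -> float:
    """National projected population (2011-census based), in thousands."""
    with resources.as_file(_data_path("published_tables", "national_population.csv")) as p:
        df = pd.read_csv(p)
    return float(df.loc[df["region"] == "IN", "population_thousands"].iloc[0])


def table18_records_frame() -> pd.DataFrame:
    """The molecule x sector injectable table as an aggregate-ready frame.

    Returns one row per molecule and sector with ``total_ddds`` and
    ``cost`` columns, suitable for :mod:`abxddd.aggregate` operations.
    """
    t = load_published_table("table18")
    rows = []
    for _, r in t.iterrows():
        for sector in ("private", "public"):
            rows.append(
                {
                    "molecule": r["molecule"],
                    "route": "injectable",
                    "sector": sector,
                    "total_ddds": float(r[f"{sector}_ddds"]),
                    "cost": float(r[f"{sector}_cost_inr"]),
                }
            )
    return pd.DataFrame(rows)
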