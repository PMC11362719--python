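"""Synthetic sales/procurement data with exact ground truth.

The real inputs this pipeline was designed for (market-audit sales panels
and state procurement ledgers) are proprietary, so the generator emulates
their statistical structure: a molecule catalogue with route-specific
DDDs, four annual cross-sections, a public/private sector split, a price
chain ``procurement <= wholesale <= MRP`` built from multiplicative
mark-ups, heavy-tailed (lognormal) pack volumes, heterogeneous pack sizes
and strengths, and a small fraction of molecules absent from the DDD
registry.

The default configuration IS the study profile: AWaRe volume mix, sector
shares, cost-per-DDD levels and population scaled to the published
Kerala/national figures.  Alongside the CSVs the generator emits a
ground-truth JSON computed by an independent per-record loop (plain
Python arithmetic, no pandas, no calls into the DDD engine), so every
pipeline stage can be checked against an oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .ingest import PopulationTable, ProcurementRecord, SalesRecord
from .registry import AwareClass, Registry, Route, Unit

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "ConfigError",
    "generate",
    "study_profile",
]

DAYS_PER_YEAR = 365


class ConfigError(ValueError):
    """Invalid generator configuration (raised before any output)."""


def _default_population() -> dict[int, float]:
    # Kerala-scale mid-year projections, thousands.
    return {2016: 34700.0, 2017: 34900.0, 2018: 35100.0, 2019: 35330.0}


def _default_aware_mix() -> dict[str, dict[str, float]]:
    # Injectable mix from the published national AWaRe volume shares;
    # oral mix chosen as a realistic Indian outpatient profile (the study
    # reports no oral AWaRe breakdown).
    return {
        "injectable": {"Access": 0.265, "Watch": 0.509, "Reserve": 0.0061,
                       "Discouraged": 0.2199},
        "oral": {"Access": 0.35, "Watch": 0.45, "Reserve": 0.003,
                 "Discouraged": 0.197},
    }


def _default_public_share() -> dict[str, dict[str, float]]:
    # Injectable public volume shares per AWaRe class from the Kerala
    # two-sector table; oral share from the route-level table.
    return {
        "injectable": {"Access": 0.34, "Watch": 0.333, "Reserve": 0.258,
                       "Discouraged": 0.208},
        "oral": {"Access": 0.398, "Watch": 0.398, "Reserve": 0.398,
                 "Discouraged": 0.398},
    }


def _default_price_per_ddd() -> dict[str, float]:
    # Injectable MRP per DDD by AWaRe class (INR), from the national table.
    return {"Access": 167.5, "Watch": 296.2, "Reserve": 2798.8,
            "Discouraged": 345.0}


@dataclass
class GeneratorConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    region: str = "KL"
    population_thousands: dict[int, float] = field(default_factory=_default_population)
    #: expected total DDDs per year across both routes and sectors.
    total_ddds_per_year: float = 285.7e6
    #: expected share of oral preparations in total DDDs.
    oral_ddd_fraction: float = 0.9716
    aware_mix: dict[str, dict[str, float]] = field(default_factory=_default_aware_mix)
    public_share: dict[str, dict[str, float]] = field(default_factory=_default_public_share)
    #: per-molecule uniform jitter (+/-) applied to the class public share.
    sector_split_jitter: float = 0.0
    #: MRP per DDD by AWaRe class for injectables, INR.
    price_per_ddd: dict[str, float] = field(default_factory=_default_price_per_ddd)
    #: oral prices are this fraction of the injectable class price
    #: (oral cost/DDD is roughly a tenth of injectable in the study data).
    oral_price_scale: float = 0.097
    #: retail margin m: wholesale = MRP / (1 + m).
    retail_margin: float = 0.20
    #: per-molecule uniform jitter (+/-) on the retail margin.
    margin_jitter: float = 0.0
    #: procurement discount d off wholesale: procurement = wholesale * (1 - d).
    procurement_discount: float = 0.82
    #: lognormal sigma of per-molecule MRP-per-DDD heterogeneity.
    price_sigma: float = 0.5
    #: lognormal sigma of packs-per-product-year (heavy-tailed volumes).
    volume_sigma: float = 1.0
    #: lognormal sigma of within-class molecule volume weights.
    weight_sigma: float = 1.0
    products_per_molecule: int = 3
    pack_size_choices: tuple[int, ...] = (1, 1, 1, 10)
    strength_fractions: tuple[float, ...] = (0.25, 0.5, 1.0)
    #: expected DDD-equivalent share of molecules missing from the registry.
    not_listed_fraction: float = 1e-4

    def validate(self) -> None:
        if not self.years:
            raise ConfigError("years must be non-empty")
        missing = [y for y in self.years if y not in self.population_thousands]
        if missing:
            raise ConfigError(f"population_thousands misses years {missing}")
        if any(v <= 0 for v in self.population_thousands.values()):
            raise ConfigError("populations must be strictly positive")
        if not self.total_ddds_per_year > 0:
            raise ConfigError("total_ddds_per_year must be positive")
        if not 0.0 <= self.oral_ddd_fraction <= 1.0:
            raise ConfigError("oral_ddd_fraction must lie in [0, 1]")
        for route, mix in self.aware_mix.items():
            if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
                raise ConfigError(f"invalid aware_mix for route {route!r}")
        for route, shares in self.public_share.items():
            if any(not 0.0 <= s <= 1.0 for s in shares.values()):
                raise ConfigError(f"public_share for {route!r} must lie in [0, 1]")
        if self.retail_margin < 0:
            raise ConfigError("retail_margin must be >= 0")
        if not 0.0 <= self.procurement_discount < 1.0:
            raise ConfigError("procurement_discount must lie in [0, 1)")
        if any(p <= 0 for p in self.price_per_ddd.values()):
            raise ConfigError("price_per_ddd values must be positive")
        if self.products_per_molecule < 1:
            raise ConfigError("products_per_molecule must be >= 1")
        if any(s < 1 for s in self.pack_size_choices) or not self.pack_size_choices:
            raise ConfigError("pack_size_choices must be positive integers")
        if any(f <= 0 for f in self.strength_fractions) or not self.strength_fractions:
            raise ConfigError("strength_fractions must be positive")
        if not 0.0 <= self.not_listed_fraction < 1.0:
            raise ConfigError("not_listed_fraction must lie in [0, 1)")
        for name in ("price_sigma", "volume_sigma", "weight_sigma",
                     "sector_split_jitter", "margin_jitter"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def study_profile(seed: int = 0) -> GeneratorConfig:
    """The bundled study-like profile (the config defaults)."""
    return GeneratorConfig(seed=seed)


def _q(x: float) -> float:
    """Quantize to 10 significant digits so CSV round-trips are exact."""
    return float("%.10g" % x)


def _mean_lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Lognormal draw with the given expectation."""
    if mean <= 0:
        return 0.0
    if sigma == 0:
        return mean
    return float(rng.lognormal(math.log(mean) - 0.5 * sigma**2, sigma))


@dataclass
class SyntheticDataset:
    sales: list[SalesRecord]
    procurement: list[ProcurementRecord]
    population: PopulationTable
    ground_truth: dict
    config: GeneratorConfig

    @property
    def n_records(self) -> int:
        return len(self.sales) + len(self.procurement)

    def all_records(self):
        return list(self.sales) + list(self.procurement)

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        from .ingest import write_procurement, write_sales

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sales": outdir / "sales.csv",
            "procurement": outdir / "procurement.csv",
            "population": outdir / "population.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_sales(self.sales, paths["sales"])
        write_procurement(self.procurement, paths["procurement"])
        self.population.write_csv(paths["population"])
        with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def generate(config: GeneratorConfig, registry: Optional[Registry] = None) -> SyntheticDataset:
    """Draw a full synthetic dataset under ``config``.

    Deterministic under ``config.seed``: a single seeded RNG drives every
    draw and records are emitted in a fixed catalogue order.
    """
    config.validate()
    if registry is None:
        from .datasets import load_bundled_registry

        registry = load_bundled_registry()

    rng = np.random.default_rng(config.seed)
    sales: list[SalesRecord] = []
    procurement: list[ProcurementRecord] = []
    product_serial = 0

    # Catalogue: registry entries grouped by (route, aware class), in a
    # fixed sorted order so the RNG stream is reproducible.
    by_route_class: dict[tuple[str, str], list] = defaultdict(list)
    for entry in sorted(registry, key=lambda e: (e.route.value, e.aware.value, e.molecule_name)):
        by_route_class[(entry.route.value, entry.aware.value)].append(entry)

    listed_fraction = 1.0 - config.not_listed_fraction

    for route in ("oral", "injectable"):
        route_frac = (
            config.oral_ddd_fraction if route == "oral" else 1.0 - config.oral_ddd_fraction
        )
        route_total = config.total_ddds_per_year * route_frac * listed_fraction
        if route_total <= 0:
            continue
        mix = config.aware_mix.get(route, {})
        mix_total = sum(mix.values())
        for aware_name in sorted(mix):
            entries = by_route_class.get((route, aware_name), [])
            if not entries:
                continue
            class_total = route_total * mix[aware_name] / mix_total
            weights = rng.lognormal(0.0, config.weight_sigma, size=len(entries))
            weights = weights / weights.sum()
            base_price = config.price_per_ddd[aware_name] * (
                config.oral_price_scale if route == "oral" else 1.0
            )
            pub_target = config.public_share.get(route, {}).get(aware_name, 0.0)
            for entry, w in zip(entries, weights):
                mol_total = class_total * float(w)
                price_per_ddd = _mean_lognormal(rng, base_price, config.price_sigma)
                margin = config.retail_margin
                if config.margin_jitter > 0:
                    margin = max(
                        0.0, margin + config.margin_jitter * float(rng.uniform(-1, 1))
                    )
                pub_frac = pub_target
                if config.sector_split_jitter > 0:
                    pub_frac = float(
                        np.clip(
                            pub_frac
                            + config.sector_split_jitter * float(rng.uniform(-1, 1)),
                            0.0,
                            1.0,
                        )
                    )
                for sector in ("private", "public"):
                    sector_frac = 1.0 - pub_frac if sector == "private" else pub_frac
                    mean_mol_sector = mol_total * sector_frac
                    if mean_mol_sector <= 0:
                        continue
                    for year in config.years:
                        for _ in range(config.products_per_molecule):
                            frac = float(rng.choice(config.strength_fractions))
                            pack_size = int(rng.choice(config.pack_size_choices))
                            # strength is a fraction of the DDD, in DDD units
                            strength = entry.ddd_value * frac
                            dpp = frac * pack_size  # DDDs per pack
                            mean_packs = (
                                mean_mol_sector / config.products_per_molecule / dpp
                            )
                            packs = _q(
                                _mean_lognormal(rng, mean_packs, config.volume_sigma)
                            )
                            mrp = _q(price_per_ddd * dpp)
                            wholesale = _q(mrp / (1.0 + margin))
                            proc_price = _q(
                                wholesale * (1.0 - config.procurement_discount)
                            )
                            if sector == "private":
                                product_serial += 1
                                sales.append(
                                    SalesRecord(
                                        product_id=f"P{product_serial:06d}",
                                        molecule_name=entry.molecule_name,
                                        route=Route(route),
                                        strength_value=_q(strength),
                                        strength_unit=entry.ddd_unit,
                                        pack_size=pack_size,
                                        packs_per_year=packs,
                                        mrp_per_pack=mrp,
                                        wholesale_per_pack=wholesale,
                                        year=year,
                                        region=config.region,
                                    )
                                )
                            else:
                                procurement.append(
                                    ProcurementRecord(
                                        molecule_name=entry.molecule_name,
                                        route=Route(route),
                                        strength_value=_q(strength),
                                        strength_unit=entry.ddd_unit,
                                        pack_size=pack_size,
                                        packs_per_year=packs,
                                        procurement_cost_per_pack=proc_price,
                                        year=year,
                                        region=config.region,
                                    )
                                )

    # Molecules missing from the registry (the coverage-report path).
    if config.not_listed_fraction > 0:
        nl_total = config.total_ddds_per_year * config.not_listed_fraction
        for year in config.years:
            product_serial += 1
            packs = _q(_mean_lognormal(rng, nl_total / 0.5, config.volume_sigma))
            sales.append(
                SalesRecord(
                    product_id=f"P{product_serial:06d}",
                    molecule_name="unlisted agent",
                    route=Route.INJECTABLE,
                    strength_value=500.0,
                    strength_unit=Unit.MG,
                    pack_size=1,
                    packs_per_year=packs,
                    mrp_per_pack=_q(_mean_lognormal(rng, 200.0, config.price_sigma)),
                    wholesale_per_pack=None,
                    year=year,
                    region=config.region,
                )
            )

    population = PopulationTable.from_mapping(
        {(config.region, y): config.population_thousands[y] for y in config.years}
    )
    ground_truth = _ground_truth(sales, procurement, registry, config)
    return SyntheticDataset(sales, procurement, population, ground_truth, config)


def _ground_truth(sales, procurement, registry: Registry, config: GeneratorConfig) -> dict:
    """Independent per-record oracle: plain arithmetic, compensated sums.

    Costs are primary-basis (MRP for private, procurement for public);
    wholesale-basis totals are carried alongside for the sensitivity
    comparison.
    """
    acc: dict[str, list[float]] = defaultdict(list)
    excluded_packs: list[float] = []
    excluded_molecules: set[str] = set()
    n_excluded = 0

    for rec in list(sales) + list(procurement):
        entry = registry.lookup(rec.molecule_name, rec.route)
        if entry is None:
            n_excluded += 1
            excluded_packs.append(rec.packs_per_year)
            excluded_molecules.add(rec.molecule_name)
            continue
        s_val, s_unit = rec.strength_value, rec.strength_unit.value
        d_val, d_unit = entry.ddd_value, entry.ddd_unit.value
        if s_unit == "g":
            s_val, s_unit = s_val * 1000.0, "mg"
        if d_unit == "g":
            d_val, d_unit = d_val * 1000.0, "mg"
        if s_unit != d_unit:  # pragma: no cover - generator never mixes units
            n_excluded += 1
            excluded_packs.append(rec.packs_per_year)
            excluded_molecules.add(rec.molecule_name)
            continue
        ddds = s_val * rec.pack_size / d_val * rec.packs_per_year
        if rec.sector == "private":
            cost = rec.mrp_per_pack * rec.packs_per_year
            cost_w = (
                rec.wholesale_per_pack if rec.wholesale_per_pack is not None
                else rec.mrp_per_pack / (1.0 + config.retail_margin)
            ) * rec.packs_per_year
        else:
            cost = cost_w = rec.procurement_cost_per_pack * rec.packs_per_year
        sr = f"{rec.sector}|{rec.route.value}"
        acc[f"ddds|{sr}"].append(ddds)
        acc[f"cost|{sr}"].append(cost)
        acc[f"cost_wholesale|{sr}"].append(cost_w)
        acc[f"ddds_aware|{entry.aware.value}"].append(ddds)
        acc[f"cost_aware|{entry.aware.value}"].append(cost)
        acc[f"ddds_year|{rec.year}"].append(ddds)
        acc[f"cost_year|{rec.year}"].append(cost)

    by_sector_route: dict[str, dict[str, float]] = {}
    for key, vals in acc.items():
        metric, rest = key.split("|", 1)
        if metric in ("ddds", "cost", "cost_wholesale"):
            by_sector_route.setdefault(rest, {})[metric] = math.fsum(vals)
    by_aware = {
        cls.value: {
            "ddds": math.fsum(acc.get(f"ddds_aware|{cls.value}", [])),
            "cost": math.fsum(acc.get(f"cost_aware|{cls.value}", [])),
        }
        for cls in AwareClass
        if f"ddds_aware|{cls.value}" in acc
    }
    by_year = {}
    did_values = []
    for year in config.years:
        ddds_y = math.fsum(acc.get(f"ddds_year|{year}", []))
        pop = config.population_thousands[year]
        did_y = ddds_y / (pop * DAYS_PER_YEAR)
        did_values.append(did_y)
        by_year[str(year)] = {
            "ddds": ddds_y,
            "cost": math.fsum(acc.get(f"cost_year|{year}", [])),
            "did": did_y,
        }
    total_ddds = math.fsum(v["ddds"] for v in by_sector_route.values())
    total_cost = math.fsum(v["cost"] for v in by_sector_route.values())
    return {
        "config": {
            "seed": config.seed,
            "years": list(config.years),
            "region": config.region,
            "retail_margin": config.retail_margin,
            "procurement_discount": config.procurement_discount,
        },
        "n_records": len(sales) + len(procurement),
        "n_excluded": n_excluded,
        "excluded_molecules": sorted(excluded_molecules),
        "excluded_packs": math.fsum(excluded_packs),
        "by_sector_route": by_sector_route,
        "by_aware": by_aware,
        "by_year": by_year,
        "overall": {
            "ddds": total_ddds,
            "cost": total_cost,
            "did_avg": math.fsum(did_values) / len(did_values),
        },
    }
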