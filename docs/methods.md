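# Methods

## The measurement model

The package implements standard ATC/DDD drug-utilization accounting.
One input record is a product–pack–year observation: molecule, route,
strength per unit, units per pack, packs moved per year (a moving annual
total, taken as given — no within-year seasonality is modelled), prices,
year, region and sector. Conversion to DDDs is exact arithmetic, not
estimation:

```
ddd_per_pack = strength × pack_size / DDD(molecule, route)
total_ddds   = ddd_per_pack × packs_per_year
DID          = total_ddds / (population_thousands × 365)
```

Assumptions baked into this model:

* **One DDD per (molecule, route).** The registry is the single source
  of truth; a lookup never substitutes the other route's DDD. Fixed-dose
  combinations are their own molecules (components joined with `+` after
  name normalization). Where the WHO index assigns no combination DDD,
  the registry row carries the principal antibacterial component's DDD
  and is flagged `ddd_source=principal_component` — a documented
  approximation, visible in the data rather than buried in code.
* **Units.** Strengths and DDDs are reduced to mg; g→mg is the only
  conversion performed. Unit-dosed molecules (benzylpenicillin,
  colistin) are kept in MU, and mixing MU with mass units is a hard
  error — silent unit corruption is the classic failure mode of DDD
  pipelines.
* **365-day years**, leap years ignored, matching the standard DID
  definition.
* **Multi-year figures are averages of per-year results**, not pooled
  totals: DID and report tables are computed per year and averaged over
  the window.
* **Coverage is explicit.** Records whose molecule has no registry DDD
  are excluded from totals but accumulated into a coverage report
  (molecule, route, reason, packs, spend). Exclusion is visible, never
  silent.

## Price bases and cost metrics

Private records are costed at MRP by default or at the wholesale price
for sensitivity analysis; public records always at the procurement
price. When a record has no observed wholesale price it is derived as
`MRP/(1+m)`; the margin `m` is configuration (a scalar, default 0.20, or
a per-ATC3 table), because real retail margins are not public. With any
uniform `m ≥ 0`, wholesale-basis totals are bounded above by MRP-basis
totals stratum by stratum, and shares *within* the private sector are
unchanged while the public–private split shifts toward the public
sector — the sensitivity comparison (`sensitivity_compare`) reports the
share under each basis and their gap in percentage points.

`cost_per_ddd` is the plain quotient and is reported as NaN (undefined)
for strata with zero DDDs rather than infinity; `per_capita_cost`
divides by persons (population is carried in thousands throughout).
Currency is plain INR; no deflation, exchange or purchasing-power
adjustment is applied.

Procurement prices are treated as directly comparable to wholesale
prices, although they may embed different distribution overheads; this
mirrors how public tender prices are usually compared against private
market prices and is a known limitation.

## Aggregation and display conventions

Share tables compute DDD and cost shares on **unrounded** values;
rounding (one decimal for shares and cost per DDD, three for DID) is
applied only when a table is written. This matters because published
consumption tables routinely show half-unit rounding inconsistencies
when shares are recomputed from their own rounded entries; recomputing
shares from stored unrounded totals never changes a comparison here.
Top-n tables fold the tail into an "All the other …" remainder row
defined as grand total minus top-n sums, so conservation is exact.
Ties in top-n are broken by descending metric, then alphabetically.
ATC level-5 totals roll up exactly to level 4, and level 4 to level 3,
because the grouping keys are prefixes of one code.

## The reference registry fixture

The bundled registry covers ~30 injectable and ~16 oral antibacterial
(J01) molecules: DDD values transcribed from the WHO ATC/DDD index
(2022 vintage, i.e. including the 2019 revisions such as ampicillin
parenteral 6 g and meropenem 3 g), AWaRe classes from the WHO 2021
list. Class membership is data, not code, so a different list vintage
is a different TSV, not a code change. Combination products without an
official ATC code are filed under synthetic `J01RA9x` codes inside the
combinations group. Veterinary ATC codes and non-J01 antibacterials are
out of scope. Each record is assumed to carry one active strength;
diluent-plus-powder presentations must be resolved upstream.

## What the synthetic generator emulates

The generator draws four annual cross-sections (2016–2019) of a
two-sector market over the bundled molecule catalogue:

* **Volume.** Expected total DDDs per year (default 285.7 million, oral
  fraction 0.972, Kerala-scale population ≈ 35.0 million so the implied
  DID is ≈ 22) are split across AWaRe classes by configured mix weights
  (injectable mix 26.5/50.9/0.6/22.0 % Access/Watch/Reserve/Discouraged),
  across molecules within a class by normalized lognormal weights
  (σ = 1.0, heavy-tailed so top-n tables are non-degenerate), across
  sectors by per-class public shares (34/33.3/25.8/20.8 % for
  injectables, 39.8 % for orals), and across products/years evenly.
  Realized packs per product-year are mean-preserving lognormal draws
  (σ = 1.0), so every configured share is matched in expectation and a
  10 000-record draw lands within ~3 percentage points.
* **Prices.** Each molecule gets a mean-preserving lognormal MRP per
  DDD around its class level (injectable 167.5/296.2/2798.8/345.0 INR
  for Access/Watch/Reserve/Discouraged; oral prices scaled by 0.097 so
  the oral cost per DDD is about a tenth of the injectable one);
  wholesale = MRP/(1+0.20); procurement = wholesale × (1 − 0.82). The
  0.82 discount is chosen so that a ~31 % public volume share yields a
  ~6 % public cost share, the efficiency asymmetry characteristic of
  bulk tender procurement.
* **Coverage noise.** A configurable fraction (default 10⁻⁴ of DDDs) of
  volume is assigned to a molecule absent from the registry, exercising
  the coverage-report path.
* **Ground truth.** At generation time an independent per-record loop
  (plain Python, compensated sums, no pandas and no calls into the DDD
  engine) computes totals by sector × route, AWaRe class and year, plus
  per-year DID. All emitted floats are quantized to 10 significant
  digits and CSVs are written at that precision, so the file round trip
  is exact and pipeline-vs-oracle agreement is at machine precision.
  One seeded `numpy` generator drives every draw; no global RNG state
  is touched, and runs are byte-identical under a fixed seed.

What the generator does **not** emulate: brand/product-name noise and
molecule-name dirt (records arrive pre-annotated), within-year dynamics,
demand elasticity, regional heterogeneity beyond a single region label,
and correlated price–volume shocks. Passing tests on synthetic data
therefore demonstrate the accounting is correct and conservative, not
that any epidemiological signal would be recovered from messy real
exports. In the study-like profile the per-molecule sector split equals
its class-level share (jitter 0), making the configured shares the
recoverable estimands for the parameter-recovery checks; molecule-level
split heterogeneity can be switched on via `sector_split_jitter`.

## Numerical and design choices

* Name normalization: lower-case, collapsed whitespace, combination
  separators (`+`, `/`, spaced hyphen/en-dash) folded to `+`; idempotent
  by construction. Tight hyphens inside a single name are preserved.
* Aggregation tolerance: conservation and oracle-equality checks use
  relative 1e-9; the per-record arithmetic itself is exact floating
  point.
* Degenerate inputs: empty selections produce empty tables with zero
  totals; zero-DDD strata produce NaN cost per DDD; `top_n` with n ≥
  rows returns the table unchanged with an empty remainder.
* Problem sizes: the default test draw uses ~1 100 records, the
  property checks ~10 000, and parameter recovery ~50 000 — sizes at
  which lognormal share noise is comfortably below the 3-SE bands while
  the whole suite stays light.
* The CLI is a thin wrapper; all behavior lives in the library so the
  pipeline is equally usable from notebooks.

## Known limitations

* DDD-based volumes understate pediatric and renal-adjusted dosing
  differences by construction (a property of the DDD methodology, not
  of this implementation).
* The wholesale margin and procurement discount are assumptions, not
  estimates; sensitivity results should be read as functions of those
  knobs.
* The registry fixture is a curated subset, not the full WHO index;
  analyses of real data should supply a complete registry TSV.
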