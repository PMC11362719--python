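# abxddd

Antibiotic drug-utilization analytics: convert pack-level sales and
procurement records into WHO defined daily doses (DDDs), normalize to
population rates, and compare public- and private-sector volumes and
costs across stewardship and pharmacological strata.

## The problem

Antimicrobial consumption surveillance asks a deceptively simple
question — *how much antibiotic does a population use, and what does it
cost, and through which channel?* — but the raw inputs are heterogeneous
pack-level records: a product is "ceftriaxone 1 g vial, pack of 1,
120 000 packs/year, MRP ₹58" in one row and "amoxicillin–clavulanate
625 mg tablet, strip of 10" in the next. The WHO ATC/DDD methodology
makes them commensurable: each molecule–route pair has a **defined daily
dose** (DDD), the assumed average adult maintenance dose per day, so

```
total DDDs = strength × pack size × packs consumed per year / DDD
```

and, normalizing by mid-year population `P` (in thousands),

```
DID = total DDDs / (P × 365)        # DDD per 1000 population per day
```

Costs are layered on top under a selectable **price basis**: MRP (the
ceiling retail price paid out of pocket in the Indian private market),
wholesale price (MRP net of the retail margin `m`, i.e. `MRP/(1+m)`,
used as a sensitivity analysis), or public procurement price. Derived
metrics are total cost, cost per DDD and per-capita cost, stratified by
route (oral/injectable), sector (public/private), WHO AWaRe class
(Access / Watch / Reserve, plus the "not recommended" fixed-dose
combinations, carried as *Discouraged*) and ATC level 3/4/5.

The intended users are pharmacoepidemiologists and health-policy
analysts working with commercial sales panels (e.g. market audit data)
and state procurement ledgers. Those datasets are proprietary, so the
package ships (a) a synthetic-data generator that emulates their
structure with exact ground truth, and (b) small fixtures transcribed
from published national/Kerala consumption tables used as test oracles
and demo inputs.

## Worked example

```python
from abxddd import (study_profile, generate, annotate, add_costs, MRP,
                    share_table, sector_share, did_by_year, multi_year_average)
from abxddd.datasets import load_bundled_registry

registry = load_bundled_registry()                       # molecule → DDD/ATC/AWaRe
dataset = generate(study_profile(seed=1), registry) # 4 years, 2 sectors
frame, coverage = annotate(dataset.all_records(), registry)
frame = add_costs(frame, MRP)

inj = frame[frame["route"] == "injectable"]
print(share_table(inj, "aware").round(1).to_string(index=False))
```

```
      aware  total_ddds  ddd_share_pct   total_cost  cost_share_pct  cost_per_ddd
      Watch  16753594.6           50.8 2380528830.6            30.2         142.1
     Access   8160511.2           24.7 1015249444.8            12.9         124.4
Discouraged   7928073.6           24.0 4305608771.4            54.6         543.1
    Reserve    166229.2            0.5  181434052.9             2.3        1091.5
      Total  33008408.6          100.0 7882821099.7           100.0         238.8
```

Half of injectable volume is Watch-group; Reserve molecules are a
rounding error of volume but carry the highest cost per DDD — the
fingerprint the generator is calibrated to. Population rates and sector
splits follow the same pattern:

```python
yearly = did_by_year(frame, dataset.population, "KL")
print("average DID:", round(multi_year_average({y: v.did for y, v in yearly.items()}), 1))
print(sector_share(inj, "route").round(1)[["route", "public_ddd_pct", "public_cost_pct"]]
      .to_string(index=False))
```

```
average DID: 19.0
     route  public_ddd_pct  public_cost_pct
injectable            37.1              6.5
     Total            37.1              6.5
```

The public sector here provides over a third of injectable DDDs for a
~6% share of the cost, because procurement prices sit far below MRP —
the efficiency asymmetry the cost engine's sensitivity analysis
(`sensitivity_compare`, MRP vs wholesale basis) is designed to probe.
(This run is a small draw, ~1100 records; shares fluctuate a few
percentage points around the configured profile.)

The same pipeline is scriptable from the shell:

```bash
abxddd generate --seed 1 --out data/
abxddd compute --sales data/sales.csv --procurement data/procurement.csv \
               --population data/population.csv --basis mrp --out store/
abxddd report --metrics store/ --tables all --out reports/
```

## Layout

| module | role |
| --- | --- |
| `abxddd.registry` | ATC/DDD/AWaRe reference registry, name normalization |
| `abxddd.ingest` | sales/procurement/population CSV readers, reject reports |
| `abxddd.ddd` | DDD formula, DID, multi-year averaging, coverage report |
| `abxddd.cost` | price bases, cost per DDD, per-capita cost, sensitivity |
| `abxddd.aggregate` | share tables, sector shares, top-n, formulation counts |
| `abxddd.synthetic` | study-profile data generator with exact ground truth |
| `abxddd.reports`, `abxddd.cli` | report builders and the `abxddd` CLI |

See `docs/methods.md` for the methodological fine print (assumptions,
defaults, numerical conventions, limitations).
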