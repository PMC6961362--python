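# amucost

Antimicrobial-use costing for small-scale meat-chicken flocks.

The package standardizes retail antimicrobial prices to the **animal daily
dose for a 1 kg bird** (ADD_kg: the label's therapeutic dilution factor times
the daily intake of a 1 kg chicken — 225 ml water or 63 g feed — costed at
the package unit price and expressed in cents of 1 US$ at 23,319 VND/US$),
classifies products by the WHO human-medicine criticality of their active
ingredients (AAIs), aggregates weekly flock-diary usage/expense stratified by
disease and mortality, and fits farm-random-intercept linear models of price
determinants with forward-stepwise covariate selection. A calibrated
synthetic diary generator makes every stage testable fully offline.

## Modules

| module | role |
| --- | --- |
| `amucost.catalog` | product/AAI data model, WHO dictionary, category-combination classification and tabulation |
| `amucost.dosing` | ADD_kg engine: dilution factor → dose amount → ₵ per ADD_kg → per-AAI attribution |
| `amucost.diaries` | flock-week model: AMU probability by age, expense per flock/bird/kg, Kruskal-Wallis strata comparisons, use-frequency vs price correlation |
| `amucost.models` | exact profile-REML random-intercept models, stepwise selection, farm-adjusted mean, outlier refits |
| `amucost.synthetic` | seeded generator of catalogues, price records and flock diaries with the calibrated statistical structure |
| `amucost.cli` | `amucost` command-line orchestration |

Package data: `data/aai_dictionary.csv` (37 AAIs in 13 classes with WHO
categories and spelling aliases) and `data/reference_catalog.csv` (the
214-product reference catalogue, stored compactly as composition × count).

## CLI

```bash
amucost simulate --config sim.yaml --seed 17 --out data/
amucost price --products data/products.csv --prices data/prices.csv --fx 23319 --out addkg.csv
amucost classify --products data/products.csv --addkg addkg.csv --out category_table.csv
amucost aggregate --diaries data/flock_weeks.csv --growth data/growth.yaml --out summaries/
amucost model --addkg addkg.csv --products data/products.csv \
    --diaries data/flock_weeks.csv --farms data/farms.csv --out models/
amucost report --config sim.yaml --seed 17 --out report/   # full pipeline
```

Exit codes: 0 success, 1 input error, 2 stage failure. `sim.yaml` holds
overrides for any `GeneratorConfig` field (all defaults are the calibrated
study-scale values: 102 farms, 203 flocks, 214 products, 775 price records,
week-1 AMU probability 0.76, week-1 disease probability 0.56, mean weekly
mortality 2.8/100 with a mid-cycle peak).

## Library example

```python
import amucost as a

cfg = a.GeneratorConfig()
bundle = a.simulate(cfg, seed=1)
weeks = a.flock_weeks_from_frame(bundle["flock_weeks"], fx=cfg.fx)

a.weekly_amu_probability(weeks)          # p_amu by week of age, with SE
a.expense_series(weeks)                  # ₵ per flock / bird / kg by age
a.stratify_expense(weeks, by="disease")  # group means + Kruskal-Wallis
```
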