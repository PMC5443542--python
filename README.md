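# oceanhealth

A composite ocean-health index toolkit.  Ten ocean-benefit goals are each
assessed on four dimensions — current status, recent trend, pressures and
resilience — projected to a likely future status, scored as the mean of
status and future, and aggregated to a single 0–100 index under an arbitrary
nonnegative goal-weight vector.  The package also implements three
customized goal calculators, four survey-derived goal-weighting schemes, a
Monte-Carlo group comparison, and synthetic-data generators so every stage
is testable offline.

## Modules

| module | contents |
| --- | --- |
| `oceanhealth.core` | scoring engine: pressure/resilience blending, future-status projection, goal scores, subgoal and index aggregation, trend and wellbeing:GDP helpers |
| `oceanhealth.carbon` | seafloor carbon 'habitats': depth/latitude masks on lat/lon grids, cell areas, anomaly-anchored habitat health, CO₂-slope trend, area-weighted combination |
| `oceanhealth.iconic` | iconic-species subgoal: COSEWIC risk weights, range-weighted risk scoring |
| `oceanhealth.needs` | community resource-access goal: food-basket price imputation (group-specific OLS), ice cover within a 300 km radius, price-ratio × ice factors vs a 1979 baseline, population-weighted index |
| `oceanhealth.weighting` | Equal / Likert / best-worst-rank / best-worst conditional-logit (maxdiff) weights, shift-then-scale normalization, bootstrap group comparison with compact letters |
| `oceanhealth.synthetic` | seeded generators for survey responses, community panels and bathymetry/ice grids with known ground truth |
| `oceanhealth.fixtures` | packaged reference tables (species roster, risk weights, price-model coefficients, the 2013 per-goal worked example) |
| `oceanhealth.io` / `oceanhealth.cli` | CSV schemas with line-numbered validation, pipeline composition, text "flower" report, CLI |

## CLI

The console script `oceanhealth` (equivalently `python -m oceanhealth.cli`)
exposes seven subcommands:

```bash
# score the packaged 2013 assessment with equal weights
oceanhealth score --out results/

# generate a synthetic survey, derive all four weighting schemes
oceanhealth simulate --kind survey --seed 7 --out sim/
oceanhealth weights --likert sim/likert.csv --tasks sim/tasks.csv --out weights.csv

# score under survey-derived weights
oceanhealth score --scheme bw-dce --tasks sim/tasks.csv --out results-dce/

# goal calculators
oceanhealth an --communities sim/communities.csv --panel sim/panel.csv
oceanhealth carbon --bathymetry grids/bathymetry.csv --co2 co2.csv --anomaly 2.15
oceanhealth iconic

# bootstrap group comparison (compact letter display)
oceanhealth compare --tasks sim/tasks.csv --demographics sim/demographics.csv \
    --by region --n-sims 500 --seed 1
```

Exit codes: 0 ok, 1 validation/usage error, 2 runtime error.  A flat
`key = value` config file (`--config run.cfg`) can supply defaults for any
option; explicitly passed flags win.  All engine defaults (β = 0.67,
γ = 0.5, δ = 0, base year 1979, 300 km radius, anomaly anchors
0.65 °C → 1 / 3.65 °C → 0) can be overridden.

## File formats

All inputs and outputs are plain CSV.  Layer files are tidy
(`goal_id, subgoal_id, dimension, year, value`); pressure and resilience may
be given combined or as ecological/regulation/social components, which the
engine blends with γ.  Grids are long-format rasters (`lat, lon, value`).
Survey tables are `likert.csv`, `tasks.csv` (shown set pipe-separated) and
`demographics.csv`.
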