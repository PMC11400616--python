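# copollute

A tested, reusable pipeline for assessing PM2.5–O3 compound pollution across a
multi-city daily monitoring panel: quality control and validity-quota
aggregation, dominant-pollution typing, Mann-Kendall trend analysis with
tie-corrected variance, a six-type exposure-risk typology, bivariate spatial
association (global/local Moran's I with permutation pseudo-significance and a
geographically weighted local correlation), and a four-quadrant synergy
classification of endpoint-year change. A synthetic-data module generates
multi-city panels with known planted structure (seasonality, trends,
missingness, gross outliers, spatially clustered city groups) so every stage
is testable offline.

## Layout

| module | purpose |
|---|---|
| `copollute.synthetic_data` | multi-city daily panels, metadata, emissions, truth ledger |
| `copollute.ingest_qc` | QC flagging (>999 µg/m³, negatives, duplicates), MDA8 ozone, monthly/seasonal/annual/study-period aggregation with validity quotas (≥27 d/month, ≥360 d/year) |
| `copollute.pollution_typing` | P-O / PM2.5-dominated / O3-dominated / Clean typing at 35 and 100 µg/m³, shares, year-to-year transitions |
| `copollute.trend` | Mann-Kendall S, tie-corrected Var(S), continuity-corrected Z, significance tiers at 1.645/1.960/2.576 |
| `copollute.exposure_risk` | three concentration bands × trend direction → HR/ST/R/DST/S/HS, combined "PM + O3" pairs, population totals |
| `copollute.spatial_assoc` | kNN great-circle weights, bivariate local/global Moran's I with conditional permutation, GW local correlation, correlation-vs-PM2.5 quadratic fit |
| `copollute.synergy` | relative rate of change (end/start year) and the four synergy quadrants |
| `copollute.pipeline` / `copollute.cli` | orchestration, YAML config, report.json |

## CLI

```bash
copollute simulate --outdir output/data --n-cities 120 --seed 7
copollute run --outdir output --seed 7            # synthetic mode
copollute run --config my_config.yaml             # CSV inputs
copollute report output                           # headline numbers
```

`run` writes per-stage CSV/JSON outputs (`aggregates.csv`, `pollution_types.csv`,
`mk_results.csv`, `risk_labels.csv`, `bimoran.csv`, `local_corr.csv`,
`synergy.csv`, …) plus a consolidated `report.json` and a `qc_report.txt` with
full row accounting. Two runs with the same config and seed produce
byte-identical reports.

Input series are long-format CSV `city_id,date,pollutant,value` (pollutant
`PM25` or `O3`, values in µg/m³) plus a city metadata CSV with coordinates and
population.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed critical
values, brute-force oracle equivalence for S/Var(S) and Moran's I, analytic
limit cases, type-I/permutation calibration, exact label recovery on
noise-free synthetic cities, QC quota rules, and end-to-end determinism.

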