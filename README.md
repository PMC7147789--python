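# ncsim

Monte Carlo simulation of greenhouse-gas reductions from **natural climate
solutions (NCS)** — changes in land management, ecosystem restoration, and
avoided conversion of native habitats — evaluated against state-level
emission-reduction targets. The package ships a fully parameterized bundle
for Oregon, USA (twelve activities, three implementation scenarios,
2020–2050) and a synthetic-bundle generator with closed-form expected
totals for verifying the engine.

It is written for land-sector carbon analysts and climate-policy modelers
who want a transparent, reproducible implementation of NCS scenario
accounting that they can re-parameterize for other regions.

## The model

Each NCS activity converts a scenario-driven implementation level into an
annual GHG reduction (Mg CO₂e yr⁻¹) relative to the current baseline rate:

- **Avoided conversion** (forests→rural/urban development, sagebrush-steppe
  →invasive annual grasses, grassland→cropland). Each avoided hectare
  yields a one-time committed emission avoided — for forests
  `(AGB·0.54 + BGB + L + WD) · 44/12` to urban, half that to rural — plus an
  ongoing foregone-sequestration credit that accumulates over cohorts of
  avoided area.
- **Land management.** Deferred timber harvest credits the committed
  emissions of the deferred volume (unused mill residue, products retired
  within 20 years, decaying logging residue and roots:
  `(0.15 + 0.28 + 0.56·(0.25 + 0.2·1.25)) · SG · 0.5 · 44/12` per m³) plus
  an amortized sequestration gain ΔC_seq/30 on cumulative deferred
  clearcut area; deferment is constrained to ≤25% of private-industrial
  baseline volume and ≥40% of overall baseline harvest. Cover crops and
  no-till credit enrolled area × a soil-carbon rate; nutrient management
  credits avoided N₂O as `ΔN · EF · 44/28 · 298`.
- **Restoration** (post-fire replanting, riparian reforestation, tidal
  wetlands, sagebrush-steppe). Annual enrollment accumulates cohorts whose
  per-hectare rates persist through 2050, clamped at the available
  restoration opportunity (e.g. 5205 ha of high-salinity tidal wetland).
  Replanting credit is the planted growth curve minus natural regeneration,
  which is delayed ten years after fire.

Uncertainty in every per-unit rate is propagated by Monte Carlo sampling
(1000 iterations by convention); results are reported as the median with an
empirical 90% confidence interval, with cumulative series accumulated
within each iteration before summarizing.

## Worked example

```python
from ncsim import load_oregon_bundle, run, report_frame

bundle = load_oregon_bundle()
result = run(bundle, "moderate", n_iter=1000, seed=42)

print(round(result.median_annual_total(2035) / 1e6, 2))   # MMT CO2e/yr
print(report_frame(result, bundle.targets).round(2).to_string(index=False))
```

prints

```
4.27
scenario  year  ncs_median  ncs_ci_lo  ncs_ci_hi  needed  fraction_of_needed
moderate  2035        4.27       4.13       4.43    30.1               14.20
moderate  2050        5.56       5.27       5.86    50.0               11.13
```

Under the Moderate scenario the simulated NCS portfolio reduces emissions
by a median 4.27 MMT CO₂e yr⁻¹ in 2035 — about 14% of the 30.1 MMT gap
between Oregon's 2017 emissions (64 MMT) and its statutory 2035 target
(33.9 MMT) — and accumulates a median 116 MMT CO₂e (90% CI 112–121) by
2050, roughly 70% of it from deferred timber harvest
(`ncsim.activity_shares(result)`).

The same runs are available from the shell:

```sh
ncsim run --scenario moderate --iters 1000 --seed 42 --out out/
ncsim report --scenario ambitious --iters 1000 --seed 1 --out report.csv
ncsim validate-bundle src/ncsim/data/oregon.yaml
```

`run` writes `annual.csv`, `cumulative.csv`, `by_activity.csv` (tidy long
format) and a `run_manifest.json` recording the seed, bundle hash, and
package version.

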