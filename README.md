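# drystocks

Global **dryland soil element-stock accounting**: aridity-index zonation,
gravel-corrected layered stocks of organic C, inorganic C, N and P with
first-order uncertainty propagation, and equal-area zonal aggregation to a
stratum × element × depth inventory table.

Drylands — land with an aridity index (AI, the ratio of mean annual
precipitation to potential evapotranspiration) below 0.65 — cover roughly
45% of the Earth's land surface, and their soils hold globally significant
C, N and P pools. Quantifying those pools from harmonized soil databases
such as WISE30sec involves a chain of standard but error-prone steps:
classify an AI raster into hyperarid (AI < 0.03), arid (0.03 ≤ AI < 0.20),
semiarid (0.20 ≤ AI < 0.50), dry subhumid (0.50 ≤ AI < 0.65) and humid
(AI ≥ 0.65) strata; convert per-layer concentration, bulk density and
coarse-fragment data to areal stocks; propagate the database's standard
deviations; and aggregate cell stocks over equal-area cell geometry to Pg
totals. `drystocks` packages that chain for raster inputs at any
resolution, together with a synthetic world generator with analytic truth
so every stage is testable without multi-GB downloads.

## The core computation

The fine-earth areal stock of one soil layer is

```
STOCK = HOT · CN · BULK · (1 − CFRAG/100)        [kg m⁻²]
```

with layer thickness `HOT` (m), element concentration `CN` (g kg⁻¹), bulk
density `BULK` (g cm⁻³) and gravel volume `CFRAG` (%). Its standard
deviation follows by first-order (Taylor) propagation of independent input
errors:

```
STOCK_std = HOT · √( CN_std²·BULK²·(1−CFRAG/100)²
                   + CN²·BULK_std²·(1−CFRAG/100)²
                   + CN²·BULK²·(CFRAG_std/100)² )
```

Layers aggregate pro-rata to depth targets (0.3, 1, 2 m by default), map
units composite their soil components by area fraction, and a stratum's
total is Σ cells stock · area in Pg with

```
std(stratum) = √( Σ (area · STOCK_std)² )
```

under the assumption that estimation errors are spatially uncorrelated.
Cell areas are exact spherical band areas `R²·Δλ·(sin φ₂ − sin φ₁)` on an
authalic sphere (R = 6371.0072 km), which is what an equal-area projection
preserves.

## Worked example

```sh
drystocks all --seed 1 --outdir out --log-level WARNING
```

runs the full chain on the default synthetic world (2° global grid) and
writes `zonal_summary.csv`, `p_summary.csv`, `ratios.json`,
`pool_comparisons.json`, `stratum_areas.csv`, `worked_examples.csv` and a
hash manifest. The organic-C rows of `zonal_summary.csv` at 2 m for that
seed are:

| stratum      | stock (Pg) | std (Pg) | mean content (kg m⁻²) |
|--------------|-----------:|---------:|----------------------:|
| hyperarid    |      38.2 |     0.39 |                  4.2 |
| arid         |     171.6 |     1.12 |                  7.6 |
| semiarid     |     351.7 |     2.11 |                 14.1 |
| dry_subhumid |     190.8 |     1.76 |                 18.3 |
| dry          |     752.4 |     2.99 |                 11.2 |
| humid        |    2146.3 |     6.95 |                 25.4 |
| global       |    2898.7 |     7.57 |                 19.2 |

Mean content rises monotonically from hyperarid (4.2 kg m⁻²) to humid
soils, the four subtype stocks sum to the dry total, and dry + humid is
the global total. `ratios.json` holds the stratum C:N:P mass ratios at
0.5 m (normalized to P = 1), e.g. `15:1.7:1` for dry and `51:4.5:1` for
humid land for this seed — the dryland-ward decline of C:N, C:P and N:P
that aridity imposes. The aggregate stds are small because spatially
uncorrelated errors largely cancel in large-area sums; see
`docs/methods.md`.

```sh
drystocks verify
```

recomputes the published inventory's internal arithmetic (stratum sums,
pool shares, reference-pool comparisons) from its printed constants and
reports pass/fail per claim.

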