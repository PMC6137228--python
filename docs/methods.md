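# Methods

## Scope and data model

`drystocks` computes per-stratum soil element stocks (Pg) with first-order
uncertainty from three kinds of gridded inputs on a shared regular lat/lon
grid: an aridity-index (AI) raster, layered soil property cubes (per-layer
concentration, bulk density and coarse-fragment volume, each with a
per-cell standard-deviation field, seven layers to 2 m by default), and
optional direct areal-content maps (the six P forms to 0.5 m). All layers
live on a `GeoGrid` — rows north→south, cell-centre samples, one numeric
nodata sentinel per raster, and nodata absorbing in arithmetic. Two grids
are aligned iff all five geometry fields are equal; every multi-raster
operation validates alignment before computing.

## Cell geometry

Stratum areas and stock totals need equal-area cell weights. Rather than
projecting, cell areas are evaluated in closed form on an authalic sphere:
a cell bounded by latitudes (φ₁, φ₂) spanning Δλ radians has area
R²·Δλ·(sin φ₂ − sin φ₁), constant along a row. The default radius is the
WGS84 authalic value R = 6371.0072 km (configurable); the underlying
radius of published Mkm² figures is not documented anywhere we know of,
so this is a package choice, not a reproduction. The closed form is exact,
row-monotone toward the poles, and a full global grid telescopes to
4πR² to machine precision — all asserted in tests at 0.5°–2°.

## Zonation

AI classes follow the standard dryland scheme with half-open intervals
exactly as conventionally printed: hyperarid [0, 0.03), arid [0.03, 0.20),
semiarid [0.20, 0.50), dry subhumid [0.50, 0.65), humid [0.65, ∞); "dry"
is the union of the first four. AI = 0.03 is therefore arid and AI = 0.65
humid. No upper AI cap is applied. Thresholds are data (an
`AridityScheme`), so older atlas boundaries can be swapped in for
sensitivity studies. Land cells whose AI is nodata join no stratum and are
reported as unclassified area rather than silently shrinking the globe.
Hyperarid's lower bound is taken as 0 (AI is non-negative by definition;
negative values are rejected with a cell count).

## Stocks and uncertainty

One layer's fine-earth areal stock is `HOT·CN·BULK·(1−CFRAG/100)` in
kg m⁻²; the unit identity (g kg⁻¹)(g cm⁻³)(m) = kg m⁻² needs no extra
factor. The standard deviation is the first-order (delta-method)
propagation of independent errors on CN, BULK and CFRAG (see README for
the formula). A Monte-Carlo oracle — written before the engine and kept in
the test suite — checks the propagation against the empirical std of 10⁵
independent truncated-normal draws; with all three relative stds ≤ 0.2 the
worst observed disagreement over 50 random parameter sets is about 1%,
within the 5% band expected of a first-order approximation of a
three-factor product.

Depth aggregation is pro-rata: the layer straddling a depth target
contributes in proportion to the slice used, assuming uniform density
within the layer (no sub-layer information exists in the data model). The
straddling layer's std scales by the same factor. How layer errors
combine within a profile is not determinable from published inventories;
the default treats layers as independent (quadrature sum), a `correlated`
mode (plain sum) is available, and every pipeline manifest logs the mode
used. Independence matches the cross-cell assumption and is conservative
relative to full correlation.

Map units composed of several soil components composite as the
fraction-weighted mean of component stocks. The default variance rule is
the fraction-weighted mean of component variances, reading component stds
as measurement uncertainty; the full mixture variance (adding
between-component spread) is available as `variance_mode="mixture"`.
Inorganic C enters the engine as an equivalent-C concentration in g kg⁻¹
(the CaCO₃-% conversion, factor 0.12, is an ingest-side concern), keeping
the engine element-agnostic. Units are a contract enforced at ingest —
g kg⁻¹, g cm⁻³, %, m — never converted silently inside operations.

## Zonal aggregation

A stratum total is Σ cells stock·area, in Pg (1 Pg = 10¹² kg); direct
areal-content maps (g m⁻²) aggregate the same way without the profile
step and carry no std. Stratum stds assume spatially uncorrelated cell
errors: std = √(Σ (area·std)²). This makes the std partition-invariant
(tested), but it also means errors largely cancel in continental sums, so
aggregate stds are small — unrealistically small if the underlying
estimation errors are in fact spatially correlated, as they likely are
for any kriged or map-unit-based product. A block-correlated aggregation
is a documented extension point, deliberately outside default scope. The
dry and global rows are aggregated directly from their own masks, so the
conservation identities (subtypes sum to dry, dry + humid = global) are
genuine floating-point checks, asserted to relative 1e-10. Per-stratum
content quartiles are plain (unweighted) cell quantiles, checked against
a sort-based oracle; mean content is the area-weighted value
total/area so that content × area recovers the stock.

Report rounding follows inventory phrasing: shares and pool comparisons
round half-up to integers, with raw values always retained alongside.

## Synthetic world

The generator emulates the statistical structure of a WISE30sec-like
input stack with closed-form expectations:

* **Aridity.** A longitude-indexed quantile curve calibrated so the
  subtypes occupy ≈5.8/14.0/16.1/8.9% of land (≈45% dry in total — the
  observed dryland share), times mean-preserving lognormal noise
  (σ = 0.15), clipped to [0, 3]. Land is an i.i.d. 30% mask. On default
  seeds the dry share of land area stays within 40–50% and every stratum
  holds ≥ 1% of land cells.
* **Concentrations.** Saturating mean-vs-AI curves with the observed
  signs: organic C (4→30 g kg⁻¹, τ = 0.6) and total N (0.5→2.5, τ = 0.35)
  increase with AI; carbonate C decreases (10→0.3, τ = 0.4). Organic
  pools decay with depth (rate 1.2 m⁻¹); carbonate accumulates slightly
  (−0.25 m⁻¹). N saturates faster than C so the stratum C:N rises from
  dry to humid, as observed. The resulting mean organic-C content to 2 m
  runs ≈4 kg m⁻² (hyperarid) to ≈18 kg m⁻² (dry subhumid) to ≈25 kg m⁻²
  (humid), matching the magnitude of published stratum means.
* **Physical fields.** Bulk density 1.58→1.33 g cm⁻³ dry→wet with a
  +0.05 g cm⁻³ m⁻¹ depth slope; coarse fragments 25→10%. Both shared
  across element cubes, as in a real database.
* **Dispersion.** Between-cell noise is mean-preserving lognormal for
  concentrations (σ 0.20–0.30) and bulk density (σ 0.05) — positive
  support without truncation bias — and logit-normal for the
  coarse-fragment fraction (σ 0.30 on the logit scale), keeping it in
  (0, 100)%. Published inventories give no error distributions for such
  databases; lognormal is a stand-in chosen for positive support, and
  nothing downstream depends on the distributional family beyond its
  mean. Within-cell std fields are proportional to the value (relative
  stds 0.30–0.40 for concentration, 0.10 for bulk, 0.20 for cfrag),
  emulating a database that publishes per-unit relative uncertainties.
* **Phosphorus.** Total P mean 450→230 g m⁻² dry→wet; five form shares
  (labile inorganic and apatite declining wetward, organic/occluded/
  secondary growing) normalized to one, each form drawn with
  mean-preserving noise, and the total defined as the cell-wise sum of
  forms — so the sum identity is exact by construction.
* **Components.** With `n_components > 1`, each cell draws symmetric
  Dirichlet fractions and per-component mean-preserving concentration
  multipliers, exercising the compositing logic without inventing a
  taxonomy.
* **Seeding.** One master seed; every product draws from a substream
  keyed by a stable label hash, so adding products never perturbs
  existing ones and every output is a pure function of (config, seed).
* **Nodata.** Independent Bernoulli masks (2% by default) on AI and on
  each element cube, constant across a cube's layers and variables.

What the generator does **not** emulate: spatial autocorrelation of
properties or of their errors, real map-unit taxonomy, climate
covariates, or coastline geometry. Passing tests therefore demonstrate
correctness of the accounting and propagation machinery under known
truth, not fidelity of any real-world number; the published global
magnitudes (646 ± 9 Pg dryland organic C etc.) require the real
high-resolution geo-databases and are covered only through the printed
worked arithmetic.

## Analytic truth and parameter recovery

`true_stocks` returns the exact expectation of the pipeline's per-stratum
totals conditional on the realized AI field and nodata masks: lognormal
dispersions are mean-preserving so their expectation is the AI-driven
mean field; the logit-normal coarse-fragment expectation has no closed
form and is evaluated by 41-node Gauss–Hermite quadrature
(deterministic, accurate far beyond test tolerances). The pipeline
estimator is therefore unbiased by construction; tests confirm it
empirically over 100 seeds at 1° (mean error within 2 standard errors)
and check each run lies within 3 reported stds of its truth. With a
dispersion-free configuration the pipeline reproduces truth to 1e-10
relative.

## Problem sizes and numerical choices

Tests run at 0.5°–2° global grids (the implementation is
resolution-agnostic; 2° is the package default, and the recovery study
uses 1° × 100 seeds). Component fractions must sum to 1 within 1e-6;
stratum conservation is asserted at relative 1e-10; sphere-area closure
at 1e-10; raster round-trips are bit-exact (float64 NetCDF via xarray's
scipy backend, geometry carried as exact attributes). Mixture variances
are clamped at zero against floating-point cancellation. Degenerate
inputs fail loudly: zero cell size, depth targets below the profile,
negative stds or AI, misaligned grids, fraction sums off by more than
the tolerance.

## Known limitations

* Aggregate stds inherit the spatial-independence assumption and should
  be read as lower bounds.
* Only geographic lat/lon grids are supported; no reprojection, no
  vector masking (the synthetic world carries its own land-mask raster).
* Pro-rata depth truncation ignores sub-layer density structure.
* No pedotransfer estimation of missing inputs: nodata propagates.
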