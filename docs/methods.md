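# Methods

## The flux model

For each peatland class c ∈ {bog, fen, swamp} the package fits, by ordinary
least squares, the offset-log regression

log₁₀(F + 2) = a_c·WT + b_c + ε,  ε ~ N(0, s_c²),

where F is the plot's mean daily CH₄ flux (mg CH₄ m⁻² d⁻¹) during the warm
season and WT its mean water-table position (cm, negative below the peat
surface). The offset of 2 mg m⁻² d⁻¹ is a fixed model constant — it makes
the logarithm defined for the small negative (uptake) fluxes that occur in
dry plots — and is never estimated. The fit is plain unweighted OLS on plot
means (statsmodels' `OLS` under the hood): the underlying literature
compilation mixes chamber protocols and gives no within-site correlation
structure, so no weighting or mixed-effects structure is attempted. The
reference coefficient sets shipped in `peatline.constants` are
(a, b) = (0.022, 1.53) for bog, (0.025, 1.67) for fen and (0.015, 0.99) for
swamp, with n = 57, 176 and 34 and R² = 0.42, 0.17 and 0.16.

Predictions back-transform **naively**, F̂ = 10^(a·WT+b) − 2, which bounds
predicted flux below by −2 and is what the reference emission factors are
arithmetically consistent with. A lognormal smearing correction
(×exp((s·ln10)²/2)) is available via `predict_daily(..., smearing=True)`
but is used nowhere in the standard pipeline: with fen s ≈ 0.5 it would
roughly double the fen factor and is a different estimand (mean vs median
flux).

Seasonal (= annual) emission factors are E = F̂·D/1000 g CH₄ m⁻² with
D = 123 days (May–August); dormant-season flux is fixed at zero. This
understates annual totals but cancels in the disturbed-minus-undisturbed
difference that is the quantity of interest.

Two sources of mean water table exist and are kept strictly apart:
reproduction runs use the published class means (−22, −8, −18 cm for bog,
fen, swamp); synthetic runs compute means from the data. The published
Results text also prints per-class mean emissions (1.4/7.1/2.5 g m⁻²) that
are inconsistent with the summary table (0.40/3.4/1.1); only the table
values are arithmetically consistent with the regression coefficients, so
the table is treated as authoritative throughout.

## Footprint geometry

Coordinates are planar metres throughout; no geodesic computation occurs
anywhere. Lines are attributed to wetland classes by clipped geometry
(shapely intersection against each polygon, STRtree-accelerated), not by
midpoint or majority rule; the residual outside every wetland polygon is
reported in an `outside` row, and marsh/open-water lengths are computed but
excluded from peatland totals. Swamps count as peatland by default
(`include_swamp=False` excludes them). Length conservation — clipped
lengths plus outside remainder equal total network length — holds exactly
when polygons do not overlap, and is asserted in tests at 1e-6 relative.

Length→area conversion has two dialects:

* **length × width** (default, reproduces the provincial totals): widths
  6 m legacy, 3 m LIS, 4 m trail;
* **buffer–dissolve** (sensitivity): each line buffered by width/2 with
  flat end caps, buffers dissolved *within* line type, then intersected
  with the class polygons. Dissolving removes double counting at crossings,
  so this area is cell-by-cell ≤ the length × width area (asserted on
  random scenes). Whether the original provincial analysis dissolved
  overlaps is unknowable from the published description; both numbers are
  therefore reported. Per-type (rather than global) dissolve was chosen so
  the class × type table remains well defined; cross-type overlaps are a
  second-order effect at realistic densities.

`density_grid` reports pooled line length per cell / cell area (km km⁻²)
on a regular grid, the standard disturbance-density summary.

## Scenario engine and units

Baseline: E₀ = Σ_c A_c·E_c(WT_c), with A_c the class areas
(30,050 / 58,580 / 46,160 km² for bog/fen/swamp). Since 1 g m⁻² over 1 km²
is exactly 1 t, kt = g m⁻² × km² × 10⁻³; a dedicated unit test pins this
chain with a contrived round-number configuration.

Disturbance: the class mean WT is shifted toward the surface by
Δ ∈ {13.9, 15.4} cm — two point scenarios from field measurements on
disturbed fens and bogs respectively, treated as a bracket, not a
distribution. The shifted fen water table (+7.4 cm at Δ=15.4) sits *above*
the surface; the regression is deliberately extrapolated there without
capping, because the reference on-line emission factors require it. A
`cap_at_surface` flag exists for sensitivity. Enhancement per class is
footprint area × (disturbed − undisturbed factor); the footprint areas for
reproduction runs are 490/790/630 km².

Under printed-constant inputs the pipeline yields per-class factors
1.12/3.38/0.40 (undisturbed), 2.52/7.83/0.80 (Δ=13.9) and 2.74/8.56/0.85
(Δ=15.4) g m⁻², baseline 250.4 kt, and enhancements summing to 4.45–5.17
kt. Four reference cells (bog 2.8, fen 8.5, fen enhancement 3.44/4.01 and
its knock-ons) differ from this arithmetic in the last printed digit; the
discrepancy is consistent with the original analysis having used unrounded
per-class areas and water tables, and those cells are documented here
rather than targeted by tests.

## Uncertainty propagation

The published 95% interval on the baseline (0–3200 kt) comes with no
stated construction, so the package implements a parametric Monte Carlo and
does not claim to reproduce those bounds. Per draw and class,
(intercept, slope) is sampled from the fitted coefficient sampling
distribution (the OLS covariance), and a single residual-scale error
ε ~ N(0, s_c²) is added to the log₁₀ linear predictor of *both* the
undisturbed and shifted prediction of that draw — ε represents how far the
class's true mean flux sits from the regression line, which is common to
both predictions rather than independent between them. The full emission
arithmetic is recomputed per draw; 2.5/50/97.5 percentiles are reported and
negative baseline draws are truncated at zero for reporting. Defaults:
2000 draws, seeded `numpy` Generator; `coef_scale`/`resid_scale`
multipliers exist for degenerate (variance-zero) and sensitivity runs.
Results objects built from published coefficients carry no covariance and
refuse to propagate uncertainty rather than inventing one.

## Synthetic data

`generate_flux_table` draws, per class, n plots with WT from
N(μ_c, 10 cm) truncated to [−60, +10] cm and flux
10^(a_c·WT + b_c + ε) − 2. Sample sizes, coefficients and WT means default
to the study conditions above. The WT spread is not a published quantity;
10 cm truncated to the plausible axis range was chosen once as realistic
for warm-season plot means and is recorded in metadata, not claimed from
any source. Residual sds (0.26/0.55/0.34 log₁₀ units) follow from
inverting R² = a²·var(WT)/(a²·var(WT)+s²) at the reference R² values with
that spread — so refits recover both the coefficients and roughly the
reference R². Plots are generated independently: the real compilation's
within-site and between-protocol correlation is *not* emulated, so
parameter-recovery tests validate the estimation machinery, not robustness
to heterogeneous field data.

`generate_landscape` tiles a rectangular region (default 10 × 10 km, 1-km
tiles) into wetland-labelled cells by largest-remainder apportionment of
the class fractions (default bog 0.25, fen 0.30, swamp 0.15, marsh 0.05,
open water 0.05; the rest unlabelled upland), shuffled by the seed. Legacy
and trail lines are straight full-span grids (horizontal/vertical) with
counts rounded to meet the target density (defaults 1.5, 0.5 km km⁻²);
LIS lines are serpentine paths confined to tiles, cut to exactly
density × tile area (default 3 km km⁻²) — emulating the dense, slightly
meandering low-impact grids. Because tiles are axis-aligned, the exact
clipped length of every line per class is computed at generation time by
interval arithmetic, independent of the geometry library, and stored as
truth metadata; the footprint stage is validated against it at 1e-6
relative. Straight-line coordinates are nudged 10⁻³ of a tile off any tile
boundary so clipped lengths are unambiguous. The landscapes are schematic:
rectangular tiles, no realistic geography, no raster layers, and no attempt
to mimic the real inventories' digitising artefacts.

## Numerical and interface choices

* GeoJSON serialisation uses `json` + `shapely.geometry.mapping/shape`;
  coordinates round-trip exactly (Python float repr). Parse errors name
  the offending file and feature index.
* Degenerate inputs fail loudly: < 3 observations, all-equal water tables,
  flux ≤ −2, invalid polygons (named by index), unknown labels, negative
  shifts, n_draws < 100.
* The CLI (`simulate | fit | footprint | scenarios | reproduce`) keeps the
  printed-constant reproduction mode and the synthetic end-to-end mode as
  separate subcommands so the two can never silently mix; every run writes
  a JSON log (parameters, seed, versions) and removes partial outputs on
  failure, exiting non-zero.
* Report tables round nothing internally; formatting to the 2-significant-
  figure convention of the reference table is left to the caller.

## Problem sizes

The test suite runs the full study-scale regressions (n = 57/176/34),
100-replicate coverage checks, 200-regeneration bias checks, 50 random
2 × 2-km scenes for the geometric invariants, and 10⁴-point sampling
oracles — about ten seconds on one CPU. The acceptance script's
Monte-Carlo diagnostic uses 2000 draws. Landscape defaults (10 × 10 km)
were chosen as the smallest region on which grid densities and class
fractions are all resolved to within a few percent.

## Known limitations

Only the hydrologic pathway is modelled: temperature shifts, vegetation
change and edge effects on adjacent peatland — all plausibly emission-
increasing — are out of scope, as are CO₂ exchange and radiative-forcing
aggregation. The line inventories the synthetic landscapes emulate are
known to under-detect narrow LIS lines, so realistic applications of the
pipeline inherit that underestimate. The regression treats WT as the sole
covariate; its extrapolation above the surface (fen scenario) is a modelling
convention, not a validated prediction.
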