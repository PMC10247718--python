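# Methods

## The harmonization model

The package reconciles two statistical layers of fertilizer reporting.
Provinces report crop-specific application *rates* for rice, wheat and
maize (two fertilizer kinds: phosphorus fertilizer, whose statistics are
already P₂O₅ mass, and compound "component" fertilizer, reported as
gross product mass) together with total consumption and sown areas.
Counties report only total consumption and sown areas. The pipeline has
five stages.

**1. Provincial residual rate.** Named-crop consumption is rate × sown
area; the residual of the provincial total is attributed to "other
crops" and divided by the residual sown area (total sown minus named).
Two degenerate cases get explicit policies rather than silent numbers:
a negative residual (named crops "consume" more than the total) is
clamped to zero and flagged `clamped` — negative mass never propagates —
and a positive residual over zero other-crops area yields no rate
(`undefined`); downstream allocation then treats the category as
zero-weight. The source statistics can contain either inconsistency and
the original study does not say how (or whether) it encountered them;
clamp-and-flag preserves auditability.

**2. Gap-filling.** County consumption and area series have sporadic
missing years. Interior runs of at most `max_run = 2` consecutive
missing years ("fewer than 3") are filled with a natural cubic spline
(second derivative zero at the ends — the least-assumption boundary
condition) through all observed points of the series, floored at zero;
longer runs and boundary gaps stay missing and the affected county-years
are dropped with a reason code. Filling is applied to the *inputs*
(county totals and areas); ratios and rates are always recomputed from
filled inputs, never interpolated directly, which preserves mass
conservation through the fill. Whether the original build filled areas,
consumptions or both is not documented; filling both is this package's
declared choice. A fill needs at least 4 observed points (a cubic
spline is not defined below that); series failing this are left
unfilled rather than aborting the run.

**3. Ratio allocation.** Per county-year-kind, the allocation ratio of
crop *i* is `FR_ipy·A_ijy / Σ_i FR_ipy·A_ijy`. The denominator sums over
the four categories in fixed enumeration order (rice, wheat, maize,
other) so the conservation property is bit-deterministic. A county
whose province has no other-crops rate for that year falls back to
allocating over the three named crops, flagged `named_only`, instead of
being discarded for a provincial bookkeeping artifact. A zero
denominator (no fertilized area) makes the county-year undefined.
County crop consumption is ratio × county total, and the county rate is
consumption / area. Division by a zero area can only occur with zero
consumption (ratio 0); such records are dropped with reason
`zero_area`, never emitted as 0/0. Positive consumption over zero area
raises — it signals inconsistent upstream tables, not a policy case.

Analytically: because ratios are normalized within each county, the
county total is conserved exactly regardless of how wrong the
provincial crop structure is locally; and when county truth equals the
provincial rates (the "provincial-uniform" regime) the three steps
collapse algebraically, so county rates are recovered exactly. These
two properties — not pointwise accuracy in heterogeneous counties — are
what the method guarantees, and the tests assert exactly that and no
more.

**4. P₂O₅ conversion.** Phosphorus-kind rates pass through unchanged
(already P₂O₅). Component-kind rates are multiplied by a year-specific
weighted content: imported product is 60.0% P₂O₅, domestic 30.8%, and
the import/domestic split (China, 2004–2016) ships as an editable
constants CSV; the conversion assumes the statistics quantify gross
product mass. If one kind is missing for a county-year-crop the sum
covers the available kind and is flagged `partial`. Elemental-P
quantities (for comparisons against P-basis datasets) convert by the
molar-mass ratio 142/62.

**5. Gridding.** County membership of a pixel comes from a supplied
county-ID raster — never re-derived from polygons — and a per-crop-year
presence mask selects growing pixels. Maps are single-band Float32
GeoTIFFs, WGS84 (EPSG:4326), north-up, pixel-center convention, NoData
−9999.0 recorded in the GDAL tag, named `CNP_<crop>_<year>.tif`. GeoTIFF
I/O is implemented directly over `tifffile` with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory),
which keeps round trips bit-exact.

## Units and missing data

Canonical internal units are grams, square metres and g m⁻² (rates);
inputs in kg/ha, tonnes, hectares etc. are converted once, on read,
driven by an explicit unit configuration, because the yearbooks' native
units vary by table. Missing data is an explicit status
(`observed/missing/gap_filled/dropped/...`), never NaN-as-zero: the
gap-fill rule needs run lengths, and every dropped record carries a
reason code.

## The synthetic world

The generator emulates the structure of the study's inputs: 31
provinces with 60–80 counties each (~2200 counties; the real county
yearbooks cover 2267), years 2004–2016, four crop categories, two
fertilizer kinds, missing county-years inserted as interior runs of at
most 2 at 5% probability. Counties are rectangular tiles on the grid
(each pixel nominally 1 km² = 10⁶ m²); rate time-series are low-order
polynomials in the year with small (1%) multiplicative noise, so spline
fills have a quantifiable truth. Base rates and growth constants are
set so the national P₂O₅ means land near the published dataset's
reported magnitudes (wheat highest at ~8.5 g m⁻², rice and maize ~6.4,
maize the fastest-rising trend at ~2 %/yr) — the nominal growth rates
are higher than the realized P₂O₅ trends because the component
fertilizer's weighted P₂O₅ content itself declines over 2004–2016 as
the domestic share grows.

Two flavors matter. *Provincial-uniform* worlds (county rates equal
provincial rates) are the exact-recovery regime and every consistency
test there asserts 10⁻⁹ relative agreement with ground truth.
*Heterogeneous* worlds (county multipliers, CV 0.15) are the realistic
regime, where tests assert only what the method guarantees:
conservation and aggregate consistency. `perturb_world` injects single
named pathologies (named-crop overshoot, a zero-area county with
positive consumption, an unfillable gap run) to exercise the edge
policies.

What the generator does **not** emulate: real administrative geography,
reporting biases or systematic under-coverage of the yearbooks,
within-year composition variation of component fertilizer, correlated
missingness (e.g. whole provinces absent in a year), or sub-county
heterogeneity. Passing tests therefore demonstrate correctness of the
accounting and allocation machinery, not the accuracy of the published
dataset against independent ground truth. Absolute consumption totals
of the synthetic country scale with its grid area and are much smaller
than national Chinese totals; rates (the per-area quantities) are the
calibrated, comparable outputs.

## National statistics

National annual means are area-weighted over counties with defined
rates; sub-crop variants (e.g. single/double-season rice) are handled
by passing a group of crop labels that is combined by area weighting
before aggregation. The relative trend is 100 × OLS slope / period
(2004–2016) mean — the published table prints "% yr⁻¹" without defining
the denominator; the period mean is the conventional choice and is
declared here. Slope significance is the two-sided t-test from the OLS
fit; a zero-residual (perfect-line) fit is flagged degenerate with p
set to 0 (or 1 when the slope is also zero) instead of reporting a
meaningless test. Tukey HSD uses crops as groups and the 13 annual
national means as replicates (the sample unit the published table most
plausibly used — declared, not asserted as the original's method), with
a compact letter display at α = 0.05 computed by insert-and-absorb.
The per-cropland analysis divides total county P₂O₅ consumption by
physical cropland area, which multi-cropping makes smaller than summed
sown area; cropland ships as an extra row kind in the county area
table.

## Numerical choices and problem sizes

All conservation-sensitive sums run in fixed ascending crop order.
Equality tolerances: 10⁻⁹ relative for conservation/recovery claims,
10⁻¹² for hand-computable arithmetic, bit-exact for raster round trips.
The default test suite and the acceptance script use worlds from 2×10
counties up to the full 31-province scale (~2200 counties, ~56,000
county-year-kind cells, 200×240 grid), sizes chosen so a complete run
of the pipeline plus statistics finishes in well under a minute on one
CPU while still exercising every code path at realistic cardinalities.
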