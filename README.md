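# cnp — crop-specific phosphorus fertilizer rate mapping

`cnp` builds gridded, crop-specific phosphorus application-rate maps from
two layers of agricultural statistics that do not match in granularity:

* **provincial** statistics report crop-specific fertilizer *rates* (kg/ha
  of phosphorus fertilizer and of multi-nutrient "component" fertilizer,
  for rice, wheat and maize) plus total consumption and sown areas;
* **county** statistics report only *total* fertilizer consumption and
  sown areas, but at far finer spatial resolution.

Naively multiplying provincial rates onto fine-scale land maps smooths
out local variability and mixes statistical calibers. `cnp` instead uses
a conservative (mass-conserving) allocation: provincial rates only set
the *split* of each county's own reported total across crops.

## Method

For crop *i*, county *j* (in province *p*), year *y*, and each fertilizer
kind separately:

```
Rat_ijy = FR_ipy · A_ijy / Σ_i FR_ipy · A_ijy      (allocation ratio)
FC_ijy  = Rat_ijy · FC_jy                          (county crop consumption)
FR_ijy  = FC_ijy / A_ijy                           (county crop rate)
```

where `FR_ipy` is the provincial crop-specific rate (the residual
"other crops" rate is derived first by subtracting the named crops'
consumption from the provincial total), `A_ijy` the county sown area and
`FC_jy` the county's reported total consumption. Because the ratios are
normalized per county, `Σ_i FC_ijy = FC_jy` holds exactly — the county
total is never rescaled. When every county in a province shares the
provincial rates, the three equations collapse and county rates are
recovered exactly.

County series with interior gaps of at most 2 consecutive missing years
are filled with a natural cubic spline; longer runs are dropped, never
guessed. Phosphorus-fertilizer statistics are already P₂O₅ mass;
component fertilizer is converted with a year-specific weighted P₂O₅
content (imported product 60.0%, domestic 30.8%, weighted by the annual
import/domestic split shipped in `src/cnp/data/component_shares.csv`).
The combined rate, in g P₂O₅ m⁻², is painted onto a WGS84 grid through a
county-ID raster and per-crop growing-area masks, one GeoTIFF per
crop-year named `CNP_<crop>_<year>.tif`.

A first-class synthetic-data module (`cnp.synth`) generates internally
consistent worlds — provinces, counties on a raster, areas, rates with
known ground truth, controlled missingness — so the whole pipeline is
testable without the source yearbooks.

## Worked example

```python
import cnp

cfg = cnp.WorldConfig(n_provinces=4, counties_per_province=(8, 12),
                      grid_rows=60, grid_cols=80, missing_rate=0.05,
                      heterogeneous=True, seed=11)
world = cnp.generate_world(cfg)
result = cnp.run_pipeline(world.prov_rates, world.prov_totals, world.county)

series = {c: cnp.national_series(result.rates, world.county, c)
          for c in cnp.NAMED_CROPS}
letters = cnp.tukey_hsd(series).letters
for crop, s in series.items():
    tr = cnp.relative_trend(s)
    print(f"{crop:6s} {s['mean'].mean():5.2f} g P2O5/m2   "
          f"{tr.relative_trend:+5.2f} %/yr (p={tr.p_value:.2g})   [{letters[crop]}]")
```

prints

```
rice    6.68 g P2O5/m2   +1.24 %/yr (p=1.7e-06)   [a]
wheat   7.21 g P2O5/m2   +0.43 %/yr (p=0.0053)   [b]
maize   6.39 g P2O5/m2   +2.53 %/yr (p=2.2e-09)   [a]
```

i.e. per crop: the 2004–2016 area-weighted national mean P₂O₅ rate, the
relative OLS trend (100 × slope / period mean) with its slope t-test
p-value, and the Tukey-HSD compact letter (crops sharing a letter do not
differ significantly at α = 0.05). Maps are then one call away:

```python
maps = cnp.grid_maps(result, world.county_raster, world.crop_masks,
                     world.geom, directory="maps", years=[2010])
rm = maps[("wheat", 2010)]
print(f"{rm.filename()}: {int(rm.finite_mask.sum())} crop pixels, "
      f"mean {rm.values[rm.finite_mask].mean():.2f} g/m2")
# CNP_wheat_2010.tif: 3480 crop pixels, mean 7.13 g/m2
```

A thin CLI wraps the same functions: `cnp synth` (generate a world),
`cnp run` (pipeline from a YAML config), `cnp stats` (national report),
`cnp grid` (rasterize one crop-year).

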