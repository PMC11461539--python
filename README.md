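# pivotwdi

Water-stress detection for row crops from sensors mounted on a center-pivot
irrigation system. The package computes the **Water Deficit Index (WDI)** from
infrared surface temperature, NDVI, and weather data, simulates the same
stress signal with a transparent daily soil-water-balance model, and ships a
fully seeded synthetic-season generator so every step can be validated
against known ground truth.

It is written for agricultural engineers and crop physiologists working on
irrigation scheduling: people who have pivot-mounted IRT/NDVI sensor logs and
weather records and want a tested, reproducible path from raw 30-second
readings to per-plot stress indices and treatment summaries.

## The model

The WDI generalizes the crop water stress index to partial canopy cover. For
a surface with canopy cover fraction *Fc*, the measured surface-minus-air
temperature is located between theoretical wet and dry limits:

    WDI = [(Ts − Ta)_measured − (Ts − Ta)_lower] / [(Ts − Ta)_upper − (Ts − Ta)_lower]

with

    (Ts − Ta)_lower = Fc·(Ts − Ta)_wet_veg  + (1 − Fc)·(Ts − Ta)_wet_soil
    (Ts − Ta)_upper = Fc·(Ts − Ta)_dry_veg  + (1 − Fc)·(Ts − Ta)_dry_soil

WDI = 0 means a fully transpiring surface, WDI = 1 a surface with no
evaporative cooling. The four corner temperatures come from one-layer energy
balances of the form

    (Ts − Ta) = ra·(Rn − G)/(ρa·Cp) · X/(Δ + X) − VPD/(Δ + X),   X = γ·(1 + rc/ra)

evaluated for a well-watered canopy (rc = rcp = 20 s m⁻¹), a fully stressed
canopy (rc = rcx = 650 s m⁻¹), saturated bare soil (rc = 0), and dry bare
soil (pure radiative term). Aerodynamic resistance uses the neutral
log-profile `ra = ln[(Zm−d)/Zom]·ln[(Ze−d)/Zov]/(k²·u2)` with
canopy-height-based roughness for vegetation and d = 0, Zom = 0.01 m for
bare soil. *Fc* comes from a linear NDVI calibration (built-in preset
`Fc = 0.9449·NDVI + 0.1539`) or from Otsu thresholding of a reflectance
raster.

The companion stress model is a daily root-zone bucket: depletion *Dr* grows
with Ks-reduced crop ET and shrinks with rain and irrigation, and

    Ks = (TAW − Dr)/(TAW − RAW)  for RAW < Dr ≤ TAW  (else 1),   WDI_sim = 1 − Ks

with the percent-ET-replacement scheduler (weekly dose = fraction × weekly
crop ET less rain; doses above 25 mm split into two applications 3 days
apart) reproducing field irrigation practice.

## Worked example

The `analysis/` scripts form a narrative pipeline over a synthetic season
(12 pie-slice plots, randomized complete block design, ET-replacement
treatments of 0/30/60/90%, twice-weekly sensor passes with 0.5 °C / 0.02
sensor noise):

```
python analysis/01_simulate_season.py      # writes results/season/*
python analysis/02_sensor_wdi.py           # sensor WDI per plot-date
python analysis/03_water_balance.py        # simulated WDI = 1 - Ks
python analysis/04_compare_models.py       # R^2, d-index, %RMSE
python analysis/05_wind_sensitivity.py     # wind-speed response
```

With the default seed the run prints:

```
seasonal mean WDI by ET-replacement treatment:
 treatment  wdi_mean  n_plot_dates
       0.0  0.575893            66
       0.3  0.412650            66
       0.6  0.148580            66
       0.9  0.006155            66

sensor vs simulated WDI over 264 plot-dates:
{"r_squared": 0.99976, "d_index": 0.99993, "rmse_pct": 2.02, "n": 264}

 factor      wdi  pct_change
    1.0 0.500000    0.000000
    1.1 0.537657    7.531425
    1.5 0.660173   32.034611
```

Reading: stress decreases monotonically with irrigation (dryland plots
average WDI ≈ 0.58, the 90% ET-replacement plots are essentially
unstressed); the sensor-derived index tracks the water-balance truth it was
generated from almost perfectly at this noise level; and increasing wind
speed by 10% / 50% raises the WDI of a stressed mid-season state by about
7.5% / 32% through reduced aerodynamic resistance.

A `pivotwdi` command-line tool exposes the same steps on files
(`simulate`, `wdi`, `balance`, `compare`, `calibrate-fc`); see
`pivotwdi --help`.

## Layout

- `src/pivotwdi/` — library: `met` (FAO-56-style meteorology and
  aerodynamics), `trapezoid` (corner temperatures, limits, WDI, wind
  sensitivity), `canopy` (NDVI calibration, Otsu cover), `waterbalance`
  (bucket model, Ks, ET-replacement scheduler), `synth` (seeded season
  generator), `pipeline` (assignment, filtering, aggregation, comparison
  statistics), `io`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property (hypothesis), and end-to-end acceptance tests.
- `docs/methods.md` — model assumptions, parameter defaults, and design
  choices.
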