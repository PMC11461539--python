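# Methods

This note records the scientific content of the package: the models, their
assumptions, the parameter defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical conventions.

## Trapezoid energy balance

The WDI locates the measured composite surface-minus-air temperature between
theoretical wet and dry limits obtained by Fc-weighting four one-layer
energy-balance corners (well-watered canopy, fully stressed canopy,
saturated bare soil, dry bare soil). Assumptions inherited from that model
family:

- One-source surfaces: the measured temperature is a composite of canopy and
  soil; no two-source partitioning is attempted.
- Neutral atmospheric stability in the aerodynamic resistance; no stability
  corrections.
- Steady conditions over a sensor pass: one meteorological state (the hourly
  record nearest solar noon) parameterizes the whole traverse.

Thermodynamics follow the standard FAO-56 closed forms: Tetens saturation
vapor pressure, Δ = 4098·es/(T+237.3)², γ = 0.000665·P, dry-air density
ρa = P/(1.01·(T+273)·0.287), Cp = 1013 J kg⁻¹ °C⁻¹. Wind measured off the
2 m reference height is corrected with the logarithmic profile factor
4.87/ln(67.8·z − 5.42).

### Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| rcp | 20 s m⁻¹ | canopy resistance, well-watered cotton canopy |
| rcx | 650 s m⁻¹ | canopy resistance, fully stressed canopy |
| hc | 0.90 m | season-average cotton canopy height; sets d = 0.67·hc, Zom = 0.123·hc, Zov = 0.0123·hc |
| bare-soil roughness | Zom = 0.01 m, d = 0 | standard bare-soil momentum roughness |
| bare-soil Zov | 0.1·Zom | heat/vapor roughness an order of magnitude below momentum, the usual convention; configurable |
| albedo | 0.23, 0.23, 0.16, 0.23 | per corner (wet veg, dry veg, wet soil, dry soil); wet soil is darker |
| cG (soil heat flux) | 0.1, 0.1, 0.3, 0.3 | G = cG·Rn; full canopies shade the soil, bare soil conducts more. No published formulation exists for the four corners, so these fractions are an explicit, configurable assumption |
| surface pressure | 101.3 kPa | default; a standard-atmosphere pressure-from-elevation helper is provided and used when a site elevation is known |

Net longwave radiation uses the hourly-scale form
Rnl = σT⁴(0.34 − 0.14√ea)(1.35·f − 0.35) with the clear-sky fraction
f = Rs/Rso clamped to [0.3, 1.0]; Rso comes from instantaneous
extraterrestrial radiation times a 0.75 clear-sky transmissivity. Hourly
formulation was chosen because the sensor streams are sub-hourly and
averaged near solar noon. Unit tests and sensitivity exercises can force
Rnl = 0 to isolate the shortwave balance.

The published form of the stressed-canopy corner mixes the vegetation
resistance (leading factor) with the bare-soil resistance (inside the
canopy-resistance ratio). A dry full-cover canopy still has canopy
roughness, so the default uses the vegetation resistance throughout the
vegetation corners; `SurfaceParams(printed_dry_vegetation=True)` reproduces
the mixed form for comparison. Measured temperatures falling outside the
theoretical envelope (routine under sensor noise) are clamped to [0, 1] and
flagged rather than rejected; a non-positive trapezoid width raises an
error naming the offending timestep.

## Canopy cover

Two routes to Fc:

- **Linear NDVI calibration**, ordinary least squares, applied with
  clamping to [0, 1] (out-of-range predictions flagged). A field-derived
  preset (slope 0.9449, intercept 0.1539) ships as the default; ground
  stations staring straight down at a closed canopy use Fc = 1.
- **Otsu thresholding** of a single-band reflectance raster: 256 equal-width
  bins over the finite pixel range, between-class variance maximized in
  exact integer arithmetic on bin indices (the statistic is affine-invariant
  in the bin values), ties broken toward the lower threshold. Exact
  arithmetic makes the tie-break genuinely deterministic — with floats, the
  empty-bin plateau between well-separated classes resolves to an arbitrary
  bin depending on rounding order. Cover is the fraction of pixels strictly
  above the threshold.

## Soil water balance

A single-bucket root zone (0–30 cm): Dr_t = Dr_{t−1} − (P + I) + Ks·Kc·ETo,
with same-day deep percolation of inputs beyond field capacity and ET capped
by the water actually present, so the seasonal mass balance closes exactly.
Ks is evaluated on the post-input depletion (irrigation relieves stress the
day it lands). Defaults:

- TAW = 40 mm over 0.30 m (a fine sandy loam's plant-available water in the
  surface layers); RAW = 0.65·TAW. These are generic placeholders for the
  soil family, not site measurements, and are the first thing a user should
  set.
- Crop coefficients: piecewise-linear cotton curve, Kc 0.35 (0–30 d),
  rising to 1.15 (80–135 d), falling to 0.70 at 180 d; values held with a
  warning beyond season end.
- Reference ET: a radiation-temperature form ETo = 0.0135·(Ta + 17.8)·Rs_w
  (Rs converted to equivalent mm) for self-containment; externally measured
  ETo can be supplied and takes precedence.
- Scheduler: week w's dose = fraction × (weekly crop ET − rain that week,
  floored at 0), applied the first day of week w+1; doses above 25 mm are
  split into two equal applications 3 days apart. Rain crediting is what
  makes the 30% treatment nearly rain-fed in wet seasons.
- Runoff is ignored (flat pivot ground); no multi-layer profile, no crop
  growth feedback on root depth.

Ks is clamped to 1 for Dr < RAW, so WDI_sim = 1 − Ks runs from 0
(unstressed) to 1 (wilting).

## Synthetic season

The generator emulates the study system: a semi-arid Southern Great Plains
summer (season mean Ta 27 °C with a zero-mean seasonal cycle and AR(1)
day-to-day noise, mostly clear skies, mean wind 4.5 m s⁻¹, sporadic
convective rain of ~9 mm at 18% daily probability), a half-circle field of
12 equal 15° pie slices on an 82 m sensor arc, treatments randomized within
3 blocks of 4, logistic canopy growth to a ~0.92 plateau with small
plot-level jitter, and 30-second sensor passes within ±2 h of solar noon.
Surface temperature is synthesized by inverting the index —
Ts = Ta + dT_lower + WDI_true·(dT_upper − dT_lower) + ε, ε ~ N(0, 0.5 °C) —
and NDVI by inverting the Fc calibration with ε′ ~ N(0, 0.02). An optional
soil-background bias proportional to (1 − Fc) can emulate the upward bias
of angled pivot sensors over partial canopies; it is off by default.

Because synthesis inverts the same equations the pipeline applies (with the
same solar-noon record and the same clear-sky fraction), a zero-noise pass
is recovered exactly — this is the package's strongest internal check. The
flip side is what passing tests do **not** show: the synthetic data cannot
reveal structural errors shared by the generator and the pipeline (e.g., a
wrong corner equation would cancel), says nothing about view-angle or
soil-background effects on real IRT/NDVI readings, row-orientation NDVI
variability, spatially varying weather, or calibration drift. The noisy
tests demonstrate statistical recovery of an imposed stress pattern, not
field accuracy.

Problem sizes: the default validation season is 150 days with 22 passes of
480 readings (≈10,500 records), which exercises every code path while the
full test suite completes in well under a minute.

## Numerical conventions

- Units: °C, kPa, W m⁻², s m⁻¹, kg m⁻³, mm of water; angles in degrees
  counterclockwise from east, plots as half-open intervals [start, end).
- Timestamps are local standard time; solar noon from site longitude, the
  time-zone meridian, and an equation-of-time approximation; no
  daylight-saving logic.
- WDI boundary values are exact (0 at the lower limit, 1 at the upper);
  plot assignment at a slice boundary goes to the higher slice.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  output.
- Every filter and drop decision in the pipeline is counted and written to
  a plain-text run report; record counts are conserved exactly.

## Known limitations

- Constant canopy height (0.90 m) all season: early-season roughness is
  overestimated; the trapezoid limits are least reliable at low Fc.
- The hourly net-longwave term and the 0.75 clear-sky transmissivity are
  approximations; users with measured net radiation should prefer it.
- The bucket model has no soil evaporation separate from transpiration and
  no stress memory; it is a transparent stand-in for a full cropping-system
  simulation, suitable for index comparison rather than yield prediction.
- The comparison statistics (R², d-index, %RMSE) are descriptive; no
  uncertainty intervals are attached.
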