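"""Synthetic season generator with known ground truth.

Emulates the study system end to end: a semi-arid summer cotton season of
daily weather with hourly records around solar noon, a half-circle pivot
field of 12 pie-slice plots in a randomized complete block design with four
percent-ET-replacement irrigation treatments (0/30/60/90%), per-plot stress
trajectories from the soil water balance, logistic canopy growth, and noisy
30-second sensor passes along the sensor arc. The sensor synthesis inverts
the trapezoid: Ts = Ta + dT_lower + WDI_true*(dT_upper - dT_lower) + noise,
with NDVI from the inverse of the Fc calibration, so that at zero noise the
downstream pipeline recovers the truth exactly.

Angular convention: bearings in degrees, counterclockwise from east, the
cropped half circle spanning [0, 180) with plots as half-open slices
[start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_type
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import met as met_mod
from . import solar
from .canopy import COTTON_PIVOT_PRESET, FcCalibration
from .errors import MissingWeatherError, ValidationError
from .met import MetRecord
from .trapezoid import SurfaceParams, corners_from_record, temperature_limits
from .waterbalance import (KcCurve, SoilProfile, eto_hargreaves,
                           et_replacement_schedule, kc_at, run_water_balance)

TREATMENTS = (0.0, 0.30, 0.60, 0.90)


@dataclass(frozen=True)
class SeasonConfig:
    """Climate and site configuration for a synthetic season.

    Defaults emulate a semi-arid Southern Great Plains summer: hot, mostly
    clear, windy, with sporadic convective rain. ``ta_mean_c`` is the
    season-mean air temperature (the seasonal cycle is constructed with zero
    mean around it).
    """

    start: str = "2021-05-27"
    days: int = 150
    lat: float = 34.194
    lon: float = -99.519
    tz_meridian: float = -90.0
    elevation_m: float = 440.0
    ta_mean_c: float = 27.0
    ta_seasonal_amp_c: float = 4.0
    ta_daily_sd_c: float = 2.0
    diurnal_amp_c: float = 7.0
    rh_mean_pct: float = 45.0
    rh_sd_pct: float = 8.0
    wind_mean_ms: float = 4.5
    wind_sd_ms: float = 1.5
    rain_prob: float = 0.18
    rain_mean_mm: float = 9.0
    noon_window_h: float = 3.0

    def validate(self) -> None:
        if self.days < 7:
            raise ValidationError("season must span at least one week")
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ValidationError(f"rain probability {self.rain_prob} outside [0, 1]")
        if self.rain_mean_mm < 0 or self.ta_daily_sd_c < 0 or self.rh_sd_pct < 0:
            raise ValidationError("negative variance/scale parameter")
        if not -90 < self.lat < 90:
            raise ValidationError(f"latitude {self.lat} out of range")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian sensor noise; soil-background temperature bias is
    proportional to the exposed soil fraction (1 - Fc) and off by default."""

    sigma_ts_c: float = 0.5
    sigma_ndvi: float = 0.02
    soil_bias_ts_c: float = 0.0

    def validate(self) -> None:
        if self.sigma_ts_c < 0 or self.sigma_ndvi < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass
class FieldLayout:
    """Half-circle pivot field of 12 equal pie-slice plots with treatments.

    ``plots`` has one row per slice: plot, block, theta_start, theta_end
    (degrees, half-open [start, end)), treatment (ET-replacement fraction).
    """

    plots: pd.DataFrame
    sensor_radius_m: float = 82.0
    lat: float = 34.194
    lon: float = -99.519
    tz_meridian: float = -90.0
    elevation_m: float = 440.0

    def plot_at(self, angle_deg: float) -> int | None:
        """Plot id whose half-open slice contains the bearing, else None."""
        if not 0.0 <= angle_deg < 180.0:
            return None
        row = self.plots[(self.plots.theta_start <= angle_deg)
                         & (angle_deg < self.plots.theta_end)]
        return int(row["plot"].iloc[0]) if len(row) else None

    def treatment_of(self, plot: int) -> float:
        return float(self.plots.set_index("plot").loc[plot, "treatment"])


def generate_field_layout(seed: int, config: SeasonConfig | None = None,
                          sensor_radius_m: float = 82.0) -> FieldLayout:
    """Randomized complete block layout: 3 blocks x 4 treatments on 15-degree slices."""
    cfg = config or SeasonConfig()
    rng = np.random.default_rng(seed)
    width = 180.0 / 12.0
    rows = []
    for block in range(3):
        order = rng.permutation(TREATMENTS)
        for j, trt in enumerate(order):
            plot = block * 4 + j + 1
            rows.append({"plot": plot, "block": block + 1,
                         "theta_start": (plot - 1) * width,
                         "theta_end": plot * width,
                         "treatment": float(trt)})
    return FieldLayout(plots=pd.DataFrame(rows), sensor_radius_m=sensor_radius_m,
                       lat=cfg.lat, lon=cfg.lon, tz_meridian=cfg.tz_meridian,
                       elevation_m=cfg.elevation_m)


def generate_weather(config: SeasonConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded daily and near-noon hourly weather for one season.

    Returns ``(daily, hourly)``. Daily rows carry season-scale means used by
    the water balance; hourly rows (within ``noon_window_h`` of solar noon)
    carry the diurnal-cycle values the sensor passes see. ``rs_wm2`` is the
    daily-mean flux in the daily table and the instantaneous flux hourly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.days
    start = pd.Timestamp(config.start)
    dates = pd.date_range(start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy()
    frac = np.arange(n) / max(n - 1, 1)

    # zero-mean seasonal cycle + AR(1) weather noise
    shape = config.ta_seasonal_amp_c * (np.sin(np.pi * frac) - 2.0 / np.pi)
    rho = 0.7
    eps = rng.normal(0.0, config.ta_daily_sd_c * np.sqrt(1 - rho ** 2), n)
    ar = np.empty(n)
    ar[0] = rng.normal(0.0, config.ta_daily_sd_c)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + eps[i]
    ta_d = config.ta_mean_c + shape + ar

    wet = rng.random(n) < config.rain_prob
    precip = np.where(wet, rng.gamma(1.5, config.rain_mean_mm / 1.5, n), 0.0)
    clearness = np.clip(1.0 - 0.12 * np.abs(rng.normal(0.0, 1.0, n)), 0.3, 1.0)
    clearness = np.clip(np.where(wet, clearness * 0.6, clearness), 0.3, 1.0)

    rso_daily = np.array([solar.daily_clear_sky_mj(config.lat, int(d)) for d in doy])
    rs_d = clearness * rso_daily / 0.0864  # MJ/day -> mean W/m2

    rh_d = np.clip(config.rh_mean_pct - 1.5 * ar + 25.0 * wet
                   + rng.normal(0.0, config.rh_sd_pct, n), 10.0, 98.0)
    wind_d = np.clip(rng.normal(config.wind_mean_ms, config.wind_sd_ms, n), 0.5, None)

    daily = pd.DataFrame({"date": dates.date, "dap": np.arange(n), "doy": doy,
                          "ta_c": ta_d, "rh_pct": rh_d, "rs_wm2": rs_d,
                          "wind_ms": wind_d, "wind_height_m": 2.0,
                          "precip_mm": precip, "clearness": clearness})

    offsets = np.arange(-config.noon_window_h, config.noon_window_h + 0.5, 1.0)
    hrows = []
    for i in range(n):
        noon = solar.solar_noon_hour(config.lon, int(doy[i]), config.tz_meridian)
        for off in offsets:
            h = noon + off
            diurnal = np.cos(np.pi * (h - 14.5) / 12.0)
            ta_h = ta_d[i] + config.diurnal_amp_c * diurnal
            rh_h = float(np.clip(rh_d[i] - 12.0 * diurnal, 0.0, 100.0))
            rs_h = clearness[i] * solar.clear_sky_wm2(
                config.lat, config.lon, int(doy[i]), h, config.tz_meridian)
            wind_h = float(np.clip(wind_d[i] + rng.normal(0.0, 0.4), 0.3, None))
            ts = pd.Timestamp(dates[i]) + pd.to_timedelta(h, unit="h")
            hrows.append({"timestamp": ts.round("s"), "date": dates[i].date(),
                          "ta_c": ta_h, "rh_pct": rh_h, "rs_wm2": rs_h,
                          "wind_ms": wind_h, "wind_height_m": 2.0,
                          "precip_mm": 0.0, "clearness": clearness[i]})
    return daily, pd.DataFrame(hrows)


def record_at_solar_noon(hourly: pd.DataFrame, day: date_type,
                         lon: float, tz_meridian: float) -> MetRecord:
    """The hourly weather record nearest solar noon on a date."""
    sub = hourly[hourly["date"] == day]
    if sub.empty:
        raise MissingWeatherError(f"no hourly weather for {day}")
    noon = solar.solar_noon_hour(lon, pd.Timestamp(day).dayofyear, tz_meridian)
    hours = sub["timestamp"].dt.hour + sub["timestamp"].dt.minute / 60.0 \
        + sub["timestamp"].dt.second / 3600.0
    row = sub.iloc[int(np.argmin(np.abs(hours.to_numpy() - noon)))]
    return MetRecord(ta_c=float(row.ta_c), rh_pct=float(row.rh_pct),
                     rs_wm2=float(row.rs_wm2), wind_ms=float(row.wind_ms),
                     wind_height_m=float(row.wind_height_m),
                     precip_mm=float(row.precip_mm),
                     timestamp=row.timestamp.to_pydatetime())


def simulate_truth(layout: FieldLayout, daily: pd.DataFrame,
                   profile: SoilProfile, kc: KcCurve, seed: int,
                   fc_max: float = 0.92, fc_rate: float = 0.10,
                   fc_t50_dap: float = 45.0) -> tuple[pd.DataFrame, dict, dict]:
    """Ground-truth stress and cover per (plot, day).

    Runs the water balance once per treatment under its ET-replacement
    schedule (rain credited week by week), then assigns each plot its
    treatment trajectory plus a small seeded plot-level jitter on the
    logistic canopy-growth curve. Returns ``(truth, schedules, balances)``
    keyed by treatment fraction.
    """
    rng = np.random.default_rng(seed)
    dap = daily["dap"].to_numpy()
    eto = eto_hargreaves(daily["ta_c"].to_numpy(), daily["rs_wm2"].to_numpy())
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        etc = kc_at(dap.astype(float), kc) * eto
    n_weeks = len(dap) // 7
    etc_weekly = [float(etc[7 * w:7 * (w + 1)].sum()) for w in range(n_weeks)]
    rain = daily["precip_mm"].to_numpy()
    rain_weekly = [float(rain[7 * w:7 * (w + 1)].sum()) for w in range(n_weeks)]

    schedules, balances = {}, {}
    for trt in sorted({float(t) for t in layout.plots.treatment}):
        schedules[trt] = et_replacement_schedule(etc_weekly, trt, rain_weekly)
        balances[trt] = run_water_balance(daily, schedules[trt], profile, kc)

    rows = []
    for _, p in layout.plots.sort_values("plot").iterrows():
        t50 = fc_t50_dap + rng.normal(0.0, 1.5)
        fmax = float(np.clip(fc_max + rng.normal(0.0, 0.015), 0.5, 0.98))
        fc = fmax / (1.0 + np.exp(-fc_rate * (dap - t50)))
        bal = balances[float(p["treatment"])]
        for i in range(len(dap)):
            rows.append({"plot": int(p["plot"]), "treatment": float(p["treatment"]),
                         "date": daily["date"].iloc[i], "dap": int(dap[i]),
                         "fc": float(fc[i]), "ks": float(bal["ks"].iloc[i]),
                         "wdi_true": float(bal["wdi_sim"].iloc[i]),
                         "irrigation_mm": float(bal["irrigation_mm"].iloc[i]),
                         "precip_mm": float(bal["precip_mm"].iloc[i])})
    return pd.DataFrame(rows), schedules, balances


def synthesize_sensor_pass(truth: pd.DataFrame, layout: FieldLayout,
                           hourly: pd.DataFrame, day: date_type,
                           noise: NoiseConfig, seed: int,
                           calibration: FcCalibration = COTTON_PIVOT_PRESET,
                           params: SurfaceParams | None = None,
                           window_h: float = 2.0,
                           interval_s: float = 30.0) -> pd.DataFrame:
    """One noisy 30-second sensor pass across all 12 slices near solar noon.

    The pass uses the weather record nearest solar noon for the whole
    traverse (conditions are treated as steady over the pass, which makes
    the zero-noise pass exactly invertible by the pipeline).
    """
    noise.validate()
    params = params or SurfaceParams()
    rng = np.random.default_rng(seed)
    sub = truth[truth["date"] == day].set_index("plot")
    if sub.empty:
        raise ValidationError(f"no truth rows for {day}")
    rec = record_at_solar_noon(hourly, day, layout.lon, layout.tz_meridian)
    clearness = met_mod.clearness_from_record(rec, layout.lat, layout.lon,
                                              layout.tz_meridian)
    p_atm = met_mod.pressure_at_elevation(layout.elevation_m)
    corners, _ = corners_from_record(rec, params, p_atm, clearness)

    n = int(round(2.0 * window_h * 3600.0 / interval_s))
    noon = solar.solar_noon_hour(layout.lon, pd.Timestamp(day).dayofyear,
                                 layout.tz_meridian)
    t0 = pd.Timestamp(day) + pd.to_timedelta(noon - window_h, unit="h")
    rows = []
    for i in range(n):
        angle = 180.0 * (i + 0.5) / n
        plot = layout.plot_at(angle)
        fc = float(sub.loc[plot, "fc"])
        wdi_true = float(sub.loc[plot, "wdi_true"])
        lower, upper = temperature_limits(corners, fc)
        ts_c = (rec.ta_c + lower + wdi_true * (upper - lower)
                + noise.soil_bias_ts_c * (1.0 - fc)
                + (rng.normal(0.0, noise.sigma_ts_c) if noise.sigma_ts_c else 0.0))
        ndvi = ((fc - calibration.intercept) / calibration.slope
                + (rng.normal(0.0, noise.sigma_ndvi) if noise.sigma_ndvi else 0.0))
        rows.append({"timestamp": (t0 + pd.to_timedelta(i * interval_s, unit="s")).round("s"),
                     "date": day, "angle_deg": angle,
                     "radius_m": layout.sensor_radius_m,
                     "ts_c": ts_c, "ndvi": ndvi, "irrigating": False})
    return pd.DataFrame(rows)


def synthesize_canopy_raster(fc: float, shape: tuple[int, int] = (64, 64),
                             seed: int = 0) -> np.ndarray:
    """Two-class reflectance raster with true canopy fraction fc.

    Canopy and soil pixel values are drawn from well-separated
    distributions (gap between 0.38 and 0.62), so thresholding recovers the
    constructed fraction to within one pixel. ``fc`` of exactly 0 or 1
    yields a constant single-class raster (the degenerate input downstream
    thresholding must reject).
    """
    if not 0.0 <= fc <= 1.0:
        raise ValidationError(f"canopy fraction {fc} outside [0, 1]")
    if shape[0] < 10 or shape[1] < 10:
        raise ValidationError(f"raster shape {shape} smaller than 10x10")
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    if fc == 0.0:
        return np.full(shape, 0.16)
    if fc == 1.0:
        return np.full(shape, 0.82)
    n_canopy = int(round(fc * n))
    vals = np.clip(rng.normal(0.16, 0.04, n), 0.02, 0.38)
    idx = rng.permutation(n)[:n_canopy]
    vals[idx] = np.clip(rng.normal(0.82, 0.04, n_canopy), 0.62, 0.98)
    return vals.reshape(shape)


def default_pass_dates(daily: pd.DataFrame, first_dap: int = 35,
                       last_dap: int = 110) -> list[date_type]:
    """Twice-weekly sensor pass dates (3/4-day alternation) over mid-season."""
    dap = daily["dap"].to_numpy()
    dates = daily["date"].to_numpy()
    out, d = [], first_dap
    step = 3
    while d <= min(last_dap, int(dap[-1])):
        out.append(dates[dap == d][0])
        d += step
        step = 7 - step
    return list(out)


@dataclass
class SeasonData:
    """Everything one synthetic season produces."""

    config: SeasonConfig
    layout: FieldLayout
    daily: pd.DataFrame
    hourly: pd.DataFrame
    truth: pd.DataFrame
    schedules: dict
    balances: dict
    readings: pd.DataFrame
    pass_dates: list = field(default_factory=list)


def simulate_season(seed: int, config: SeasonConfig | None = None,
                    noise: NoiseConfig | None = None,
                    profile: SoilProfile | None = None,
                    kc: KcCurve | None = None,
                    params: SurfaceParams | None = None,
                    calibration: FcCalibration = COTTON_PIVOT_PRESET,
                    pass_dates: list | None = None) -> SeasonData:
    """Generate a complete synthetic season (weather, layout, truth, passes)."""
    config = config or SeasonConfig()
    noise = noise if noise is not None else NoiseConfig()
    profile = profile or SoilProfile()
    kc = kc or KcCurve()
    params = params or SurfaceParams()

    daily, hourly = generate_weather(config, seed)
    layout = generate_field_layout(seed + 1, config)
    truth, schedules, balances = simulate_truth(layout, daily, profile, kc, seed + 2)
    if pass_dates is None:
        pass_dates = default_pass_dates(daily)
    passes = [synthesize_sensor_pass(truth, layout, hourly, d, noise,
                                     seed + 1000 + i, calibration, params)
              for i, d in enumerate(pass_dates)]
    readings = pd.concat(passes, ignore_index=True) if passes else pd.DataFrame()
    return SeasonData(config, layout, daily, hourly, truth, schedules,
                      balances, readings, pass_dates)
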