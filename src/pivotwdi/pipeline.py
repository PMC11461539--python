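"""End-to-end sensor pipeline: plot assignment, filtering, aggregation, WDI,
seasonal summaries, and model-comparison statistics.

The flow mirrors field practice: geolocated 30-second sensor records are
assigned to pie-slice plots by bearing, filtered to a window around solar
noon (and by irrigation status depending on operating mode), averaged per
plot pass, and converted to a Water Deficit Index with weather taken at
pass time. Sensor WDI series are compared against water-balance-simulated
WDI with R^2, Willmott's index of agreement, and percent RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import met as met_mod
from . import solar
from .canopy import COTTON_PIVOT_PRESET, FcCalibration, ndvi_to_fc
from .errors import ValidationError
from .synth import FieldLayout, record_at_solar_noon
from .trapezoid import SurfaceParams, corners_from_record, temperature_limits, wdi


@dataclass(frozen=True)
class FilterRules:
    """Record-level filtering policy.

    ``noon_window_h``: keep records within this many hours of solar noon
    (None disables). ``irrigation_policy``: "exclude_irrigating" for
    research-style dry runs, "require_irrigating" for production fields
    where only in-water passes are valid, None to keep all.
    """

    noon_window_h: float | None = 2.0
    irrigation_policy: str | None = "exclude_irrigating"


@dataclass(frozen=True)
class ComparisonStats:
    """Model-performance statistics for paired WDI series."""

    r_squared: float
    d_index: float
    rmse_pct: float
    n: int


def assign_readings(readings: pd.DataFrame, layout: FieldLayout,
                    radius_tol_m: float = 5.0) -> tuple[pd.DataFrame, dict]:
    """Label each reading with its plot/treatment by bearing from the pivot.

    Readings outside the cropped half circle [0, 180), outside the sensor
    radius band, or with unreadable positions are dropped and counted.
    Returns ``(labeled, counts)`` with counts keyed by drop reason;
    input count == assigned + dropped exactly.
    """
    plots = layout.plots.sort_values("theta_start").reset_index(drop=True)
    starts = plots["theta_start"].to_numpy()
    angle = readings["angle_deg"].to_numpy(dtype=float)
    radius = (readings["radius_m"].to_numpy(dtype=float)
              if "radius_m" in readings.columns
              else np.full(len(readings), layout.sensor_radius_m))

    bad_pos = ~np.isfinite(angle)
    outside_arc = ~bad_pos & ((angle < 0.0) | (angle >= 180.0))
    outside_radius = (~bad_pos & ~outside_arc
                      & (np.abs(radius - layout.sensor_radius_m) > radius_tol_m))
    keep = ~(bad_pos | outside_arc | outside_radius)

    idx = np.searchsorted(starts, angle[keep], side="right") - 1
    in_slice = angle[keep] < plots["theta_end"].to_numpy()[idx]
    # contiguous slices partition the half circle, so in_slice is all-true there
    labeled = readings.loc[keep].iloc[np.flatnonzero(in_slice)].copy()
    sel = idx[in_slice]
    labeled["plot"] = plots["plot"].to_numpy()[sel]
    labeled["block"] = plots["block"].to_numpy()[sel]
    labeled["treatment"] = plots["treatment"].to_numpy()[sel]
    counts = {"input": int(len(readings)),
              "assigned": int(len(labeled)),
              "dropped_unreadable_position": int(bad_pos.sum()),
              "dropped_outside_half_circle": int(outside_arc.sum()),
              "dropped_outside_radius_band": int(outside_radius.sum()),
              "dropped_no_slice": int((~in_slice).sum())}
    return labeled, counts


def _noon_offset_hours(ts: pd.Series, lon: float, tz_meridian: float) -> np.ndarray:
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    doy = ts.dt.dayofyear
    noon = np.array([solar.solar_noon_hour(lon, int(d), tz_meridian) for d in doy])
    return hours.to_numpy() - noon


def filter_readings(labeled: pd.DataFrame, rules: FilterRules,
                    layout: FieldLayout) -> tuple[pd.DataFrame, dict]:
    """Apply the solar-noon window and irrigation-status policy."""
    out = labeled.copy()
    out["noon_offset_h"] = _noon_offset_hours(pd.to_datetime(out["timestamp"]),
                                              layout.lon, layout.tz_meridian)
    counts = {"input": int(len(out))}
    if rules.noon_window_h is not None:
        ok = np.abs(out["noon_offset_h"].to_numpy()) <= rules.noon_window_h
        counts["removed_outside_noon_window"] = int((~ok).sum())
        out = out.loc[ok]
    if rules.irrigation_policy == "exclude_irrigating":
        ok = ~out["irrigating"].to_numpy(dtype=bool)
        counts["removed_irrigating"] = int((~ok).sum())
        out = out.loc[ok]
    elif rules.irrigation_policy == "require_irrigating":
        ok = out["irrigating"].to_numpy(dtype=bool)
        counts["removed_not_irrigating"] = int((~ok).sum())
        out = out.loc[ok]
    elif rules.irrigation_policy is not None:
        raise ValidationError(f"unknown irrigation policy {rules.irrigation_policy!r}")
    counts["kept"] = int(len(out))
    if len(out) == 0:
        import warnings
        warnings.warn("all readings filtered out; empty result", stacklevel=2)
    return out, counts


def aggregate_plot_observations(filtered: pd.DataFrame,
                                layout: FieldLayout) -> pd.DataFrame:
    """Per (plot, date) pass means of surface temperature and NDVI."""
    if filtered.empty:
        return pd.DataFrame(columns=["plot", "treatment", "date", "ts_c", "ndvi",
                                     "n", "noon_offset_h"])
    if "noon_offset_h" not in filtered.columns:
        filtered = filtered.copy()
        filtered["noon_offset_h"] = _noon_offset_hours(
            pd.to_datetime(filtered["timestamp"]), layout.lon, layout.tz_meridian)
    grouped = (filtered.groupby(["plot", "date"], sort=True)
               .agg(ts_c=("ts_c", "mean"), ndvi=("ndvi", "mean"),
                    n=("ts_c", "size"), noon_offset_h=("noon_offset_h", "mean"))
               .reset_index())
    trt = layout.plots.set_index("plot")["treatment"]
    grouped.insert(1, "treatment", grouped["plot"].map(trt))
    return grouped


def compute_field_wdi(observations: pd.DataFrame, hourly: pd.DataFrame,
                      layout: FieldLayout,
                      calibration: FcCalibration = COTTON_PIVOT_PRESET,
                      params: SurfaceParams | None = None,
                      assume_full_cover: bool = False,
                      clamp: bool = True) -> pd.DataFrame:
    """WDI per plot observation, with weather taken at pass time.

    For each observation date, the hourly record nearest solar noon sets the
    meteorological state; Fc comes from the NDVI calibration (or is forced
    to 1 for a ground station staring straight at the canopy).
    """
    params = params or SurfaceParams()
    p_atm = met_mod.pressure_at_elevation(layout.elevation_m)
    rows = []
    for day, obs_day in observations.groupby("date", sort=True):
        rec = record_at_solar_noon(hourly, day, layout.lon, layout.tz_meridian)
        clearness = met_mod.clearness_from_record(rec, layout.lat, layout.lon,
                                                  layout.tz_meridian)
        corners, _ = corners_from_record(rec, params, p_atm, clearness)
        for _, o in obs_day.iterrows():
            if assume_full_cover:
                fc, fc_clamped = 1.0, False
            else:
                fc, fc_clamped = ndvi_to_fc(float(o.ndvi), calibration)
            lower, upper = temperature_limits(corners, fc)
            dt_meas = float(o.ts_c) - rec.ta_c
            res = wdi(dt_meas, lower, upper, clamp=clamp, fc=fc,
                      label=f"plot {int(o['plot'])} on {day}")
            rows.append({"plot": int(o["plot"]), "treatment": float(o.treatment),
                         "date": day, "n": int(o.n),
                         "dt_measured": dt_meas, "ndvi": float(o.ndvi),
                         "fc": fc, "fc_clamped": fc_clamped,
                         "dt_lower": lower, "dt_upper": upper,
                         "wdi": res.wdi, "clamped": res.clamped})
    return (pd.DataFrame(rows)
            .sort_values(["plot", "date"]).reset_index(drop=True))


def per_plot_seasonal(wdi_results: pd.DataFrame) -> pd.DataFrame:
    """Seasonal mean WDI per plot (observation dates weighted equally)."""
    return (wdi_results.groupby(["plot", "treatment"], sort=True)["wdi"]
            .agg(["mean", "size"]).reset_index()
            .rename(columns={"mean": "wdi_mean", "size": "n_dates"}))


def seasonal_summary(wdi_results: pd.DataFrame) -> pd.DataFrame:
    """Seasonal mean WDI per treatment over all plot-dates."""
    if wdi_results.empty:
        raise ValidationError("no WDI results to summarize")
    return (wdi_results.groupby("treatment", sort=True)["wdi"]
            .agg(["mean", "size"]).reset_index()
            .rename(columns={"mean": "wdi_mean", "size": "n_plot_dates"}))


def compare_models(observed, predicted) -> ComparisonStats:
    """R^2, Willmott d-index, and percent RMSE for paired WDI series.

    R^2 is the squared Pearson correlation of the paired series; the
    d-index is 1 - sum((P-O)^2) / sum((|P-Obar| + |O-Obar|)^2); percent
    RMSE is 100*RMSE/mean(O). Undefined statistics (zero variance, zero
    observed mean) are reported as NaN rather than raised.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValidationError("need paired 1-D series of length >= 2")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValidationError("non-finite values in comparison series")

    if np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
        r2 = float("nan")
    else:
        r2 = float(stats.linregress(obs, pred).rvalue ** 2)

    obar = obs.mean()
    denom = float(np.sum((np.abs(pred - obar) + np.abs(obs - obar)) ** 2))
    d = 1.0 - float(np.sum((pred - obs) ** 2)) / denom if denom > 0 else float("nan")

    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    rmse_pct = 100.0 * rmse / obar if obar != 0.0 else float("nan")
    return ComparisonStats(r_squared=r2, d_index=d, rmse_pct=rmse_pct, n=int(obs.size))
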