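"""Delimited-text readers and writers for every pipeline artifact.

All tabular formats are comma-separated with headers; layout and
calibration files are flat YAML. Weather files may carry shortwave as
``rs_wm2`` (flux, W m^-2) or ``rs_mj_day`` (daily total, MJ m^-2 day^-1);
the reader converts to W m^-2 and records the source dialect in
``df.attrs["rs_dialect"]``. Unknown columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .canopy import FcCalibration
from .errors import ValidationError
from .synth import FieldLayout

_WEATHER_REQUIRED = ("ta_c", "rh_pct", "wind_ms", "precip_mm")
MJ_DAY_TO_WM2 = 1.0 / 0.0864


def read_weather(path) -> pd.DataFrame:
    """Read a weather table (daily or hourly) and normalise radiation units."""
    df = pd.read_csv(path)
    missing = [c for c in _WEATHER_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"weather file {path} missing columns {missing}")
    if "rs_wm2" in df.columns:
        df.attrs["rs_dialect"] = "rs_wm2"
    elif "rs_mj_day" in df.columns:
        df["rs_wm2"] = df["rs_mj_day"] * MJ_DAY_TO_WM2
        df.attrs["rs_dialect"] = "rs_mj_day"
    else:
        raise ValidationError(f"weather file {path} has neither rs_wm2 nor rs_mj_day")
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    elif "timestamp" in df.columns:
        df["date"] = df["timestamp"].dt.date
    if "wind_height_m" not in df.columns:
        df["wind_height_m"] = 2.0
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_sensor_log(path) -> pd.DataFrame:
    """Read a geolocated sensor log (timestamp, angle_deg, radius_m, ts_c, ndvi, irrigating)."""
    df = pd.read_csv(path)
    required = ("timestamp", "angle_deg", "ts_c", "ndvi")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"sensor log {path} missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "date" not in df.columns:
        df["date"] = df["timestamp"].dt.date
    else:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    if "irrigating" not in df.columns:
        df["irrigating"] = False
    return df


def write_sensor_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_layout(layout: FieldLayout, path) -> None:
    doc = {"sensor_radius_m": layout.sensor_radius_m, "lat": layout.lat,
           "lon": layout.lon, "tz_meridian": layout.tz_meridian,
           "elevation_m": layout.elevation_m,
           "plots": layout.plots.to_dict(orient="records")}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path) -> FieldLayout:
    doc = yaml.safe_load(Path(path).read_text())
    plots = pd.DataFrame(doc["plots"])
    return FieldLayout(plots=plots, sensor_radius_m=doc["sensor_radius_m"],
                       lat=doc["lat"], lon=doc["lon"],
                       tz_meridian=doc["tz_meridian"],
                       elevation_m=doc["elevation_m"])


def write_calibration(calib: FcCalibration, path) -> None:
    doc = {"slope": calib.slope, "intercept": calib.intercept,
           "ndvi_min": calib.ndvi_range[0], "ndvi_max": calib.ndvi_range[1],
           "n_points": calib.n_points, "r_squared": calib.r_squared}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_calibration(path) -> FcCalibration:
    doc = yaml.safe_load(Path(path).read_text())
    return FcCalibration(slope=float(doc["slope"]), intercept=float(doc["intercept"]),
                         ndvi_range=(float(doc.get("ndvi_min", float("-inf"))),
                                     float(doc.get("ndvi_max", float("inf")))),
                         n_points=int(doc.get("n_points", 0)),
                         r_squared=float(doc.get("r_squared", float("nan"))))


def read_calibration_pairs(path) -> list[tuple[float, float]]:
    """Two-column (ndvi, fc) delimited text, header optional."""
    df = pd.read_csv(path)
    if {"ndvi", "fc"}.issubset(df.columns):
        return list(zip(df["ndvi"].astype(float), df["fc"].astype(float)))
    df = pd.read_csv(path, header=None)
    return list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))


def load_config(path) -> dict:
    """Flat key-value configuration file (YAML mapping)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"config file {path} is not a key-value mapping")
    return doc


def write_report(counts: dict, path) -> None:
    """Plain-text run report of every filter and drop count."""
    lines = [f"{k}: {v}" for k, v in counts.items()]
    Path(path).write_text("\n".join(lines) + "\n")
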