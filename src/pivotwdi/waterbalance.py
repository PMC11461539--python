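"""Daily root-zone water balance, stress coefficient Ks, and ET-replacement scheduling.

A single-bucket model of the surface root zone (0-30 cm by default): daily
depletion Dr grows with Ks-reduced crop evapotranspiration and shrinks with
rain and irrigation; inputs beyond field capacity drain to deep percolation
the same day. The stress coefficient follows the standard two-piece form

    Ks = 1                      for Dr <= RAW
    Ks = (TAW - Dr)/(TAW - RAW) for RAW < Dr <= TAW

and the simulated water-stress index is WDI = 1 - Ks, directly comparable
with the sensor-derived index. The scheduler reproduces the percent-ET-
replacement irrigation rule used on the pivot: a weekly dose equal to a
fraction of the previous week's crop ET less rain, split into two equal
applications a few days apart when it exceeds 25 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class SoilProfile:
    """Root-zone water-holding properties (all depths in mm of water).

    ``taw_mm`` is total available water between field capacity and wilting
    point over the root zone; ``p`` the depletion fraction that defines
    readily available water RAW = p*TAW; ``dr0_mm`` the initial depletion.
    """

    taw_mm: float = 40.0
    p: float = 0.65
    root_depth_m: float = 0.30
    dr0_mm: float = 0.0

    @property
    def raw_mm(self) -> float:
        return self.p * self.taw_mm

    def validate(self) -> None:
        if not 0.0 < self.raw_mm < self.taw_mm:
            raise ValidationError(
                f"need 0 < RAW < TAW, got RAW={self.raw_mm}, TAW={self.taw_mm}")
        if not 0.0 <= self.dr0_mm <= self.taw_mm:
            raise ValidationError(f"initial depletion {self.dr0_mm} outside [0, TAW]")


@dataclass(frozen=True)
class KcCurve:
    """Piecewise-linear crop-coefficient curve over days after planting."""

    dap_points: tuple[float, ...] = (0.0, 30.0, 80.0, 135.0, 180.0)
    kc_values: tuple[float, ...] = (0.35, 0.35, 1.15, 1.15, 0.70)

    def validate(self) -> None:
        d = np.asarray(self.dap_points)
        k = np.asarray(self.kc_values)
        if d.size != k.size or d.size < 2:
            raise ValidationError("Kc curve needs matching breakpoints and values")
        if not np.all(np.diff(d) > 0):
            raise ValidationError("Kc breakpoints must be strictly increasing")
        if not np.all(k > 0):
            raise ValidationError("Kc values must be positive")

    @property
    def season_end(self) -> float:
        return float(self.dap_points[-1])


def kc_at(dap, curve: KcCurve):
    """Crop coefficient at a day after planting (scalar or array).

    Beyond the last breakpoint the final value is held, with a warning.
    """
    curve.validate()
    arr = np.asarray(dap, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("days after planting must be >= 0")
    if np.any(arr > curve.season_end):
        warnings.warn(f"dap beyond season end {curve.season_end}; holding final Kc",
                      stacklevel=2)
    out = np.interp(arr, curve.dap_points, curve.kc_values)
    return float(out) if np.isscalar(dap) else out


def eto_hargreaves(ta_c, rs_wm2):
    """Radiation-and-temperature reference ET (mm day^-1).

    ETo = 0.0135*(Ta + 17.8)*Rs_w, with the daily-mean shortwave flux
    converted to equivalent evaporation (Rs_w = Rs * 0.0864 / 2.45 mm).
    Used when no externally measured reference ET is supplied.
    """
    rs_mm = np.asarray(rs_wm2, dtype=float) * 0.0864 / 2.45
    return 0.0135 * (np.asarray(ta_c, dtype=float) + 17.8) * rs_mm


def stress_index(dr_mm: float, profile: SoilProfile) -> tuple[float, float]:
    """Stress coefficient Ks and simulated WDI = 1 - Ks at a depletion level."""
    profile.validate()
    if dr_mm < 0 or dr_mm > profile.taw_mm:
        raise ValidationError(f"depletion {dr_mm} outside [0, TAW={profile.taw_mm}] mm")
    if dr_mm <= profile.raw_mm:
        ks = 1.0
    else:
        ks = (profile.taw_mm - dr_mm) / (profile.taw_mm - profile.raw_mm)
    return ks, 1.0 - ks


def et_replacement_schedule(etc_weekly, fraction: float,
                            precip_weekly=None,
                            split_threshold_mm: float = 25.0,
                            split_gap_days: int = 3,
                            start_day: int = 0) -> list[tuple[int, float]]:
    """Dated irrigation events for a percent-ET-replacement treatment.

    Week ``w`` of crop ET (less rain credited that week, floored at zero)
    prescribes ``fraction`` of the deficit, applied on the first day of the
    following week; a prescription above ``split_threshold_mm`` is split
    into two equal applications ``split_gap_days`` apart. Returns a list of
    (day index, depth mm) events.
    """
    etc = np.asarray(etc_weekly, dtype=float)
    if np.any(etc < 0):
        raise ValidationError("negative weekly crop ET")
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"ET replacement fraction {fraction} outside [0, 1]")
    rain = (np.zeros_like(etc) if precip_weekly is None
            else np.asarray(precip_weekly, dtype=float))
    if rain.shape != etc.shape:
        raise ValidationError("weekly rain series length mismatch")
    events: list[tuple[int, float]] = []
    for w, (e, r) in enumerate(zip(etc, rain)):
        dose = max(0.0, fraction * e - r)
        if dose <= 0.0:
            continue
        day = start_day + 7 * (w + 1)
        if dose > split_threshold_mm:
            events.append((day, dose / 2.0))
            events.append((day + split_gap_days, dose / 2.0))
        else:
            events.append((day, dose))
    return events


def run_water_balance(daily: pd.DataFrame,
                      events: list[tuple[int, float]],
                      profile: SoilProfile,
                      kc: KcCurve,
                      eto_series=None) -> pd.DataFrame:
    """Simulate a season of daily depletion, Ks and simulated WDI.

    ``daily`` must carry contiguous integer ``dap`` plus ``ta_c``,
    ``rs_wm2`` (daily means) and ``precip_mm``. ``eto_series`` optionally
    supplies measured reference ET (mm day^-1, aligned with ``daily``);
    otherwise the built-in radiation-temperature form is used.

    Per day: water inputs first reduce depletion (excess below zero goes to
    deep percolation), Ks is evaluated on the post-input depletion, and the
    Ks-reduced crop ET (capped by the water actually present) deepens it.
    The mass balance sum(P+I) - sum(ETc_adj) - sum(DP) = Dr0 - Dr_final
    closes to rounding error by construction.
    """
    profile.validate()
    kc.validate()
    dap = np.asarray(daily["dap"], dtype=int)
    gaps = np.flatnonzero(np.diff(dap) != 1)
    if gaps.size:
        missing = [f"{dap[i]}->{dap[i + 1]}" for i in gaps]
        raise ValidationError(f"daily series has gaps at dap {missing}")

    irr = np.zeros(len(dap))
    for day, mm in events:
        idx = np.flatnonzero(dap == day)
        if idx.size:
            irr[idx[0]] += mm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kc_vals = kc_at(dap.astype(float), kc)
    eto = (np.asarray(eto_series, dtype=float) if eto_series is not None
           else eto_hargreaves(daily["ta_c"].to_numpy(), daily["rs_wm2"].to_numpy()))
    etc = kc_vals * eto

    rows = []
    dr = profile.dr0_mm
    for i in range(len(dap)):
        p_in = float(daily["precip_mm"].iloc[i])
        supply = p_in + irr[i]
        dr_in = dr - supply
        dp = 0.0
        if dr_in < 0.0:
            dp = -dr_in
            dr_in = 0.0
        ks, wdi_sim = stress_index(dr_in, profile)
        etc_adj = min(ks * etc[i], profile.taw_mm - dr_in)
        dr = dr_in + etc_adj
        rows.append({"dap": int(dap[i]), "dr_mm": dr, "ks": ks, "wdi_sim": wdi_sim,
                     "eto_mm": float(eto[i]), "etc_mm": float(etc[i]),
                     "etc_adj_mm": etc_adj, "irrigation_mm": float(irr[i]),
                     "precip_mm": p_in, "deep_percolation_mm": dp})
    out = pd.DataFrame(rows)
    if "date" in daily.columns:
        out.insert(0, "date", daily["date"].to_numpy())
    return out
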