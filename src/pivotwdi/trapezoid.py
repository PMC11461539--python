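"""The vegetation-index/temperature trapezoid and the Water Deficit Index.

The trapezoid has four theoretical corners, each a surface-minus-air
temperature (Ts - Ta) obtained from a one-layer energy balance: a
well-watered full-cover canopy, a fully stressed full-cover canopy, a
saturated bare soil, and an air-dry bare soil. For a partial canopy with
cover fraction Fc, the wet and dry edges of the trapezoid interpolate
linearly between the vegetation and soil corners, and the WDI is the
normalized position of the measured Ts - Ta between those two edges:
0 = no water stress, 1 = no transpiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import met as met_mod
from .errors import DegenerateTrapezoidError, ValidationError
from .met import MetDerived, MetRecord


@dataclass(frozen=True)
class SurfaceParams:
    """Surface parameters of the four trapezoid corners.

    ``rcp``/``rcx`` are canopy resistances for a well-watered and a fully
    stressed canopy (s m^-1); ``hc`` the assumed season-average canopy
    height (m); ``albedo`` and ``c_g`` are per-corner surface albedos and
    soil-heat-flux fractions in the order (wet vegetation, dry vegetation,
    wet bare soil, dry bare soil). ``printed_dry_vegetation`` switches the
    dry-vegetation corner to use the bare-soil resistance inside the
    canopy-resistance ratio (an inconsistent published form kept for
    comparison); by default the vegetation roughness is used throughout the
    vegetation corners.
    """

    rcp: float = 20.0
    rcx: float = 650.0
    hc: float = 0.90
    albedo: tuple[float, float, float, float] = (0.23, 0.23, 0.16, 0.23)
    c_g: tuple[float, float, float, float] = (0.1, 0.1, 0.3, 0.3)
    zom_soil: float = 0.01
    zov_soil_ratio: float = 0.1
    printed_dry_vegetation: bool = False

    def validate(self) -> None:
        # rcp == rcx is allowed as a degenerate limit (corners collapse)
        if not 0.0 <= self.rcp <= self.rcx:
            raise ValidationError(f"need 0 <= rcp <= rcx, got rcp={self.rcp}, rcx={self.rcx}")
        if self.hc <= 0:
            raise ValidationError(f"canopy height must be positive, got {self.hc}")
        if any(not 0.0 <= a <= 1.0 for a in self.albedo):
            raise ValidationError(f"albedos outside [0, 1]: {self.albedo}")
        if any(not 0.0 <= c < 1.0 for c in self.c_g):
            raise ValidationError(f"soil-heat-flux fractions outside [0, 1): {self.c_g}")


@dataclass(frozen=True)
class TrapezoidCorners:
    """The four theoretical Ts - Ta corner values (degC)."""

    wet_vegetation: float
    dry_vegetation: float
    wet_soil: float
    dry_soil: float


@dataclass
class WdiResult:
    """WDI for one observation: measured Ts - Ta located between the limits."""

    dt_measured: float
    fc: float
    dt_lower: float
    dt_upper: float
    wdi: float
    clamped: bool
    label: str | None = None


def trapezoid_corners(met: MetDerived, params: SurfaceParams) -> TrapezoidCorners:
    """Evaluate the four energy-balance corner temperatures.

    Each full-cover corner has the form
    ra*(Rn-G)/(rho_a*Cp) * X/(Delta+X) - VPD/(Delta+X) with
    X = gamma*(1 + rc/ra); the saturated-soil corner takes rc = 0 and the
    dry-soil corner is the pure radiative term ra2*(Rn-G)/(rho_a*Cp).
    """
    params.validate()
    if met.rn_by_surface is None or met.ra1 is None or met.ra2 is None:
        raise ValidationError("met state lacks surface terms; call add_surface_terms first")
    fields = (met.vpd, met.delta, met.gamma, met.rho_a, met.ra1, met.ra2,
              *met.rn_by_surface, *met.g_by_surface)
    if not all(np.isfinite(v) for v in fields):
        raise ValidationError("non-finite derived meteorology")
    rn, g = met.rn_by_surface, met.g_by_surface
    denom = met.rho_a * met.cp

    x_wet = met.gamma * (1.0 + params.rcp / met.ra1)
    wet_veg = (met.ra1 * (rn[0] - g[0]) / denom * x_wet / (met.delta + x_wet)
               - met.vpd / (met.delta + x_wet))

    ra_ratio = met.ra2 if params.printed_dry_vegetation else met.ra1
    x_dry = met.gamma * (1.0 + params.rcx / ra_ratio)
    dry_veg = (met.ra1 * (rn[1] - g[1]) / denom * x_dry / (met.delta + x_dry)
               - met.vpd / (met.delta + x_dry))

    wet_soil = (met.ra2 * (rn[2] - g[2]) / denom * met.gamma / (met.delta + met.gamma)
                - met.vpd / (met.delta + met.gamma))

    dry_soil = met.ra2 * (rn[3] - g[3]) / denom

    return TrapezoidCorners(wet_veg, dry_veg, wet_soil, dry_soil)


def corners_from_record(rec: MetRecord, params: SurfaceParams,
                        p_atm_kpa: float = 101.3, clearness: float = 1.0,
                        rnl: float | None = None) -> tuple[TrapezoidCorners, MetDerived]:
    """Convenience path from a raw weather record to corner temperatures."""
    met = met_mod.derive_met_state(rec, p_atm_kpa)
    met_mod.add_surface_terms(met, params.albedo, params.c_g, params.hc,
                              params.zom_soil, params.zov_soil_ratio, clearness, rnl)
    return trapezoid_corners(met, params), met


def temperature_limits(corners: TrapezoidCorners, fc: float) -> tuple[float, float]:
    """Fc-weighted wet (lower) and dry (upper) temperature limits (degC)."""
    if not 0.0 <= fc <= 1.0:
        raise ValidationError(f"canopy cover fraction {fc} outside [0, 1]")
    lower = fc * corners.wet_vegetation + (1.0 - fc) * corners.wet_soil
    upper = fc * corners.dry_vegetation + (1.0 - fc) * corners.dry_soil
    return lower, upper


def wdi(dt_measured: float, dt_lower: float, dt_upper: float,
        clamp: bool = True, fc: float = float("nan"),
        label: str | None = None) -> WdiResult:
    """Water Deficit Index: normalized position of measured Ts - Ta.

    Raises :class:`DegenerateTrapezoidError` when the upper limit does not
    strictly exceed the lower. Out-of-trapezoid measurements are clamped to
    [0, 1] and flagged (measurement noise routinely places a reading just
    outside the theoretical envelope).
    """
    if not dt_upper > dt_lower:
        where = f" at {label}" if label else ""
        raise DegenerateTrapezoidError(
            f"upper limit {dt_upper:.4f} <= lower limit {dt_lower:.4f} degC{where}")
    raw = (dt_measured - dt_lower) / (dt_upper - dt_lower)
    clamped = bool(raw < 0.0 or raw > 1.0)
    value = min(1.0, max(0.0, raw)) if clamp else raw
    return WdiResult(dt_measured, fc, dt_lower, dt_upper, value,
                     clamped and clamp, label)


def wind_sensitivity(rec: MetRecord, params: SurfaceParams, dt_measured: float,
                     fc: float, factors: list[float],
                     p_atm_kpa: float = 101.3, clearness: float = 1.0,
                     rnl: float | None = None):
    """Recompute WDI with wind speed scaled by each factor.

    Returns a pandas DataFrame with columns (factor, wdi, pct_change); the
    percent change is relative to the unscaled (factor 1.0) WDI, so the
    factor-1.0 row is exactly zero.
    """
    import pandas as pd

    if any(f <= 0 for f in factors):
        raise ValidationError(f"wind factors must be positive: {factors}")
    work = [1.0] + [f for f in factors if f != 1.0]
    values = {}
    for f in work:
        scaled = MetRecord(rec.ta_c, rec.rh_pct, rec.rs_wm2, rec.wind_ms * f,
                           rec.wind_height_m, rec.precip_mm, rec.timestamp)
        corners, _ = corners_from_record(scaled, params, p_atm_kpa, clearness, rnl)
        lower, upper = temperature_limits(corners, fc)
        values[f] = wdi(dt_measured, lower, upper).wdi
    base = values[1.0]
    rows = [{"factor": f,
             "wdi": values.get(f, base),
             "pct_change": 0.0 if f == 1.0 else
             (100.0 * (values[f] - base) / base if base != 0.0 else float("nan"))}
            for f in factors]
    return pd.DataFrame(rows)
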