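"""FAO-56-style meteorology and aerodynamics feeding the temperature trapezoid.

All thermodynamic quantities follow the FAO-56 closed forms: Tetens saturation
vapor pressure, its temperature slope, the psychrometric constant from surface
pressure, and dry-air density from the ideal-gas law with the 1.01 virtual
temperature factor. The aerodynamic resistance uses the neutral-stability
logarithmic-profile formulation with separate roughness lengths for momentum
and for heat/vapor transfer; no stability corrections are applied.

Units contract: temperatures in degC, pressures in kPa, radiation in W m^-2,
resistances in s m^-1, air density in kg m^-3, Cp in J kg^-1 degC^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .errors import ValidationError
from . import solar

#: Specific heat of dry air at constant pressure, J kg^-1 degC^-1.
CP_AIR = 1013.0

#: Stefan-Boltzmann constant, W m^-2 K^-4.
STEFAN_BOLTZMANN = 5.67e-8

VON_KARMAN = 0.41


@dataclass
class MetRecord:
    """One timestep of raw weather-station output.

    ``wind_height_m`` is the anemometer height; wind is internally corrected
    to the 2 m reference height before any resistance calculation.
    """

    ta_c: float
    rh_pct: float
    rs_wm2: float
    wind_ms: float
    wind_height_m: float = 2.0
    precip_mm: float = 0.0
    timestamp: datetime | None = None

    def validate(self) -> None:
        vals = (self.ta_c, self.rh_pct, self.rs_wm2, self.wind_ms,
                self.wind_height_m, self.precip_mm)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite weather record: {self}")
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValidationError(f"relative humidity {self.rh_pct} outside [0, 100]%")
        if self.rs_wm2 < 0.0:
            raise ValidationError(f"negative shortwave irradiance {self.rs_wm2}")
        if self.wind_ms < 0.0:
            raise ValidationError(f"negative wind speed {self.wind_ms}")
        if self.wind_height_m <= 0.0:
            raise ValidationError(f"non-positive anemometer height {self.wind_height_m}")
        if self.precip_mm < 0.0:
            raise ValidationError(f"negative precipitation {self.precip_mm}")


@dataclass
class RoughnessSpec:
    """Roughness geometry for the log-profile aerodynamic resistance.

    ``zm``/``ze`` are the wind and humidity measurement heights (2 m here),
    ``d`` the zero-plane displacement, ``zom``/``zov`` the roughness lengths
    for momentum and for heat/vapor, ``k`` the von Karman constant.
    """

    d: float
    zom: float
    zov: float
    zm: float = 2.0
    ze: float = 2.0
    k: float = VON_KARMAN
    hc: float | None = None

    def validate(self) -> None:
        if self.zom <= 0 or self.zov <= 0:
            raise ValidationError("roughness lengths must be positive")
        if self.zm <= self.d + self.zom:
            raise ValidationError(
                f"wind measurement height {self.zm} m not above d+Zom = {self.d + self.zom} m")
        if self.ze <= self.d + self.zov:
            raise ValidationError(
                f"humidity measurement height {self.ze} m not above d+Zov = {self.d + self.zov} m")

    @classmethod
    def vegetation(cls, hc: float = 0.90) -> "RoughnessSpec":
        """Canopy roughness from canopy height: d=0.67*hc, Zom=0.123*hc, Zov=0.0123*hc."""
        if hc <= 0:
            raise ValidationError(f"canopy height must be positive, got {hc}")
        return cls(d=0.67 * hc, zom=0.123 * hc, zov=0.0123 * hc, hc=hc)

    @classmethod
    def bare_soil(cls, zom: float = 0.01, zov_ratio: float = 0.1) -> "RoughnessSpec":
        """Bare-soil roughness: d=0, Zom=0.01 m, Zov = zov_ratio*Zom by convention."""
        return cls(d=0.0, zom=zom, zov=zov_ratio * zom, hc=None)


@dataclass
class MetDerived:
    """Derived meteorological state for one timestep.

    Thermodynamic fields are always present; the per-surface radiation terms
    and the two aerodynamic resistances (``ra1`` vegetation, ``ra2`` bare
    soil) are attached by :func:`add_surface_terms` once surface parameters
    are known. The four surfaces are ordered (wet vegetation, dry vegetation,
    wet bare soil, dry bare soil).
    """

    es: float
    ea: float
    vpd: float
    delta: float
    gamma: float
    rho_a: float
    u2: float
    cp: float = CP_AIR
    rn_by_surface: tuple[float, float, float, float] | None = None
    g_by_surface: tuple[float, float, float, float] | None = None
    ra1: float | None = None
    ra2: float | None = None
    clearness: float | None = None
    record: MetRecord | None = field(default=None, repr=False)


def sat_vapor_pressure(ta_c: float) -> float:
    """Saturation vapor pressure (kPa) at air temperature, Tetens form."""
    return 0.6108 * math.exp(17.27 * ta_c / (ta_c + 237.3))


def svp_slope(ta_c: float) -> float:
    """Slope of the saturation vapor pressure curve (kPa degC^-1)."""
    return 4098.0 * sat_vapor_pressure(ta_c) / (ta_c + 237.3) ** 2


def psychrometric_constant(p_atm_kpa: float) -> float:
    """Psychrometric constant gamma = 0.000665 * P (kPa degC^-1)."""
    return 0.000665 * p_atm_kpa


def air_density(ta_c: float, p_atm_kpa: float) -> float:
    """Dry-air density (kg m^-3) with the 1.01 virtual-temperature factor."""
    return p_atm_kpa / (1.01 * (ta_c + 273.0) * 0.287)


def pressure_at_elevation(z_m: float) -> float:
    """Surface pressure (kPa) from elevation, standard-atmosphere profile."""
    return 101.3 * ((293.0 - 0.0065 * z_m) / 293.0) ** 5.26


def wind_to_reference_height(uz_ms: float, z_m: float) -> float:
    """Correct wind speed measured at height z to the 2 m reference height.

    Uses the logarithmic-profile factor 4.87/ln(67.8 z - 5.42) over short
    grass; the factor is 1 at z = 2 m to within 0.1%.
    """
    if uz_ms < 0:
        raise ValidationError(f"negative wind speed {uz_ms}")
    arg = 67.8 * z_m - 5.42
    if z_m <= 0.08 or arg <= 1.0:
        raise ValidationError(f"anemometer height {z_m} m too low for profile correction")
    return uz_ms * 4.87 / math.log(arg)


def aerodynamic_resistance(u2_ms: float, spec: RoughnessSpec) -> float:
    """Aerodynamic resistance r_a (s m^-1) for neutral stability.

    r_a = ln[(Zm-d)/Zom] * ln[(Ze-d)/Zov] / (k^2 * u2); inversely
    proportional to wind speed, undefined in calm air.
    """
    spec.validate()
    if u2_ms <= 0:
        raise ValidationError(f"aerodynamic resistance undefined at wind speed {u2_ms} m/s")
    return (math.log((spec.zm - spec.d) / spec.zom)
            * math.log((spec.ze - spec.d) / spec.zov)
            / (spec.k ** 2 * u2_ms))


def net_longwave(ta_c: float, ea_kpa: float, clearness: float = 1.0) -> float:
    """Net outgoing longwave radiation (W m^-2), hourly-scale formulation.

    Rnl = sigma*Tk^4 * (0.34 - 0.14*sqrt(ea)) * (1.35*f - 0.35), with the
    clear-sky fraction f = Rs/Rso clamped to [0.3, 1.0].
    """
    f = min(1.0, max(0.3, clearness))
    tk = ta_c + 273.16
    emissivity_term = 0.34 - 0.14 * math.sqrt(max(ea_kpa, 0.0))
    return STEFAN_BOLTZMANN * tk ** 4 * emissivity_term * (1.35 * f - 0.35)


def net_radiation(rs_wm2: float, albedo: float, ta_c: float, ea_kpa: float,
                  clearness: float = 1.0, rnl: float | None = None) -> float:
    """Net radiation Rn = (1 - albedo)*Rs - Rnl (W m^-2).

    ``rnl`` overrides the computed net longwave term (``rnl=0`` gives the
    pure shortwave balance, used in unit checks).
    """
    if not 0.0 <= albedo <= 1.0:
        raise ValidationError(f"albedo {albedo} outside [0, 1]")
    if rs_wm2 < 0:
        raise ValidationError(f"negative shortwave irradiance {rs_wm2}")
    if rnl is None:
        rnl = net_longwave(ta_c, ea_kpa, clearness)
    return (1.0 - albedo) * rs_wm2 - rnl


def soil_heat_flux(rn_wm2: float, c_g: float) -> float:
    """Soil heat flux density as a fixed fraction of net radiation, G = cG*Rn."""
    if not 0.0 <= c_g < 1.0:
        raise ValidationError(f"soil heat flux fraction {c_g} outside [0, 1)")
    return c_g * rn_wm2


def derive_met_state(rec: MetRecord, p_atm_kpa: float = 101.3) -> MetDerived:
    """Thermodynamic state (es, ea, VPD, Delta, gamma, rho_a, u2) for one record."""
    rec.validate()
    if not 50.0 < p_atm_kpa < 110.0:
        raise ValidationError(f"implausible surface pressure {p_atm_kpa} kPa")
    es = sat_vapor_pressure(rec.ta_c)
    ea = es * rec.rh_pct / 100.0
    u2 = (rec.wind_ms if rec.wind_height_m == 2.0
          else wind_to_reference_height(rec.wind_ms, rec.wind_height_m))
    return MetDerived(
        es=es,
        ea=ea,
        vpd=es - ea,
        delta=svp_slope(rec.ta_c),
        gamma=psychrometric_constant(p_atm_kpa),
        rho_a=air_density(rec.ta_c, p_atm_kpa),
        u2=u2,
        record=rec,
    )


def add_surface_terms(met: MetDerived,
                      albedo: tuple[float, float, float, float],
                      c_g: tuple[float, float, float, float],
                      hc: float = 0.90,
                      zom_soil: float = 0.01,
                      zov_soil_ratio: float = 0.1,
                      clearness: float = 1.0,
                      rnl: float | None = None) -> MetDerived:
    """Attach per-surface Rn and G and the two aerodynamic resistances.

    Surface order is (wet vegetation, dry vegetation, wet bare soil, dry
    bare soil). Requires a record (for Ta and Rs) on the derived state.
    """
    if met.record is None:
        raise ValidationError("derived state has no underlying weather record")
    rec = met.record
    rn = tuple(net_radiation(rec.rs_wm2, a, rec.ta_c, met.ea, clearness, rnl)
               for a in albedo)
    g = tuple(soil_heat_flux(r, c) for r, c in zip(rn, c_g))
    met.rn_by_surface = rn
    met.g_by_surface = g
    met.ra1 = aerodynamic_resistance(met.u2, RoughnessSpec.vegetation(hc))
    met.ra2 = aerodynamic_resistance(met.u2, RoughnessSpec.bare_soil(zom_soil, zov_soil_ratio))
    met.clearness = clearness
    return met


def clearness_from_record(rec: MetRecord, lat_deg: float, lon_deg: float,
                          tz_meridian_deg: float) -> float:
    """Clear-sky fraction Rs/Rso for a timestamped record, clamped to [0.3, 1.0]."""
    if rec.timestamp is None:
        raise ValidationError("record has no timestamp; cannot locate the sun")
    ts = rec.timestamp
    doy = ts.timetuple().tm_yday
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    rso = solar.clear_sky_wm2(lat_deg, lon_deg, doy, hour, tz_meridian_deg)
    if rso <= 1.0:
        return 0.3
    return min(1.0, max(0.3, rec.rs_wm2 / rso))
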