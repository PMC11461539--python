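"""Solar geometry: declination, equation of time, solar noon, clear-sky radiation.

Standard-meridian local time throughout; no daylight-saving logic. Longitudes
are signed degrees (east positive), so a site in Texas has lon ~ -99.5 and a
Central-Standard-Time meridian of -90.
"""

from __future__ import annotations

import math

SOLAR_CONSTANT_WM2 = 1361.0
CLEAR_SKY_TRANSMISSIVITY = 0.75  # fraction of extraterrestrial reaching ground on a clear day


def declination_rad(doy: int) -> float:
    """Solar declination (radians) for a day of year."""
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def inverse_earth_sun_distance(doy: int) -> float:
    """Relative inverse squared earth-sun distance d_r (dimensionless)."""
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)


def equation_of_time_hours(doy: int) -> float:
    """Seasonal correction between clock noon and solar noon, in hours."""
    b = 2.0 * math.pi * (doy - 81) / 364.0
    return 0.1645 * math.sin(2 * b) - 0.1255 * math.cos(b) - 0.025 * math.sin(b)


def solar_noon_hour(lon_deg: float, doy: int, tz_meridian_deg: float) -> float:
    """Local standard-time hour of solar noon for a site longitude."""
    return 12.0 + (tz_meridian_deg - lon_deg) / 15.0 - equation_of_time_hours(doy)


def cos_zenith(lat_deg: float, lon_deg: float, doy: int, hour: float,
               tz_meridian_deg: float) -> float:
    """Cosine of the solar zenith angle at a local-standard-time hour (can be < 0 at night)."""
    delta = declination_rad(doy)
    phi = math.radians(lat_deg)
    omega = math.pi / 12.0 * (hour - solar_noon_hour(lon_deg, doy, tz_meridian_deg))
    return math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(omega)


def clear_sky_wm2(lat_deg: float, lon_deg: float, doy: int, hour: float,
                  tz_meridian_deg: float) -> float:
    """Instantaneous clear-sky shortwave irradiance (W m^-2); zero at night."""
    mu = cos_zenith(lat_deg, lon_deg, doy, hour, tz_meridian_deg)
    if mu <= 0.0:
        return 0.0
    return CLEAR_SKY_TRANSMISSIVITY * SOLAR_CONSTANT_WM2 * inverse_earth_sun_distance(doy) * mu


def daily_extraterrestrial_mj(lat_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m^-2 day^-1)."""
    delta = declination_rad(doy)
    phi = math.radians(lat_deg)
    x = -math.tan(phi) * math.tan(delta)
    omega_s = math.acos(min(1.0, max(-1.0, x)))
    gsc = 0.0820  # MJ m^-2 min^-1
    dr = inverse_earth_sun_distance(doy)
    return (24.0 * 60.0 / math.pi) * gsc * dr * (
        omega_s * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(omega_s)
    )


def daily_clear_sky_mj(lat_deg: float, doy: int) -> float:
    """Daily clear-sky shortwave total (MJ m^-2 day^-1)."""
    return CLEAR_SKY_TRANSMISSIVITY * daily_extraterrestrial_mj(lat_deg, doy)
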