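"""Solar position, sunrise, and civil-twilight night classification.

Implements the NOAA solar-calculator algorithm (geometric mean longitude and
anomaly, equation of centre, apparent longitude, obliquity with nutation
correction, equation of time), good to well under 0.2 deg of elevation for
the years of interest. Elevations returned are geometric (airless): twilight
definitions refer to the true position of the sun, so night classification
uses the unrefracted elevation, while sunrise/sunset use the conventional
-0.833 deg threshold that folds refraction and the solar radius back in.

All timestamps are naive site-local clock times; the site's fixed UTC offset
converts them to UT internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .site import SiteConfig, to_timestamp

__all__ = [
    "SolarResult",
    "solar_elevation",
    "solar_position",
    "is_night",
    "sunrise_time",
    "hours_from_sunrise",
]

_RAD = math.pi / 180.0


@dataclass(frozen=True)
class SolarResult:
    """Sun position at one site-local instant (degrees)."""

    timestamp: pd.Timestamp
    elevation: float
    azimuth: float


def _julian_day(ts_utc: pd.Timestamp) -> float:
    y, m = ts_utc.year, ts_utc.month
    d = (
        ts_utc.day
        + (ts_utc.hour + ts_utc.minute / 60 + ts_utc.second / 3600 + ts_utc.microsecond / 3.6e9)
        / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_ephemeris(jd: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at Julian day jd."""
    jc = (jd - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqc = (
        math.sin(gmas * _RAD) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gmas * _RAD) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gmas * _RAD) * 0.000289
    )
    stl = gmls + seqc
    omega = 125.04 - 1934.136 * jc
    sal = stl - 0.00569 - 0.00478 * math.sin(omega * _RAD)
    moe = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * math.cos(omega * _RAD)
    decl = math.degrees(math.asin(math.sin(oc * _RAD) * math.sin(sal * _RAD)))
    vary = math.tan(oc / 2 * _RAD) ** 2
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2 * gmls * _RAD)
        - 2 * eeo * math.sin(gmas * _RAD)
        + 4 * eeo * vary * math.sin(gmas * _RAD) * math.cos(2 * gmls * _RAD)
        - 0.5 * vary * vary * math.sin(4 * gmls * _RAD)
        - 1.25 * eeo * eeo * math.sin(2 * gmas * _RAD)
    )
    return decl, eqtime


def solar_position(site: SiteConfig, timestamp) -> SolarResult:
    """Geometric solar elevation and azimuth at a site-local instant."""
    ts = to_timestamp(timestamp)
    ts_utc = ts - pd.Timedelta(hours=site.utc_offset)
    jd = _julian_day(ts_utc)
    decl, eqtime = _sun_ephemeris(jd)

    local_min = ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    tst = (local_min + eqtime + 4.0 * site.longitude - 60.0 * site.utc_offset) % 1440.0
    ha = tst / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0

    lat = site.latitude * _RAD
    d = decl * _RAD
    cos_zen = math.sin(lat) * math.sin(d) + math.cos(lat) * math.cos(d) * math.cos(ha * _RAD)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    elevation = 90.0 - zenith

    sin_zen = math.sin(zenith * _RAD)
    if sin_zen < 1e-9:
        azimuth = 0.0  # sun at zenith: azimuth undefined
    else:
        cos_az = (math.sin(lat) * cos_zen - math.sin(d)) / (math.cos(lat) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.degrees(math.acos(cos_az))
        azimuth = (az + 180.0) % 360.0 if ha > 0 else (540.0 - az) % 360.0
    return SolarResult(timestamp=ts, elevation=elevation, azimuth=azimuth)


def solar_elevation(site: SiteConfig, timestamp) -> float:
    """Geometric solar elevation in degrees at a site-local instant."""
    return solar_position(site, timestamp).elevation


def is_night(site: SiteConfig, timestamp) -> bool:
    """True when the sun is strictly more than ``|twilight_elevation|`` deg
    below the horizon (outside civil twilight, by default below -6 deg)."""
    return solar_elevation(site, timestamp) < site.twilight_elevation


def sunrise_time(site: SiteConfig, date) -> pd.Timestamp | None:
    """Site-local sunrise of the given calendar date.

    Sunrise is the upward crossing of the geometric elevation through
    ``site.sunrise_elevation`` (default -0.833 deg). Returns None during
    polar day/night, which cannot occur at this study's latitude but is
    guarded for generality.
    """
    ts = to_timestamp(date).normalize()
    # Ephemeris evaluated at local solar noon of the date (NOAA convention);
    # the sub-minute drift of declination to actual sunrise is negligible.
    noon_utc = ts + pd.Timedelta(hours=12.0 - site.utc_offset)
    decl, eqtime = _sun_ephemeris(_julian_day(noon_utc))

    lat = site.latitude * _RAD
    d = decl * _RAD
    zen0 = (90.0 - site.sunrise_elevation) * _RAD
    cos_ha = (math.cos(zen0) - math.sin(lat) * math.sin(d)) / (math.cos(lat) * math.cos(d))
    if not -1.0 <= cos_ha <= 1.0:
        return None
    ha_deg = math.degrees(math.acos(cos_ha))
    solar_noon_min = 720.0 - 4.0 * site.longitude + 60.0 * site.utc_offset - eqtime
    sunrise_min = solar_noon_min - 4.0 * ha_deg
    return ts + pd.Timedelta(minutes=sunrise_min)


def hours_from_sunrise(site: SiteConfig, timestamp) -> tuple[float, float]:
    """Signed and absolute hours from the same local date's sunrise."""
    ts = to_timestamp(timestamp)
    sr = sunrise_time(site, ts)
    if sr is None:
        raise ValueError("no sunrise on this date at this latitude")
    delta = (ts - sr).total_seconds() / 3600.0
    return delta, abs(delta)
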