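"""Site configuration and time helpers shared across the pipeline.

All timestamps in data files are site-local clock time (fixed UTC offset,
no daylight saving). Dates are handled at day resolution with fractional
days permitted throughout: the hatch-dating rules work in half-days, so
nothing is ever rounded to whole days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import pandas as pd

__all__ = ["SiteConfig", "DUBAI", "to_timestamp", "timestamp_to_doy", "doy_to_timestamp"]


@dataclass(frozen=True)
class SiteConfig:
    """Study-site constants and analysis conventions.

    latitude, longitude : degrees (north/east positive)
    utc_offset : hours; timestamps in data files are site-local
    incubation_days : length of incubation from clutch initiation to hatch
    laying_interval : days between successive eggs
    twilight_elevation : solar elevation (deg) below which it is "night"
        (civil-twilight convention: sun at least 6 deg below the horizon)
    sunrise_elevation : solar elevation defining sunrise/sunset; the
        conventional -0.833 deg folds in standard refraction and solar radius
    temperature_ceiling : deg C above which predation is never observed
    midday_hour : local clock hour used for "midday" ground temperature
    """

    latitude: float = 24.84
    longitude: float = 55.36
    utc_offset: float = 4.0
    incubation_days: float = 30.0
    laying_interval: float = 1.5
    twilight_elevation: float = -6.0
    sunrise_elevation: float = -0.833
    temperature_ceiling: float = 45.0
    midday_hour: int = 12

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.incubation_days <= 0:
            raise ValueError("incubation_days must be positive")
        if self.laying_interval <= 0:
            raise ValueError("laying_interval must be positive")
        if self.twilight_elevation >= 0:
            raise ValueError("twilight_elevation must be below the horizon")


#: Default site: Al Marmoom desert reserve, Dubai (no DST in the UAE).
DUBAI = SiteConfig()


def to_timestamp(value) -> pd.Timestamp:
    """Coerce a datetime-like or ISO string to a (naive, site-local) Timestamp."""
    ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts


def timestamp_to_doy(ts) -> float:
    """Fractional day of year: Jan 1 00:00 -> 1.0, Jan 1 12:00 -> 1.5."""
    ts = to_timestamp(ts)
    frac = (ts.hour + ts.minute / 60 + ts.second / 3600 + ts.microsecond / 3.6e9) / 24
    return float(ts.dayofyear) + frac


def doy_to_timestamp(year: int, doy: float) -> pd.Timestamp:
    """Inverse of :func:`timestamp_to_doy` for a given calendar year."""
    base = _dt.datetime(year, 1, 1)
    return pd.Timestamp(base) + pd.Timedelta(days=float(doy) - 1.0)
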