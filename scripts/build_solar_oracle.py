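"""Build the frozen solar oracle fixture (tests/data/solar_oracle.json).

Independent ephemeris: sun position from mean longitude/anomaly and the
ecliptic-to-equatorial transform, with the hour angle obtained through
Greenwich mean sidereal time and the sun's right ascension — a different
route than the package's equation-of-time formulation, so agreement is a
genuine cross-check. Sunrise is located by bisection on the elevation
crossing rather than by a closed-form hour-angle formula.

Run once from the repository root:  python scripts/build_solar_oracle.py
"""

from __future__ import annotations

import datetime as dt
import json
import math
import pathlib

LAT, LON, TZ = 24.84, 55.36, 4.0
RAD = math.pi / 180.0


def _days_since_j2000(t_utc: dt.datetime) -> float:
    j2000 = dt.datetime(2000, 1, 1, 12, 0, 0)
    return (t_utc - j2000).total_seconds() / 86400.0


def elevation(local: dt.datetime) -> float:
    """Geometric (airless) solar elevation, degrees, at Dubai local time."""
    t_utc = local - dt.timedelta(hours=TZ)
    n = _days_since_j2000(t_utc)
    L = (280.460 + 0.9856474 * n) % 360.0
    g = (357.528 + 0.9856003 * n) % 360.0
    lam = L + 1.915 * math.sin(g * RAD) + 0.020 * math.sin(2 * g * RAD)
    eps = 23.439 - 0.0000004 * n
    sin_lam = math.sin(lam * RAD)
    ra = math.degrees(math.atan2(math.cos(eps * RAD) * sin_lam, math.cos(lam * RAD)))
    dec = math.degrees(math.asin(math.sin(eps * RAD) * sin_lam))
    gmst_h = (18.697374558 + 24.06570982441908 * n) % 24.0
    lst_deg = (gmst_h * 15.0 + LON) % 360.0
    ha = (lst_deg - ra + 540.0) % 360.0 - 180.0
    sin_el = math.sin(LAT * RAD) * math.sin(dec * RAD) + math.cos(LAT * RAD) * math.cos(
        dec * RAD
    ) * math.cos(ha * RAD)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def sunrise(date: dt.date) -> dt.datetime:
    """Upward -0.833 deg crossing found by bisection between 02:00 and 10:00."""
    lo = dt.datetime.combine(date, dt.time(2, 0))
    hi = dt.datetime.combine(date, dt.time(10, 0))
    assert elevation(lo) < -0.833 < elevation(hi)
    for _ in range(40):
        mid = lo + (hi - lo) / 2
        if elevation(mid) < -0.833:
            lo = mid
        else:
            hi = mid
    return lo + (hi - lo) / 2


SAMPLES = [
    "2018-01-15T07:30",
    "2018-03-20T12:30",
    "2018-06-21T05:45",
    "2018-09-23T18:10",
    "2019-02-10T00:30",
    "2019-05-05T13:00",
    "2019-08-17T20:00",
    "2019-11-30T06:40",
    "2020-03-20T12:30",
    "2020-07-04T03:15",
]


def main() -> None:
    records = []
    for iso in SAMPLES:
        local = dt.datetime.fromisoformat(iso)
        sr = sunrise(local.date())
        records.append(
            {
                "local_time": iso,
                "elevation_deg": round(elevation(local), 3),
                "sunrise_local": sr.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )
    out = pathlib.Path(__file__).resolve().parents[1] / "tests" / "data" / "solar_oracle.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(
        json.dumps({"latitude": LAT, "longitude": LON, "utc_offset": TZ, "samples": records}, indent=2)
        + "\n"
    )
    print(f"wrote {out} ({len(records)} samples)")


if __name__ == "__main__":
    main()
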