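"""Continuous nest recordings: cleaning and predation-time extraction.

An incubated nest holds its temperature well above ambient on cold nights
and below ground temperature on hot days; when incubation ends, the nest
sensor converges to the ambient channel and stays there. Predation time is
therefore the earliest instant from which nest and ambient temperature
agree within a tolerance, persistently, through to the end of the trace —
allowing brief re-warming episodes when a parent briefly returns after the
event. Nests monitored only by a transponder reader fall back to the last
detection of an incubating parent (less precise: parents exchange roughly
hourly).

The tolerances are deliberate constructions: diel ambient swings at the
site exceed 10 deg C, so a 2 deg C convergence band held for 60 minutes is
unambiguous. Cleaning never alters sample values — it only reports a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .site import SiteConfig, to_timestamp, timestamp_to_doy
from .solar_time import is_night

__all__ = [
    "SensorTrace",
    "PredationEvent",
    "UnusableTraceError",
    "NoPredationSignal",
    "clean_trace",
    "detect_incubation_end",
    "to_predation_event",
    "read_trace_csv",
    "events_to_frame",
]

TEMP_BOUNDS = (-10.0, 80.0)     # physically plausible ground/nest temps, deg C
FLATLINE_HOURS = 6.0            # identical readings longer than this = device fault


class UnusableTraceError(RuntimeError):
    """Every sample of the trace is masked."""


class NoPredationSignal(RuntimeError):
    """The trace ends with the nest still incubated (e.g. at hatching)."""


@dataclass
class SensorTrace:
    """Timestamped multichannel recording for one nest.

    ``samples`` columns: timestamp, t_nest, rh_nest, t_ambient, rh_ambient,
    tag_id (missing channels as NaN/None). Timestamps must be strictly
    increasing.
    """

    nest_id: str
    samples: pd.DataFrame
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.samples.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        for col in ("t_nest", "rh_nest", "t_ambient", "rh_ambient", "tag_id"):
            if col not in df.columns:
                df[col] = np.nan
        if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
            raise ValueError(f"{self.nest_id}: timestamps not strictly increasing")
        self.samples = df.reset_index(drop=True)

    @property
    def sampling_interval(self) -> float:
        """Median sampling interval in seconds."""
        dt = self.samples["timestamp"].diff().dropna().dt.total_seconds()
        return float(dt.median())


@dataclass
class PredationEvent:
    nest_id: str
    timestamp: pd.Timestamp
    doy: float
    hour: float
    night: bool
    hourly_temp: float | None
    midday_temp: float | None
    source: str  # temperature | humidity | rfid | field

    def __post_init__(self) -> None:
        self.timestamp = to_timestamp(self.timestamp)
        if not 0 <= self.hour < 24:
            raise ValueError("hour outside [0, 24)")


def _runs(flags: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b)


def clean_trace(
    trace: SensorTrace,
    delta_temp: float = 2.0,
    active_until: pd.Timestamp | None = None,
) -> SensorTrace:
    """Mask device faults and displaced-sensor spans; values are untouched.

    Masks (1) samples outside physical temperature bounds, (2) flat-line
    spans of bit-identical nest readings longer than 6 h, and (3) spans
    where the nest channel tracks ambient within ``delta_temp`` although a
    visit confirmed the nest active through ``active_until`` (the bird had
    pulled the sensor out of the nest). The mask is stored on the returned
    trace; a fully masked trace raises :class:`UnusableTraceError`.
    """
    df = trace.samples
    n = len(df)
    if n == 0:
        raise UnusableTraceError(f"{trace.nest_id}: empty trace")
    mask = np.zeros(n, dtype=bool)
    t_nest = df["t_nest"].to_numpy(dtype=float)
    t_amb = df["t_ambient"].to_numpy(dtype=float)
    ts = df["timestamp"]

    with np.errstate(invalid="ignore"):
        for chan in (t_nest, t_amb):
            bad = (chan < TEMP_BOUNDS[0]) | (chan > TEMP_BOUNDS[1])
            mask |= np.nan_to_num(bad, nan=False).astype(bool)

    # flat-line device faults: runs of identical consecutive nest readings
    same = np.concatenate(([False], np.diff(t_nest) == 0.0))
    for a, b in _runs(same):
        a0 = max(a - 1, 0)  # include the first sample of the constant run
        dur_h = (ts.iloc[b - 1] - ts.iloc[a0]).total_seconds() / 3600.0
        if dur_h > FLATLINE_HOURS:
            mask[a0:b] = True

    # displaced sensor: nest tracks ambient while the nest is known active
    if active_until is not None:
        active_until = to_timestamp(active_until)
        with np.errstate(invalid="ignore"):
            conv = np.abs(t_nest - t_amb) < delta_temp
        conv = np.nan_to_num(conv, nan=False).astype(bool) & (ts <= active_until).to_numpy()
        for a, b in _runs(conv):
            if (ts.iloc[b - 1] - ts.iloc[a]).total_seconds() >= 3600.0:
                mask[a:b] = True

    if mask.all():
        raise UnusableTraceError(f"{trace.nest_id}: every sample masked")
    return SensorTrace(nest_id=trace.nest_id, samples=df, mask=mask)


def detect_incubation_end(
    trace: SensorTrace,
    delta_temp: float = 2.0,
    delta_rh: float = 5.0,
    window_minutes: float = 60.0,
) -> tuple[pd.Timestamp, str]:
    """Timestamp at which incubation ended, and the channel that dated it.

    Temperature route: the earliest time from which |nest - ambient| stays
    within ``delta_temp`` to the end of the trace, where re-warming
    episodes shorter than the persistence window (a parent visiting the
    nest shortly after the event) are ignored. Transponder-only traces
    return the last detection. Raises :class:`NoPredationSignal` when the
    nest is still incubated at the end of the recording.
    """
    df = trace.samples
    mask = trace.mask if trace.mask is not None else np.zeros(len(df), dtype=bool)
    keep = ~mask
    t_nest = df["t_nest"].to_numpy(dtype=float)
    t_amb = df["t_ambient"].to_numpy(dtype=float)
    have_temp = keep & np.isfinite(t_nest) & np.isfinite(t_amb)

    if have_temp.sum() >= 2:
        sub = df.loc[have_temp].copy()
        dev = np.abs(t_nest[have_temp] - t_amb[have_temp]) >= delta_temp
        ts = sub["timestamp"].reset_index(drop=True)
        window = pd.Timedelta(minutes=window_minutes)
        # Humidity corroboration: ambient temperature sits inside the
        # incubation band for hours around summer nights and sweeps through
        # it twice a day in between, collapsing the temperature contrast on
        # a live nest. Nest humidity stays well above outside humidity until
        # incubation truly ends, so wherever both humidity channels exist a
        # nest-minus-ambient humidity gap of at least delta_rh keeps the
        # deviation alive.
        rh = sub["rh_nest"].to_numpy(dtype=float)
        rh_amb = (
            sub["rh_ambient"].to_numpy(dtype=float)
            if "rh_ambient" in sub.columns
            else np.full(len(sub), np.nan)
        )
        with np.errstate(invalid="ignore"):
            dev |= np.nan_to_num(rh - rh_amb >= delta_rh, nan=False)
        # genuine incubation = a deviation run at least one window long;
        # shorter deviations after the collapse are parental re-warming blips
        last_incubation_stop = None
        for a, b in _runs(dev):
            if ts.iloc[b - 1] - ts.iloc[a] >= window:
                last_incubation_stop = b
        if last_incubation_stop is None:
            # never deviated: sensor saw no incubation at all
            raise UnusableTraceError(f"{trace.nest_id}: no incubation signal in trace")
        if last_incubation_stop >= len(ts):
            raise NoPredationSignal(f"{trace.nest_id}: incubated through end of trace")
        if ts.iloc[len(ts) - 1] - ts.iloc[last_incubation_stop] < window:
            raise NoPredationSignal(
                f"{trace.nest_id}: convergence too short to confirm incubation end"
            )
        # Refine to the onset of the abrupt change: the convergence criterion
        # fires only once the nest channel has decayed into the delta band,
        # a few minutes after the parent left. Within the last deviation
        # window, the event is placed just after the last sample still at
        # half the pre-collapse channel gap (temperature or humidity).
        j = last_incubation_stop
        dT = np.abs(t_nest[have_temp] - t_amb[have_temp])
        rh_gap = np.where(np.isfinite(rh - rh_amb), rh - rh_amb, -np.inf)
        w_n = max(2, int(round(window.total_seconds() / max(trace.sampling_interval, 1.0))))
        lo = max(0, j - w_n)
        gap_t = float(np.median(dT[lo:j][np.isfinite(dT[lo:j])])) if np.isfinite(dT[lo:j]).any() else np.inf
        rh_pre = rh_gap[lo:j][np.isfinite(rh_gap[lo:j])]
        gap_rh = float(np.median(rh_pre)) if len(rh_pre) else np.inf
        use_t = np.isfinite(gap_t) and gap_t >= 2.0 * delta_temp
        use_rh = np.isfinite(gap_rh) and gap_rh >= 2.0 * delta_rh
        k = j - 1
        while (
            k > lo
            and (use_t or use_rh)
            and not (
                (use_t and dT[k] >= gap_t / 2.0)
                or (use_rh and rh_gap[k] >= gap_rh / 2.0)
            )
        ):
            k -= 1
        end_time = ts.iloc[min(k + 1, j)]
        return to_timestamp(end_time), "temperature"

    tags = df.loc[keep & df["tag_id"].notna(), "timestamp"]
    if len(tags):
        return to_timestamp(tags.iloc[-1]), "rfid"
    raise UnusableTraceError(f"{trace.nest_id}: no usable channel")


def to_predation_event(
    nest_id: str,
    timestamp,
    site: SiteConfig,
    hourly_table: pd.DataFrame | None = None,
    source: str = "temperature",
) -> PredationEvent:
    """Attach solar and ground-temperature context to a predation time.

    ``hourly_table`` is the long-format hourly ground-temperature summary
    (doy, hour, median, ...); the event gets the median of its (doy, hour)
    cell and the day's midday cell, absent cells yielding absent fields.
    """
    ts = to_timestamp(timestamp)
    doy = timestamp_to_doy(ts)
    hour = ts.hour + ts.minute / 60 + ts.second / 3600

    def _cell(d: int, h: int):
        if hourly_table is None or len(hourly_table) == 0:
            return None
        hit = hourly_table[(hourly_table["doy"] == d) & (hourly_table["hour"] == h)]
        return None if hit.empty else float(hit["median"].iloc[0])

    return PredationEvent(
        nest_id=nest_id,
        timestamp=ts,
        doy=doy,
        hour=hour,
        night=is_night(site, ts),
        hourly_temp=_cell(int(doy), int(hour)),
        midday_temp=_cell(int(doy), site.midday_hour),
        source=source,
    )


def read_trace_csv(path, nest_id: str | None = None) -> SensorTrace:
    """Trace CSV columns: timestamp, t_nest, rh_nest, t_ambient, tag_id."""
    df = pd.read_csv(path)
    nid = nest_id if nest_id is not None else str(df["nest_id"].iloc[0]) if "nest_id" in df else "?"
    return SensorTrace(nest_id=nid, samples=df.drop(columns=["nest_id"], errors="ignore"))


def events_to_frame(events: list[PredationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nest_id": e.nest_id,
                "timestamp": e.timestamp,
                "doy": e.doy,
                "hour": e.hour,
                "night": e.night,
                "hourly_temp": e.hourly_temp,
                "midday_temp": e.midday_temp,
                "source": e.source,
            }
            for e in events
        ]
    )
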