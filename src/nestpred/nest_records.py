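"""Nest life histories: dating rules, fate decision tree, exposure tables.

The unit of the daily-predation analysis is the *exposure day*: one day on
which a nest was under observation and at risk. This module turns dated
nest observations (finding data plus periodic visits, optionally a
sensor-derived end time) into per-nest exposure rows
(exposure_days, event 0/1, midpoint day of year) for the Mayfield
exposure-binomial model, applying the field dating conventions:

* clutch initiation back-dated from clutch size at finding (eggs laid at
  1.5-day intervals) or from egg-floating age for complete clutches;
* expected hatch = initiation + 30 days of incubation;
* hatch date from (in order) continuous data / fresh chicks, eggs-and-
  chicks at a visit (minus 12 h), or the expected hatch date;
* predation date from the sensor when available, otherwise the midpoint
  between last-seen-alive and the fate visit, capped at expected hatch.

Dates are datetime-like at day resolution with fractional days kept
end-to-end (the 12-hour rule demands it); every dating helper also accepts
plain fractional day numbers, which the doc examples use.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .site import SiteConfig, to_timestamp, timestamp_to_doy

__all__ = [
    "Fate",
    "VisitStatus",
    "VisitEvent",
    "NestRecord",
    "InvalidRecordError",
    "estimate_clutch_initiation",
    "expected_hatch_date",
    "assign_fate",
    "estimate_hatch_date",
    "estimate_predation_date",
    "observation_period",
    "build_exposure_table",
    "read_nest_tables",
    "write_exposure_table",
]


class Fate(str, enum.Enum):
    HATCHED = "hatched"
    PREDATED = "predated"
    OTHER_FAILURE = "other_failure"
    UNKNOWN = "unknown"
    EXCLUDED = "excluded"


class VisitStatus(str, enum.Enum):
    """Mutually exclusive nest states recorded at a visit."""

    ACTIVE = "active"                              # incubated clutch present
    EGGS_AND_CHICKS = "eggs_and_chicks"            # hatching in progress
    EMPTY_WITH_HATCH_SIGNS = "empty_with_hatch_signs"  # <=5 mm eggshell pieces
    EMPTY_NO_HATCH_SIGNS = "empty_no_hatch_signs"
    EGG_REMAINS = "egg_remains"                    # predated-egg remains
    PARTIAL_LOSS = "partial_loss"                  # eggs missing, rest abandoned
    CHICKS_NEAR_NEST = "chicks_near_nest"
    OTHER = "other"                                # e.g. trampled, sand-covered


@dataclass
class VisitEvent:
    timestamp: pd.Timestamp
    status: VisitStatus
    eggs: int | None = None
    chicks: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        self.timestamp = to_timestamp(self.timestamp)
        self.status = VisitStatus(self.status)


@dataclass
class NestRecord:
    """One nest's dated life history, from finding to fate."""

    nest_id: str
    found_date: pd.Timestamp
    eggs_at_finding: int
    clutch_complete_at_finding: bool
    float_age_days: float | None = None
    visits: list[VisitEvent] = field(default_factory=list)
    attempt_rank: int | None = None
    parents_seen_with_chicks: bool = False        # hatch evidence (ii)
    found_at_hatching: bool = False               # excluded from analyses
    chicks_fresh_at_final_visit: bool = False     # hatch-dating rule 1b
    sensor_end: pd.Timestamp | None = None        # incubation end from sensors
    sensor_end_is_chicks_leaving: bool = False    # hatch-dating rule 1a
    fate: Fate | None = None
    fate_evidence: str | None = None
    review_flag: bool = False

    def __post_init__(self) -> None:
        self.found_date = to_timestamp(self.found_date)
        if self.sensor_end is not None:
            self.sensor_end = to_timestamp(self.sensor_end)
        if self.eggs_at_finding < 0:
            raise InvalidRecordError(f"{self.nest_id}: negative eggs_at_finding")
        for v in self.visits:
            if v.timestamp < self.found_date:
                raise InvalidRecordError(f"{self.nest_id}: visit before found_date")

    @property
    def final_visit(self) -> VisitEvent | None:
        return self.visits[-1] if self.visits else None

    def last_active_visit(self) -> pd.Timestamp | None:
        """Last visit at which the nest held an incubated clutch."""
        times = [v.timestamp for v in self.visits if v.status is VisitStatus.ACTIVE]
        return max(times) if times else None

    def last_seen_alive(self) -> pd.Timestamp:
        """Last time the nest is known to have been alive (visit or sensor)."""
        t = self.last_active_visit()
        candidates = [self.found_date]
        if t is not None:
            candidates.append(t)
        if self.sensor_end is not None:
            candidates.append(self.sensor_end)
        return max(candidates)


class InvalidRecordError(ValueError):
    """A record violates the life-history invariants."""


def _shift(date, days: float):
    """date + days, for Timestamps and plain fractional day numbers alike."""
    if isinstance(date, (int, float, np.floating)):
        return date + days
    return to_timestamp(date) + pd.Timedelta(days=days)


def _midpoint(a, b):
    if isinstance(a, (int, float, np.floating)):
        return (a + b) / 2.0
    a, b = to_timestamp(a), to_timestamp(b)
    return a + (b - a) / 2


# ---------------------------------------------------------------- dating


def estimate_clutch_initiation(
    found_date,
    eggs_at_finding: int,
    clutch_complete_at_finding: bool,
    float_age_days: float | None = None,
    site: SiteConfig | None = None,
):
    """Date the first egg was laid.

    Found during laying: back-date by the laying interval per additional
    egg, ``found - 1.5 * (eggs - 1)`` days. Found complete: the clutch age
    comes from egg floating and is consumed here as a precomputed input.
    Returns None ("undatable") when a complete clutch has no floating age —
    never a silent default.
    """
    site = site or SiteConfig()
    if eggs_at_finding < 1:
        raise InvalidRecordError("cannot date a clutch with no eggs")
    if clutch_complete_at_finding:
        if float_age_days is None:
            return None
        return _shift(found_date, -float(float_age_days))
    return _shift(found_date, -site.laying_interval * (eggs_at_finding - 1))


def expected_hatch_date(initiation_date, site: SiteConfig | None = None):
    """Clutch initiation plus the incubation period (default 30 days)."""
    site = site or SiteConfig()
    return _shift(initiation_date, site.incubation_days)


# ------------------------------------------------------------------ fate


_HATCH_STATUSES = {
    VisitStatus.CHICKS_NEAR_NEST,
    VisitStatus.EGGS_AND_CHICKS,
    VisitStatus.EMPTY_WITH_HATCH_SIGNS,
}
_PREDATION_STATUSES = {
    VisitStatus.EMPTY_NO_HATCH_SIGNS,
    VisitStatus.EGG_REMAINS,
    VisitStatus.PARTIAL_LOSS,
}


def assign_fate(record: NestRecord) -> tuple[Fate, str | None]:
    """Apply the fate decision tree in fixed priority order.

    Hatched on (i) chicks on/at the nest at the final check, (ii) marked
    parents later guiding chicks, or (iii) small eggshell pieces; predated
    on (a) empty with no hatch signs, (b) predated-egg remains, or
    (c) partial loss followed by abandonment; otherwise other-failure or
    unknown. Nests found at hatching are excluded. Contradictory evidence
    (hatch signs and egg remains) yields fate unknown with a review flag.
    The fate and evidence code are stored on the record and returned.
    """
    if record.found_at_hatching:
        record.fate, record.fate_evidence = Fate.EXCLUDED, "found_at_hatching"
        return record.fate, record.fate_evidence
    if not record.visits and record.sensor_end is None:
        raise InvalidRecordError(f"{record.nest_id}: no visits and no sensor end")

    statuses = {v.status for v in record.visits}
    has_hatch_signs = bool(statuses & _HATCH_STATUSES) or record.parents_seen_with_chicks
    has_predation_signs = bool(statuses & _PREDATION_STATUSES)
    if has_hatch_signs and has_predation_signs:
        record.review_flag = True
        record.fate, record.fate_evidence = Fate.UNKNOWN, "contradictory_evidence"
        return record.fate, record.fate_evidence

    final = record.final_visit
    if final is not None and final.status in (
        VisitStatus.CHICKS_NEAR_NEST,
        VisitStatus.EGGS_AND_CHICKS,
    ):
        record.fate, record.fate_evidence = Fate.HATCHED, "i"
    elif record.parents_seen_with_chicks:
        record.fate, record.fate_evidence = Fate.HATCHED, "ii"
    elif final is not None and final.status is VisitStatus.EMPTY_WITH_HATCH_SIGNS:
        record.fate, record.fate_evidence = Fate.HATCHED, "iii"
    elif final is not None and final.status is VisitStatus.EMPTY_NO_HATCH_SIGNS:
        record.fate, record.fate_evidence = Fate.PREDATED, "a"
    elif final is not None and final.status is VisitStatus.EGG_REMAINS:
        record.fate, record.fate_evidence = Fate.PREDATED, "b"
    elif final is not None and final.status is VisitStatus.PARTIAL_LOSS:
        record.fate, record.fate_evidence = Fate.PREDATED, "c"
    elif final is not None and final.status is VisitStatus.OTHER:
        # distinguishes a known non-predation failure from no information
        record.fate = Fate.OTHER_FAILURE if (final.notes or "").strip() else Fate.UNKNOWN
        record.fate_evidence = None
    else:
        record.fate, record.fate_evidence = Fate.UNKNOWN, None
    return record.fate, record.fate_evidence


# ---------------------------------------------------------- event dating


def estimate_hatch_date(record: NestRecord, site: SiteConfig | None = None):
    """Hatch date for a hatched nest, by the ordered dating rules."""
    site = site or SiteConfig()
    if record.fate is not Fate.HATCHED:
        raise InvalidRecordError(f"{record.nest_id}: hatch date requested for fate {record.fate}")
    # Rule 1: chicks known to have left the nest -> hatched one day earlier.
    if record.sensor_end is not None and record.sensor_end_is_chicks_leaving:
        return _shift(record.sensor_end, -1.0)
    if record.chicks_fresh_at_final_visit and record.final_visit is not None:
        return _shift(record.final_visit.timestamp, -1.0)
    # Rule 2: eggs and chicks together at the visit -> 12 h before it.
    final = record.final_visit
    if final is not None and final.status is VisitStatus.EGGS_AND_CHICKS:
        return _shift(final.timestamp, -0.5)
    # Rule 3: hatch signs only / older chicks / parents later with chicks.
    init = estimate_clutch_initiation(
        record.found_date,
        record.eggs_at_finding,
        record.clutch_complete_at_finding,
        record.float_age_days,
        site,
    )
    if init is None:
        raise InvalidRecordError(f"{record.nest_id}: undatable clutch, cannot place hatch")
    expected = expected_hatch_date(init, site)
    last_active = record.last_active_visit()
    if last_active is not None and expected < last_active:
        return _shift(last_active, 1.0)
    return expected


def estimate_predation_date(last_alive, fate_visit, expected_hatch, sensor_time=None):
    """Predation time: sensor time if known, else interval midpoint rules.

    The midpoint between last-seen-alive and the fate-determination visit,
    capped at the expected hatch date; a nest last seen alive after its
    expected hatch is dated one day after that visit.
    """
    if sensor_time is not None:
        return sensor_time
    if last_alive > fate_visit:
        raise InvalidRecordError("last_alive after fate visit")
    if last_alive > expected_hatch:
        return _shift(last_alive, 1.0)
    mid = _midpoint(last_alive, fate_visit)
    return min(mid, expected_hatch)


def observation_period(record: NestRecord, site: SiteConfig | None = None):
    """(start, end, exposure_days) for which the nest was followed at risk.

    Starts at finding; ends at the estimated hatch or predation date for
    those fates, else at the last time the nest was seen alive. Records
    with non-positive exposure are re-tagged excluded.
    """
    site = site or SiteConfig()
    if record.fate is None:
        assign_fate(record)
    start = record.found_date
    if record.fate is Fate.EXCLUDED:
        return start, start, 0.0
    if record.fate is Fate.HATCHED:
        end = estimate_hatch_date(record, site)
    elif record.fate is Fate.PREDATED:
        init = estimate_clutch_initiation(
            record.found_date,
            record.eggs_at_finding,
            record.clutch_complete_at_finding,
            record.float_age_days,
            site,
        )
        expected = (
            expected_hatch_date(init, site) if init is not None
            else _shift(record.found_date, site.incubation_days)
        )
        final = record.final_visit
        fate_visit = final.timestamp if final is not None else record.last_seen_alive()
        end = estimate_predation_date(
            record.last_seen_alive(), fate_visit, expected, record.sensor_end
        )
    else:  # other failure / unknown: last time seen alive
        end = record.last_seen_alive()
    exposure = (to_timestamp(end) - to_timestamp(start)).total_seconds() / 86400.0
    if exposure <= 0:
        record.fate, record.fate_evidence = Fate.EXCLUDED, "no_observation_period"
        return start, start, 0.0
    return start, end, exposure


# -------------------------------------------------------- exposure table


def build_exposure_table(
    records: list[NestRecord],
    site: SiteConfig | None = None,
    cap_exposure: float | None = None,
    drop_unknown_fate: bool = False,
    first_attempts_only: bool = False,
) -> pd.DataFrame:
    """One exposure row per non-excluded nest.

    Columns: nest_id, start, end, exposure_days, event, midpoint_doy.
    event=1 iff the nest was predated; the event is attributed to the final
    exposure day, which is included in the denominator. Filters mirror the
    sensitivity analyses: ``cap_exposure`` truncates long observation
    periods (e.g. at 30 days), ``drop_unknown_fate`` removes unknown-fate
    nests, ``first_attempts_only`` keeps first nesting attempts (nests with
    no recorded attempt rank count as first attempts).
    """
    site = site or SiteConfig()
    rows = []
    for rec in records:
        if rec.fate is None:
            assign_fate(rec)
        start, end, exposure = observation_period(rec, site)
        if rec.fate is Fate.EXCLUDED or exposure <= 0:
            continue
        if drop_unknown_fate and rec.fate is Fate.UNKNOWN:
            continue
        if first_attempts_only and rec.attempt_rank is not None and rec.attempt_rank > 1:
            continue
        if cap_exposure is not None and exposure > cap_exposure:
            exposure = float(cap_exposure)
            end = _shift(start, exposure)
        mid = _midpoint(start, end)
        rows.append(
            {
                "nest_id": rec.nest_id,
                "start": to_timestamp(start),
                "end": to_timestamp(end),
                "exposure_days": float(exposure),
                "event": int(rec.fate is Fate.PREDATED),
                "midpoint_doy": timestamp_to_doy(mid),
            }
        )
    if not rows:
        raise InvalidRecordError("exposure table is empty after filtering")
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- IO


def read_nest_tables(header_csv, visits_csv) -> list[NestRecord]:
    """Load records from the two-file CSV layout.

    ``header_csv``: nest_id, found_date, eggs_at_finding, clutch_complete,
    float_age_days, attempt_rank (plus optional evidence flag columns).
    ``visits_csv``: nest_id, timestamp, status, eggs, chicks, notes.
    """
    head = pd.read_csv(header_csv)
    visits = pd.read_csv(visits_csv)
    records = []
    for _, h in head.iterrows():
        nid = str(h["nest_id"])
        vs = visits[visits["nest_id"].astype(str) == nid].sort_values("timestamp")
        events = [
            VisitEvent(
                timestamp=r["timestamp"],
                status=VisitStatus(r["status"]),
                eggs=None if pd.isna(r.get("eggs")) else int(r["eggs"]),
                chicks=None if pd.isna(r.get("chicks")) else int(r["chicks"]),
                notes="" if pd.isna(r.get("notes")) else str(r["notes"]),
            )
            for _, r in vs.iterrows()
        ]

        def _flag(col):
            return bool(h[col]) if col in h.index and not pd.isna(h[col]) else False

        records.append(
            NestRecord(
                nest_id=nid,
                found_date=h["found_date"],
                eggs_at_finding=int(h["eggs_at_finding"]),
                clutch_complete_at_finding=bool(h["clutch_complete"]),
                float_age_days=None if pd.isna(h.get("float_age_days")) else float(h["float_age_days"]),
                attempt_rank=None if pd.isna(h.get("attempt_rank")) else int(h["attempt_rank"]),
                visits=events,
                parents_seen_with_chicks=_flag("parents_seen_with_chicks"),
                found_at_hatching=_flag("found_at_hatching"),
                chicks_fresh_at_final_visit=_flag("chicks_fresh_at_final_visit"),
                sensor_end=None if pd.isna(h.get("sensor_end")) else to_timestamp(h["sensor_end"]),
                sensor_end_is_chicks_leaving=_flag("sensor_end_is_chicks_leaving"),
            )
        )
    return records


def write_exposure_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
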