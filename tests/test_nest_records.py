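"""Dating rules, the fate decision tree, and exposure-table construction."""

import numpy as np
import pandas as pd
import pytest

from conftest import mk
from nestpred.nest_records import (
    Fate,
    InvalidRecordError,
    NestRecord,
    VisitEvent,
    VisitStatus,
    assign_fate,
    build_exposure_table,
    estimate_clutch_initiation,
    estimate_hatch_date,
    estimate_predation_date,
    expected_hatch_date,
    observation_period,
    read_nest_tables,
)
from nestpred.site import SiteConfig, timestamp_to_doy


# ----------------------------------------------------------- clutch dating


@pytest.mark.parametrize(
    "eggs, expected_doy",
    [(3, 97.0), (1, 100.0), (4, 95.5), (2, 98.5)],
)
def test_initiation_backdated_during_laying(eggs, expected_doy):
    # eggs laid at 1.5-day intervals: found - 1.5 * (eggs - 1)
    assert estimate_clutch_initiation(100.0, eggs, False) == expected_doy
    ts = estimate_clutch_initiation(mk(100.0), eggs, False)
    assert timestamp_to_doy(ts) == pytest.approx(expected_doy)


def test_initiation_complete_clutch_uses_float_age():
    assert estimate_clutch_initiation(100.0, 4, True, float_age_days=7.5) == 92.5


def test_initiation_undatable_without_float_age():
    assert estimate_clutch_initiation(100.0, 4, True, float_age_days=None) is None


def test_initiation_requires_at_least_one_egg():
    with pytest.raises(InvalidRecordError):
        estimate_clutch_initiation(100.0, 0, False)


@pytest.mark.parametrize(
    "init, incubation, expected", [(97.0, 30, 127.0), (1.0, 30, 31.0), (10.0, 25, 35.0)]
)
def test_expected_hatch_adds_incubation(init, incubation, expected):
    site = SiteConfig(incubation_days=incubation)
    assert expected_hatch_date(init, site) == expected


# -------------------------------------------------------------------- fate


def _record(final_status, *, notes="", **kwargs):
    visits = [
        VisitEvent(timestamp=mk(105.0), status=VisitStatus.ACTIVE),
        VisitEvent(timestamp=mk(112.0), status=final_status, notes=notes),
    ]
    defaults = dict(
        nest_id="X1",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=5.0,
        visits=visits,
    )
    defaults.update(kwargs)
    return NestRecord(**defaults)


@pytest.mark.parametrize(
    "status, kwargs, fate, code",
    [
        (VisitStatus.CHICKS_NEAR_NEST, {}, Fate.HATCHED, "i"),
        (VisitStatus.EGGS_AND_CHICKS, {}, Fate.HATCHED, "i"),
        (VisitStatus.ACTIVE, {"parents_seen_with_chicks": True}, Fate.HATCHED, "ii"),
        (VisitStatus.EMPTY_WITH_HATCH_SIGNS, {}, Fate.HATCHED, "iii"),
        (VisitStatus.EMPTY_NO_HATCH_SIGNS, {}, Fate.PREDATED, "a"),
        (VisitStatus.EGG_REMAINS, {}, Fate.PREDATED, "b"),
        (VisitStatus.PARTIAL_LOSS, {}, Fate.PREDATED, "c"),
    ],
)
def test_fate_decision_tree(status, kwargs, fate, code):
    rec = _record(status, **kwargs)
    got_fate, got_code = assign_fate(rec)
    assert got_fate is fate
    assert got_code == code


def test_sand_covered_nest_is_unknown():
    rec = _record(VisitStatus.OTHER, notes="")
    assert assign_fate(rec)[0] is Fate.UNKNOWN


def test_noted_other_cause_is_other_failure():
    rec = _record(VisitStatus.OTHER, notes="trampled by camel")
    assert assign_fate(rec)[0] is Fate.OTHER_FAILURE


def test_found_at_hatching_is_excluded():
    rec = _record(VisitStatus.CHICKS_NEAR_NEST, found_at_hatching=True)
    assert assign_fate(rec)[0] is Fate.EXCLUDED


def test_contradictory_evidence_flags_review():
    visits = [
        VisitEvent(timestamp=mk(105.0), status=VisitStatus.EMPTY_WITH_HATCH_SIGNS),
        VisitEvent(timestamp=mk(112.0), status=VisitStatus.EGG_REMAINS),
    ]
    rec = _record(VisitStatus.ACTIVE)
    rec.visits = visits
    fate, code = assign_fate(rec)
    assert fate is Fate.UNKNOWN
    assert rec.review_flag


def test_every_valid_record_gets_exactly_one_fate(rng):
    """Decision-tree totality over randomized final statuses and flags."""
    statuses = list(VisitStatus)
    for _ in range(100):
        rec = _record(
            statuses[rng.integers(len(statuses))],
            notes="x" if rng.random() < 0.5 else "",
            parents_seen_with_chicks=bool(rng.random() < 0.2),
            found_at_hatching=bool(rng.random() < 0.1),
        )
        fate, _ = assign_fate(rec)
        assert fate in Fate


# ------------------------------------------------------------ hatch dating


def test_hatch_one_day_before_chicks_left_via_sensor():
    rec = _record(
        VisitStatus.EMPTY_WITH_HATCH_SIGNS,
        sensor_end=mk(130.0),
        sensor_end_is_chicks_leaving=True,
    )
    assign_fate(rec)
    assert timestamp_to_doy(estimate_hatch_date(rec)) == pytest.approx(129.0)


def test_hatch_12h_before_eggs_and_chicks_visit():
    rec = _record(VisitStatus.ACTIVE)
    rec.visits = [VisitEvent(timestamp=mk(128.5), status=VisitStatus.EGGS_AND_CHICKS)]
    assign_fate(rec)
    assert timestamp_to_doy(estimate_hatch_date(rec)) == pytest.approx(128.0)


def test_hatch_falls_back_to_expected_date():
    rec = _record(VisitStatus.EMPTY_WITH_HATCH_SIGNS)
    assign_fate(rec)
    # initiation = 100 - 5 = 95; expected hatch = 125
    assert timestamp_to_doy(estimate_hatch_date(rec)) == pytest.approx(125.0)


def test_hatch_one_day_after_late_active_visit():
    # expected hatch (127) before the nest was last seen active (129)
    rec = NestRecord(
        nest_id="L1",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=3.0,  # initiation 97, expected hatch 127
        visits=[
            VisitEvent(timestamp=mk(129.0), status=VisitStatus.ACTIVE),
            VisitEvent(timestamp=mk(133.0), status=VisitStatus.EMPTY_WITH_HATCH_SIGNS),
        ],
    )
    assign_fate(rec)
    assert timestamp_to_doy(estimate_hatch_date(rec)) == pytest.approx(130.0)


# -------------------------------------------------------- predation dating


@pytest.mark.parametrize(
    "last_alive, fate_visit, expected_hatch, result",
    [
        (110.0, 116.0, 120.0, 113.0),   # plain midpoint
        (110.0, 130.0, 118.0, 118.0),   # capped at expected hatch
        (121.0, 123.0, 120.0, 122.0),   # seen alive after expected hatch
    ],
)
def test_predation_date_interval_rules(last_alive, fate_visit, expected_hatch, result):
    assert estimate_predation_date(last_alive, fate_visit, expected_hatch) == result


def test_sensor_time_overrides_interval_rules():
    assert estimate_predation_date(110.0, 116.0, 120.0, sensor_time=111.7) == 111.7


def test_predation_date_rejects_inverted_interval():
    with pytest.raises(InvalidRecordError):
        estimate_predation_date(117.0, 116.0, 120.0)


def test_predation_date_monotone_in_fate_visit(rng):
    for _ in range(200):
        last_alive = float(rng.uniform(90, 120))
        hatch = last_alive + float(rng.uniform(0, 25))
        v1 = last_alive + float(rng.uniform(0, 15))
        v2 = v1 + float(rng.uniform(0, 15))
        d1 = estimate_predation_date(last_alive, v1, hatch)
        d2 = estimate_predation_date(last_alive, v2, hatch)
        assert d2 >= d1


# ------------------------------------------------------ observation period


def _three_nest_cohort():
    hatched = NestRecord(
        nest_id="H",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=3.0,  # expected hatch 127
        visits=[
            VisitEvent(timestamp=mk(120.0), status=VisitStatus.ACTIVE),
            VisitEvent(timestamp=mk(128.0), status=VisitStatus.EMPTY_WITH_HATCH_SIGNS),
        ],
    )
    predated = NestRecord(
        nest_id="P",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=1.0,
        visits=[
            VisitEvent(timestamp=mk(110.0), status=VisitStatus.ACTIVE),
            VisitEvent(timestamp=mk(116.0), status=VisitStatus.EMPTY_NO_HATCH_SIGNS),
        ],
    )
    unknown = NestRecord(
        nest_id="U",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=1.0,
        visits=[
            VisitEvent(timestamp=mk(104.0), status=VisitStatus.ACTIVE),
            VisitEvent(timestamp=mk(111.0), status=VisitStatus.OTHER),
        ],
    )
    return [hatched, predated, unknown]


def test_observation_periods_by_fate():
    hatched, predated, unknown = _three_nest_cohort()
    for rec in (hatched, predated, unknown):
        assign_fate(rec)
    assert observation_period(hatched)[2] == pytest.approx(27.0)
    assert observation_period(predated)[2] == pytest.approx(13.0)  # midpoint 113
    assert observation_period(unknown)[2] == pytest.approx(4.0)    # last seen alive


def test_zero_observation_period_becomes_excluded():
    rec = NestRecord(
        nest_id="Z",
        found_date=mk(100.0),
        eggs_at_finding=4,
        clutch_complete_at_finding=True,
        float_age_days=1.0,
        visits=[VisitEvent(timestamp=mk(100.0), status=VisitStatus.OTHER)],
    )
    assign_fate(rec)
    _, _, exposure = observation_period(rec)
    assert exposure == 0.0
    assert rec.fate is Fate.EXCLUDED


def test_exposure_table_sums_and_filters():
    table = build_exposure_table(_three_nest_cohort())
    assert len(table) == 3
    assert table["exposure_days"].sum() == pytest.approx(44.0)
    assert table["event"].sum() == 1

    dropped = build_exposure_table(_three_nest_cohort(), drop_unknown_fate=True)
    assert len(dropped) == 2
    assert dropped["exposure_days"].sum() == pytest.approx(40.0)


def test_exposure_cap_truncates_long_periods():
    hatched = _three_nest_cohort()[0]
    hatched.float_age_days = None  # force no cap interference
    hatched.clutch_complete_at_finding = False
    hatched.eggs_at_finding = 1
    hatched.visits = [
        VisitEvent(timestamp=mk(160.0), status=VisitStatus.ACTIVE),
        VisitEvent(timestamp=mk(167.8), status=VisitStatus.EMPTY_WITH_HATCH_SIGNS),
    ]
    # expected hatch 130 < last active 160 -> hatch 161; 61 d of exposure
    table = build_exposure_table([hatched], cap_exposure=30.0)
    assert table["exposure_days"].iloc[0] == pytest.approx(30.0)
    mid = table["midpoint_doy"].iloc[0]
    assert 100.0 <= mid <= 130.0  # midpoint recomputed inside the capped window


def test_first_attempts_filter():
    nests = _three_nest_cohort()
    nests[1].attempt_rank = 2
    table = build_exposure_table(nests, first_attempts_only=True)
    assert set(table["nest_id"]) == {"H", "U"}


def test_exposure_conservation_and_event_bijection():
    nests = _three_nest_cohort()
    table = build_exposure_table(nests)
    per_nest = {}
    for rec in nests:
        per_nest[rec.nest_id] = observation_period(rec)[2]
    for _, row in table.iterrows():
        assert row["exposure_days"] == pytest.approx(per_nest[row["nest_id"]])
        assert (row["event"] == 1) == (
            next(r for r in nests if r.nest_id == row["nest_id"]).fate is Fate.PREDATED
        )


def test_empty_exposure_table_is_an_error():
    rec = _record(VisitStatus.CHICKS_NEAR_NEST, found_at_hatching=True)
    with pytest.raises(InvalidRecordError):
        build_exposure_table([rec])


def test_csv_round_trip(tmp_path):
    nests = _three_nest_cohort()
    head = pd.DataFrame(
        [
            {
                "nest_id": r.nest_id,
                "found_date": r.found_date.isoformat(),
                "eggs_at_finding": r.eggs_at_finding,
                "clutch_complete": int(r.clutch_complete_at_finding),
                "float_age_days": r.float_age_days,
                "attempt_rank": np.nan,
            }
            for r in nests
        ]
    )
    visits = pd.DataFrame(
        [
            {
                "nest_id": r.nest_id,
                "timestamp": v.timestamp.isoformat(),
                "status": v.status.value,
                "eggs": np.nan,
                "chicks": np.nan,
                "notes": v.notes,
            }
            for r in nests
            for v in r.visits
        ]
    )
    head.to_csv(tmp_path / "head.csv", index=False)
    visits.to_csv(tmp_path / "visits.csv", index=False)
    loaded = read_nest_tables(tmp_path / "head.csv", tmp_path / "visits.csv")
    table = build_exposure_table(loaded)
    assert table["exposure_days"].sum() == pytest.approx(44.0)
    assert table["event"].sum() == 1
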