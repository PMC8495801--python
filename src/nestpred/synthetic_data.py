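"""Synthetic nest cohorts, visit schedules, sensor traces, temperatures.

The generator is the study's statistical world written forward: clutches
initiated across a February-August season, a constant (or seasonally
tilted) daily predation hazard acting from clutch initiation through a
30-day incubation, predation hours drawn from a mixture of a
sunrise-centred von Mises bump over a uniform background with a
season-increasing night share, periodic nest visits that leave the same
evidence codes the fate decision tree consumes, continuous nest/ambient
temperature-humidity traces that collapse to ambient at the true predation
time, and a ground-temperature field with seasonal and diurnal structure
whose summer midday medians exceed 45 deg C. Every draw flows from one
seed and the full ground truth is returned alongside, so recovery tests
can compare pipeline output against what actually happened.

Defaults mirror the study cohort: 444 nests, daily hazard 0.0095, 52%
sensor coverage, visits every few days, 7% unknown-fate and 5%
other-failure nests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .site import SiteConfig, DUBAI, doy_to_timestamp, timestamp_to_doy
from .solar_time import solar_elevation, sunrise_time
from .nest_records import NestRecord, VisitEvent, VisitStatus
from .sensor_timing import SensorTrace

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "generate_temperature_field",
    "generate_cohort",
    "generate_observations",
    "generate_scenario",
    "sample_event_hours",
    "generate_trace",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic season.

    Hazard acts per day on the logit scale:
    logit(p_doy) = logit(daily_hazard) + hazard_doy_slope * (doy - centre).
    The diel density is w * vonMises(sunrise, kappa) + (1-w) * uniform; the
    night share of predation follows
    logit(P(night)) = logit(base_night_share)
                      + night_share_slope * (doy - centre),
    realised by drawing from the diel mixture conditioned on the drawn
    night/day state. Temperature truth is
    T(doy, h) = temp_base + seas_amp * cos(2*pi*(doy - seas_peak_doy)/365)
                + diurnal_amp * cos(2*pi*(h - diurnal_peak_hour)/24)
                + day_noise + sensor noise,
    calibrated so summer midday medians exceed 45 deg C while winter midday
    stays below 35, and midday medians correlate with day of year at about
    the strength seen at the site (r ~ 0.85-0.9; day-to-day weather noise
    keeps the correlation below 1).
    """

    n_nests: int = 444
    year: int = 2019
    season_window: tuple[float, float] = (32.0, 213.0)
    daily_hazard: float = 0.0095
    hazard_doy_slope: float = 0.0
    diel_weight: float = 0.5
    diel_kappa: float = 2.0
    base_night_share: float = 0.48
    night_share_slope: float = 0.03
    ceiling_rule: bool = True
    visit_interval: float = 3.5
    discovery_lag_max: float = 20.0
    sensor_coverage: float = 0.52
    unknown_fate_fraction: float = 0.07
    other_failure_fraction: float = 0.05
    clutch_probs: tuple[tuple[int, float], ...] = ((2, 0.05), (3, 0.25), (4, 0.70))
    sampling_interval_s: float = 60.0
    nest_temp_mean: float = 37.5
    nest_temp_sd: float = 0.7
    nest_rh_mean: float = 70.0
    outside_rh_mean: float = 25.0
    rh_sd: float = 3.0
    collapse_tau_min: float = 2.0
    rewarm_blip_prob: float = 0.3
    temp_base: float = 30.0
    seas_amp: float = 16.0
    seas_peak_doy: float = 201.0
    diurnal_amp: float = 10.0
    diurnal_peak_hour: float = 14.0
    day_noise_sd: float = 4.0
    sensor_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.daily_hazard <= 1.0:
            raise ValueError("daily_hazard outside [0, 1]")
        if not 0.0 <= self.diel_weight <= 1.0:
            raise ValueError("diel_weight outside [0, 1]")
        lo, hi = self.season_window
        if not (1 <= lo < hi <= 366):
            raise ValueError("season window must lie inside the year")


@dataclass
class Scenario:
    """Everything one synthetic season produced."""

    config: ScenarioConfig
    truth: pd.DataFrame
    records: list[NestRecord]
    traces: list[SensorTrace]
    ambient_samples: pd.DataFrame
    temp_truth: "TemperatureTruth"


# ------------------------------------------------------------ temperature


@dataclass(frozen=True)
class TemperatureTruth:
    """Deterministic + per-day weather components of the temperature field."""

    config: ScenarioConfig
    day_offsets: dict[int, float] = field(repr=False, default_factory=dict)

    def deterministic(self, doy, hour):
        c = self.config
        doy = np.asarray(doy, dtype=float)
        hour = np.asarray(hour, dtype=float)
        out = (
            c.temp_base
            + c.seas_amp * np.cos(2 * np.pi * (doy - c.seas_peak_doy) / 365.0)
            + c.diurnal_amp * np.cos(2 * np.pi * (hour - c.diurnal_peak_hour) / 24.0)
        )
        return float(out) if out.ndim == 0 else out

    def true_temp(self, doy, hour):
        """Deterministic component plus that day's weather offset."""
        base = self.deterministic(doy, hour)
        off = np.vectorize(lambda d: self.day_offsets.get(int(d), 0.0))(np.asarray(doy))
        out = base + off
        return float(out) if np.ndim(out) == 0 else out


def _day_offsets(config: ScenarioConfig, rng: np.random.Generator, doy_range) -> dict[int, float]:
    return {int(d): float(rng.normal(0.0, config.day_noise_sd)) for d in doy_range}


def generate_temperature_field(
    config: ScenarioConfig,
    seed: int | None = None,
    n_sensors: int = 3,
    doy_pad: float = 40.0,
) -> tuple[pd.DataFrame, TemperatureTruth]:
    """Hourly ambient samples over the season plus the noiseless truth.

    Emits ``n_sensors`` pooled readings per (doy, hour) cell, as from
    ground loggers next to nests; the returned truth object exposes both
    the deterministic surface and the realised per-day weather offsets for
    oracle tests.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.season_window
    doys = np.arange(int(lo), int(hi + doy_pad) + 1)
    truth = TemperatureTruth(config=config, day_offsets=_day_offsets(config, rng, doys))
    rows = []
    for d in doys:
        for h in range(24):
            t0 = truth.true_temp(d, h)
            for _ in range(n_sensors):
                rows.append((doy_to_timestamp(config.year, d + h / 24.0),
                             t0 + rng.normal(0.0, config.sensor_noise_sd)))
    df = pd.DataFrame(rows, columns=["timestamp", "temperature"])
    return df, truth


# ------------------------------------------------------------ diel hours


def _crossing(site: SiteConfig, date, lo_h: float, hi_h: float, target: float) -> float:
    """Clock hour where solar elevation crosses ``target`` (bisection)."""
    base = pd.Timestamp(date).normalize()

    def elev(h: float) -> float:
        return solar_elevation(site, base + pd.Timedelta(hours=h)) - target

    a, b = lo_h, hi_h
    fa = elev(a)
    for _ in range(36):
        m = (a + b) / 2.0
        fm = elev(m)
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    return (a + b) / 2.0


class _SolarCache:
    """Per-date sunrise hour and civil-twilight night window."""

    def __init__(self, site: SiteConfig, year: int):
        self.site, self.year = site, year
        self._sunrise: dict[int, float] = {}
        self._night: dict[int, tuple[float, float]] = {}

    def sunrise_hour(self, doy: int) -> float:
        if doy not in self._sunrise:
            ts = sunrise_time(self.site, doy_to_timestamp(self.year, doy))
            self._sunrise[doy] = ts.hour + ts.minute / 60 + ts.second / 3600
        return self._sunrise[doy]

    def night_window(self, doy: int) -> tuple[float, float]:
        """(dawn_end, dusk_start): night = hour < dawn_end or hour > dusk_start."""
        if doy not in self._night:
            date = doy_to_timestamp(self.year, doy)
            dawn = _crossing(self.site, date, 0.0, 12.0, self.site.twilight_elevation)
            dusk = _crossing(self.site, date, 12.0, 24.0, self.site.twilight_elevation)
            self._night[doy] = (dawn, dusk)
        return self._night[doy]

    def is_night_hour(self, doy: int, hour: float) -> bool:
        dawn, dusk = self.night_window(doy)
        return hour < dawn or hour > dusk


def sample_event_hours(
    doys: np.ndarray,
    rng: np.random.Generator,
    site: SiteConfig = DUBAI,
    year: int = 2019,
    diel_weight: float = 0.5,
    diel_kappa: float = 2.0,
    base_night_share: float | None = None,
    night_share_slope: float = 0.0,
    season_centre: float | None = None,
    temp_truth: TemperatureTruth | None = None,
    temperature_ceiling: float = 45.0,
    solar_cache: _SolarCache | None = None,
) -> np.ndarray:
    """Predation clock hours for events on the given days of year.

    Hours come from ``w * vonMises(sunrise(doy), kappa) + (1-w) * uniform``;
    if ``base_night_share`` is given, the night/day state is first drawn
    from the seasonal logit and the mixture is sampled conditional on it.
    With a ``temp_truth``, hours whose true ground temperature exceeds the
    ceiling are redrawn (predators do not move in extreme heat).
    """
    doys = np.asarray(doys, dtype=float)
    cache = solar_cache or _SolarCache(site, year)
    centre = float(np.mean(doys)) if season_centre is None else season_centre
    out = np.empty(len(doys))

    def draw_hour(doy_i: int) -> float:
        if rng.random() < diel_weight:
            mu = 2 * np.pi * cache.sunrise_hour(doy_i) / 24.0
            theta = rng.vonmises(mu, diel_kappa)
            return (theta * 24.0 / (2 * np.pi)) % 24.0
        return rng.uniform(0.0, 24.0)

    for i, d in enumerate(doys):
        di = int(d)
        want_night = None
        if base_night_share is not None:
            logit0 = math.log(base_night_share / (1.0 - base_night_share))
            p_night = 1.0 / (1.0 + math.exp(-(logit0 + night_share_slope * (d - centre))))
            want_night = rng.random() < p_night
        for _ in range(200):
            h = draw_hour(di)
            if want_night is not None and cache.is_night_hour(di, h) != want_night:
                continue
            if (
                temp_truth is not None
                and temp_truth.true_temp(di, h) > temperature_ceiling
            ):
                continue
            break
        out[i] = h
    return out


# ---------------------------------------------------------------- cohort


def generate_cohort(
    config: ScenarioConfig,
    seed: int | None = None,
    site: SiteConfig = DUBAI,
    temp_truth: TemperatureTruth | None = None,
) -> pd.DataFrame:
    """True nest histories: initiation, fate, and (for predation) its time.

    Predation is a first-event time from per-day Bernoulli draws — the
    generative mirror of the constant-daily-hazard model the estimator
    assumes — with the hazard optionally tilted over the season on the
    logit scale. Survivors hatch at initiation + 30 days; a configurable
    fraction instead fails for other reasons at a uniform time.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_nests
    lo, hi = config.season_window
    centre = (lo + hi) / 2.0
    init = rng.uniform(lo, hi, size=n)
    sizes, probs = zip(*config.clutch_probs)
    clutch = rng.choice(sizes, size=n, p=np.asarray(probs) / sum(probs))

    inc_days = int(round(site.incubation_days))
    day_idx = np.arange(inc_days)
    doy_mat = np.floor(init)[:, None] + day_idx[None, :]
    if config.daily_hazard <= 0:
        p_mat = np.zeros_like(doy_mat)
    elif config.daily_hazard >= 1:
        p_mat = np.ones_like(doy_mat)
    else:
        logit0 = math.log(config.daily_hazard / (1.0 - config.daily_hazard))
        p_mat = 1.0 / (1.0 + np.exp(-(logit0 + config.hazard_doy_slope * (doy_mat - centre))))
    hit = rng.random((n, inc_days)) < p_mat
    first = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)

    other_t = np.where(
        rng.random(n) < config.other_failure_fraction,
        rng.uniform(0.0, site.incubation_days, size=n),
        np.inf,
    )

    cache = _SolarCache(site, config.year)
    rows = []
    for i in range(n):
        pred_day = first[i]
        pred_time = np.inf if pred_day < 0 else float(pred_day)  # days since initiation
        fate, end_doy, pred_doy, hour, night = "hatched", init[i] + site.incubation_days, np.nan, np.nan, None
        if other_t[i] < min(pred_time + 1.0, site.incubation_days):
            # other failure strikes before that day's predation could be dated
            fate = "other_failure"
            end_doy = init[i] + other_t[i]
        elif pred_day >= 0:
            fate = "predated"
            event_doy = int(np.floor(init[i])) + pred_day
            hour = float(
                sample_event_hours(
                    np.array([event_doy], dtype=float),
                    rng,
                    site=site,
                    year=config.year,
                    diel_weight=config.diel_weight,
                    diel_kappa=config.diel_kappa,
                    base_night_share=config.base_night_share,
                    night_share_slope=config.night_share_slope,
                    season_centre=centre,
                    temp_truth=temp_truth if config.ceiling_rule else None,
                    temperature_ceiling=site.temperature_ceiling,
                    solar_cache=cache,
                )[0]
            )
            pred_doy = event_doy + hour / 24.0
            end_doy = pred_doy
            night = cache.is_night_hour(event_doy, hour)
        rows.append(
            {
                "nest_id": f"N{i + 1:04d}",
                "initiation_doy": float(init[i]),
                "clutch_size": int(clutch[i]),
                "true_fate": fate,
                "true_end_doy": float(end_doy),
                "true_predation_doy": float(pred_doy),
                "true_predation_hour": hour if fate == "predated" else np.nan,
                "true_night": night,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------- observations


def generate_trace(
    nest_id: str,
    start_ts: pd.Timestamp,
    end_ts: pd.Timestamp,
    predation_ts: pd.Timestamp | None,
    config: ScenarioConfig,
    rng: np.random.Generator,
    temp_truth: TemperatureTruth,
    with_rfid: bool = True,
    with_blip: bool | None = None,
) -> SensorTrace:
    """One nest's temperature/humidity/transponder recording.

    The nest channel sits in the incubation band until ``predation_ts``,
    then relaxes exponentially onto the ambient channel; an optional brief
    (< persistence window) re-warming blip a couple of hours later mimics a
    parent returning to the empty nest. Humidity drops to outside levels at
    the event; transponder reads occur at roughly hourly parent exchanges.
    """
    step = pd.Timedelta(seconds=config.sampling_interval_s)
    times = pd.date_range(start_ts, end_ts, freq=step)
    n = len(times)
    doy = times.dayofyear.to_numpy().astype(float)
    hour = (times.hour + times.minute / 60 + times.second / 3600).to_numpy()
    amb = temp_truth.true_temp(doy, hour) + rng.normal(0.0, 0.5, size=n)

    if predation_ts is None:
        incubating = np.ones(n, dtype=bool)
    else:
        incubating = times < predation_ts
    t_nest = np.where(
        incubating, config.nest_temp_mean + rng.normal(0.0, config.nest_temp_sd, size=n), np.nan
    )
    rh = np.where(
        incubating,
        config.nest_rh_mean + rng.normal(0.0, config.rh_sd, size=n),
        config.outside_rh_mean + rng.normal(0.0, config.rh_sd, size=n),
    )
    rh_amb = config.outside_rh_mean + rng.normal(0.0, config.rh_sd, size=n)
    if predation_ts is not None and (~incubating).any():
        after = np.flatnonzero(~incubating)
        dt_min = (times[after] - predation_ts).total_seconds().to_numpy() / 60.0
        gap = config.nest_temp_mean - amb[after[0]]
        t_nest[after] = (
            amb[after] + gap * np.exp(-dt_min / config.collapse_tau_min)
            + rng.normal(0.0, 0.3, size=len(after))
        )
        do_blip = rng.random() < config.rewarm_blip_prob if with_blip is None else with_blip
        if do_blip:
            b0 = predation_ts + pd.Timedelta(hours=float(rng.uniform(1.0, 3.0)))
            b1 = b0 + pd.Timedelta(minutes=float(rng.uniform(10.0, 30.0)))
            in_blip = (times >= b0) & (times < b1)
            t_nest[in_blip] = config.nest_temp_mean + rng.normal(
                0.0, config.nest_temp_sd, size=int(in_blip.sum())
            )

    tag = np.full(n, np.nan)
    if with_rfid:
        t = 0.0
        total_h = (times[-1] - times[0]).total_seconds() / 3600.0
        while t < total_h:
            idx = int(t * 3600.0 / config.sampling_interval_s)
            if idx < n and incubating[idx]:
                tag[idx] = float(rng.integers(1, 3))
            t += rng.exponential(1.0)

    df = pd.DataFrame(
        {
            "timestamp": times,
            "t_nest": t_nest,
            "rh_nest": rh,
            "t_ambient": amb,
            "rh_ambient": rh_amb,
            "tag_id": tag,
        }
    )
    return SensorTrace(nest_id=nest_id, samples=df)


def generate_observations(
    cohort: pd.DataFrame,
    config: ScenarioConfig,
    seed: int | None = None,
    site: SiteConfig = DUBAI,
    temp_truth: TemperatureTruth | None = None,
    include_traces: bool = True,
) -> tuple[list[NestRecord], list[SensorTrace]]:
    """Visit histories (and sensor traces) that a field crew would record.

    Nests are discovered with a lag after initiation (those already lost
    are never found), visited every ``visit_interval`` days, and given a
    final-visit evidence code so the fate decision tree recovers the truth
    except for a configurable unknown-fate fraction whose last visit is
    uninformative. A ``sensor_coverage`` fraction of found nests get
    continuous traces starting at discovery.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    if temp_truth is None:
        temp_truth = TemperatureTruth(config=config)
    records, traces = [], []
    year = config.year

    for _, nest in cohort.iterrows():
        lag = rng.uniform(0.5, config.discovery_lag_max)
        found_doy = nest["initiation_doy"] + lag
        if found_doy >= nest["true_end_doy"]:
            continue  # lost before it could be found
        found_ts = doy_to_timestamp(year, float(np.floor(found_doy)) + rng.uniform(0.33, 0.45))
        found_doy_clock = timestamp_to_doy(found_ts)
        if (
            found_doy_clock >= nest["true_end_doy"]
            or found_doy_clock < nest["initiation_doy"] + 0.2
        ):
            found_ts = doy_to_timestamp(year, found_doy)
        end_ts = doy_to_timestamp(year, float(nest["true_end_doy"]))

        laying_days = site.laying_interval * (nest["clutch_size"] - 1)
        age_at_finding = timestamp_to_doy(found_ts) - nest["initiation_doy"]
        laid = min(int(nest["clutch_size"]), int(np.floor(age_at_finding / site.laying_interval)) + 1)
        complete = age_at_finding >= laying_days
        float_age = float(age_at_finding) if complete else None

        unknown = rng.random() < config.unknown_fate_fraction
        visits = []
        t = found_ts
        while t < end_ts:
            visits.append(VisitEvent(timestamp=t, status=VisitStatus.ACTIVE))
            t = t + pd.Timedelta(days=config.visit_interval + rng.uniform(-0.4, 0.4))
        final_t = t if t > end_ts else end_ts + pd.Timedelta(days=config.visit_interval)
        fate = nest["true_fate"]
        if unknown:
            visits.append(VisitEvent(timestamp=final_t, status=VisitStatus.OTHER, notes=""))
        elif fate == "hatched":
            visits.append(VisitEvent(timestamp=final_t, status=VisitStatus.EMPTY_WITH_HATCH_SIGNS))
        elif fate == "predated":
            visits.append(VisitEvent(timestamp=final_t, status=VisitStatus.EMPTY_NO_HATCH_SIGNS))
        else:
            visits.append(
                VisitEvent(timestamp=final_t, status=VisitStatus.OTHER, notes="failed: other cause")
            )

        rec = NestRecord(
            nest_id=str(nest["nest_id"]),
            found_date=found_ts,
            eggs_at_finding=laid,
            clutch_complete_at_finding=bool(complete),
            float_age_days=float_age,
            visits=visits,
            attempt_rank=1,
        )
        records.append(rec)

        if include_traces and rng.random() < config.sensor_coverage:
            pred_ts = (
                doy_to_timestamp(year, float(nest["true_predation_doy"]))
                if fate == "predated"
                else None
            )
            trace_end = (
                min(pred_ts + pd.Timedelta(days=float(rng.uniform(0.5, 2.0))), final_t)
                if pred_ts is not None
                else end_ts  # logger lifted at hatch/last-alive
            )
            if trace_end > found_ts + pd.Timedelta(hours=6):
                traces.append(
                    generate_trace(
                        str(nest["nest_id"]), found_ts, trace_end, pred_ts,
                        config, rng, temp_truth,
                    )
                )
    return records, traces


def generate_scenario(config: ScenarioConfig | None = None, seed: int | None = None) -> Scenario:
    """Full synthetic season: temperature field, cohort, observations."""
    config = config or ScenarioConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    ambient, temp_truth = generate_temperature_field(config)
    cohort = generate_cohort(config, temp_truth=temp_truth)
    records, traces = generate_observations(cohort, config, temp_truth=temp_truth)
    return Scenario(
        config=config,
        truth=cohort,
        records=records,
        traces=traces,
        ambient_samples=ambient,
        temp_truth=temp_truth,
    )
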