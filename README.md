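# nestpred

Nest predation rates and the diel timing of predation for ground-nesting
birds, from dated nest observations and continuous nest-sensor recordings.

Field studies of nest survival face two chronic measurement problems.
First, nests are found at different ages and checked at intervals, so the
naive fraction of nests predated is biased; the standard remedy is the
Mayfield *exposure-day* formulation, here fitted as a binomial GLM in which
each nest contributes its observation days as the binomial denominator:

    y_i ~ Binomial(E_i, p),  logit(p) = beta_0,
    total rate over incubation = 1 - (1 - p)^30

with flat-prior posterior simulation (5,000 draws) giving 95% credible
intervals, and AICc comparing the constant model against a seasonal one.
Second, visit-based dating cannot say *when in the day* a nest was lost.
Continuous in-nest temperature/humidity loggers and transponder readers
can: predation time is the change-point at which the nest channel collapses
onto ambient. Around those two estimators the package provides the full
pipeline: the field dating rules and fate decision tree, civil-twilight
night classification from a built-in solar ephemeris (night = sun more than
6 degrees below the horizon), circular (sine/cosine harmonic) models of
event timing, night-probability models in season and midday ground
temperature with residual decomposition, and a synthetic-data generator
that emulates a subtropical desert season — clutches initiated February to
August, a ~0.01/day predation hazard, a sunrise-leaning diel pattern whose
night share grows over the season, and ground temperatures exceeding
45 degrees C at summer midday — with full ground truth for recovery tests.

The defaults describe the system the package was built around (a lapwing
population breeding near Dubai at 24.84 N, 55.36 E, UTC+4); every site
constant and threshold is configurable.

## Worked example

Simulate a 444-nest season, build the known-fate exposure table, and
estimate the predation rate:

```python
from nestpred import (ScenarioConfig, generate_scenario, build_exposure_table,
                      mayfield_rate, seasonal_rate_model, aicc, evidence_ratio)

scen = generate_scenario(ScenarioConfig(n_nests=444, seed=3))
table = build_exposure_table(scen.records, drop_unknown_fate=True)
res = mayfield_rate(table, seed=3)
print(f"nests analysed: {res.n_nests}, predation events: {res.n_events}, "
      f"exposure: {res.total_exposure:.0f} days")
print(f"daily predation rate: {100*res.daily_rate.median:.2f}% "
      f"(95%CrI {100*res.daily_rate.lo95:.2f}-{100*res.daily_rate.hi95:.2f}%)")
print(f"total predation rate over 30-day incubation: {100*res.total_rate.median:.1f}% "
      f"({100*res.total_rate.lo95:.1f}-{100*res.total_rate.hi95:.1f}%)")
season_fit, slope = seasonal_rate_model(table, seed=3)
print(f"evidence ratio, seasonal vs constant: "
      f"{evidence_ratio(aicc(season_fit), aicc(res.fit)):.2f}")
```

prints

```
nests analysed: 368, predation events: 61, exposure: 6586 days
daily predation rate: 0.93% (95%CrI 0.72-1.19%)
total predation rate over 30-day incubation: 24.4% (19.5-30.1%)
evidence ratio, seasonal vs constant: 0.25
```

Reading it: of 444 simulated nests, 368 were found, analysable, and of
known fate; they were watched for 6,586 exposure days over which 61 were
predated. The daily rate 0.93% brackets the generator's true hazard
(0.95%/day) and compounds to a ~24% chance of losing a nest over a 30-day
incubation. The evidence ratio below 1 says the seasonal model is not
preferred over the constant-hazard model by AICc here. (The seasonal
slope itself carries a small negative offset inherent to the per-nest
midpoint covariate; see `docs/methods.md`.)

The same analysis runs stage by stage from the shell, through CSV files:

```
nestpred simulate --seed 3 --n-nests 444 --out run/
nestpred extract  --traces run/traces --ambient run/ambient.csv --out run/events.csv
nestpred fates    --header run/nests_header.csv --visits run/nest_visits.csv \
                  --events run/events.csv --drop-unknown --out run/exposure.csv
nestpred report   --exposure run/exposure.csv --events run/events.csv \
                  --ambient run/ambient.csv --seed 3 --out run/report.json
```

`extract` recovers per-event timing from the sensor traces (timestamp,
day of year, fractional hour, night flag, ground temperature at the event
hour and at midday); `report` emits one JSON with the rate estimates, the
night/day breakdown, the diel peak, the AICc table of the
night-probability models, and the 45-degree ceiling check.

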