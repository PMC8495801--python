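# Methods

`nestpred` estimates how often, and at what time of day, ground nests are
lost to predators, from two kinds of field data: dated nest observations
(finding data plus periodic visits) and continuous nest recordings
(temperature/humidity loggers and transponder readers). This note records
the models, the conventions, the numerical choices, and the places where
the design was genuinely open.

## Exposure model for the daily predation rate

The daily predation rate is estimated per *exposure day* (Mayfield's
insight: nests found late must not be credited with the days nobody
watched them). Each nest contributes one row — exposure days `E_i`, an
event indicator `y_i`, and the day-of-year midpoint of its observation
window — and the rate is the intercept of a binomial GLM with `E_i` as the
binomial denominator ("logistic exposure"):

    y_i ~ Binomial(E_i, p),    logit(p) = beta_0 [+ beta_1 * doy_i]

Exposure is fractional (the dating rules below work in half-days), and
enters the likelihood through variance weights on the proportion response
rather than integer rounding. Event rows with under one day of exposure
get a one-day denominator floor (an event consumes a whole trial day).
The intercept-only MLE is exactly `sum(y_i)/sum(E_i)`, which the test
suite uses as a closed-form oracle. The total predation probability over
an incubation of `d` days is `1 - (1 - p)^d` (30 days by default).

Uncertainty: flat-prior large-sample posterior. Coefficient vectors are
drawn from `MVN(beta_hat, Cov_hat)` (5,000 draws by default), derived
quantities are computed per draw, and 95% credible intervals are the
2.5/97.5 percentiles. No MCMC; with these sample sizes the normal
approximation is the model. Fitting is IRLS (statsmodels): tolerance 1e-8
on the coefficient change, at most 100 iterations, covariance from the
inverse observed information; non-convergence and rank-deficiency raise a
diagnostic rather than returning silently.

Model comparison uses AICc with `n` = number of exposure rows (nests).
The count of independent units is genuinely arguable (nests vs exposure
days); rows are the default and `n` is an explicit argument. Evidence
ratios are `exp(dAICc/2)`.

### Known limitations of the exposure table

Two properties of the per-nest formulation are worth stating because the
test suite had to be designed around them:

* **Midpoint endogeneity.** The seasonal model uses the midpoint of each
  nest's observation window as its covariate. Event windows end at the
  event, so predated nests have systematically shorter, earlier-centred
  windows than their cohort mates, which imprints a small negative offset
  (about -0.003/day under these study conditions) on the fitted seasonal
  slope even when the hazard is constant. The offset is additive: a
  matched contrast between sloped and constant-hazard synthetic cohorts
  recovers an injected log(2)/180 per-day tilt almost exactly, and that is
  how the tests assess the model. The per-interval "logistic exposure"
  formulation in the literature exists to avoid exactly this artifact; the
  per-nest form is kept here because it is the formulation under study.
* **Informative censoring of unknown-fate nests.** A nest whose fate could
  not be determined keeps its exposure up to the last time it was seen
  alive and contributes no event. Because that window is defined to end
  before any event, unknown-fate nests can only ever add survival days:
  with ~7% unknowns the rate deflates by roughly 6%. The drop-unknown
  filter reproduces the corresponding sensitivity analysis, and the
  calibration experiment (credible-interval coverage on synthetic cohorts)
  runs on the known-fate cohort for this reason. Coverage there is 94-95%
  over 200 replicates, with a median absolute bias of ~8% of the true
  hazard, driven by discovery-lag truncation and interval-midpoint dating.

## Dating rules and the fate decision tree

Clutch initiation is back-dated from clutch size at finding (eggs laid at
1.5-day intervals; `found - 1.5*(eggs-1)`) or taken from egg-floating age
for complete clutches (floating is consumed as a precomputed
`float_age_days` input; its calibration is out of scope). A complete
clutch without a floating age is *undatable* (an explicit `None`), never a
silent default. Expected hatch is initiation + 30 days.

Fates are assigned by a fixed-priority decision tree — hatched on chicks
seen, marked parents later guiding chicks, or ≤5 mm eggshell chips;
predated on an empty nest without hatch signs, egg remains, or partial
loss then abandonment; otherwise other-failure or unknown. Contradictory
evidence yields `unknown` plus a review flag. Nests found at hatching and
nests with a non-positive observation period are tagged `excluded` and
kept in the file but dropped from analysis tables.

Hatch dates use the ordered rules (chicks left per continuous data or
fresh chicks: minus one day; eggs-and-chicks at a visit: minus 12 h;
otherwise the expected hatch date, or last-active-visit + 1 day if the
nest outlived its expected date). Predation dates use the sensor time
when one exists, else the midpoint of (last seen alive, fate visit),
capped at the expected hatch date; a nest seen alive after its expected
hatch date is dated one day after that visit. Everything stays fractional
end-to-end; nothing is rounded to whole days.

## Solar geometry

Night classification follows the civil-twilight convention: an event is
"night" when the sun's geometric (unrefracted) elevation is strictly below
-6 deg. Sunrise is the upward crossing of -0.833 deg (refraction plus
solar radius). Both thresholds are configurable; a +-0.5 deg change in the
sunrise convention moves sunrise by under 3 minutes at this latitude.
Solar position is the NOAA-calculator algorithm (equation of time plus
declination from the mean longitude/anomaly series); the test fixture
pins it against an independently coded sidereal-time/right-ascension
ephemeris at ten date-times (agreement: better than 0.01 deg elevation,
0.3 min sunrise — tolerances 0.5 deg / 10 min). The site is fixed-offset
UTC+4, no daylight saving.

## Predation time from continuous recordings

An incubated nest is a thermal anomaly: ~37.5 deg C against an ambient
channel that swings more than 10 deg C over the day. When incubation
ends, the nest sensor relaxes onto ambient and stays there. The detector
classifies each sample as *deviating* (|t_nest - t_ambient| >= 2 deg C, or
a nest-minus-ambient humidity gap >= 5% where both humidity channels
exist) and takes the incubation end as the first sample after the last
deviation run at least one persistence window (60 min) long, refined
backwards to the half-gap crossing so the reported time is the onset of
the abrupt change rather than the moment the band is reached. Shorter
deviation episodes after that point — a parent briefly returning to the
empty nest — do not move the estimate. Traces that deviate through to the
end raise "no predation signal" (the nest was still incubated, e.g. it
hatched); transponder-only traces fall back to the last parent detection,
which is honest but coarser (parents exchange roughly hourly).

The humidity corroboration matters in the hot season, when ambient passes
through (and at night sits inside) the incubation band for hours: without
an outside-humidity reference the temperature rule false-fires on intact
nests. The thresholds (2 deg C, 5%, 60 min) are this package's
constructions — the source data pipeline did this step by eye — and all
three are exposed in configuration. Cleaning (physical bounds, >6 h
flat-lines, displaced-sensor spans while a visit confirms the nest active)
only ever reports a mask; sample values are never altered. On synthetic
traces the detector stays within max(sampling interval, 5 min) of the
injected truth in 100% of 200 replicates, re-warming blips included.

## Diel and seasonal models

Event clock hours are embedded on the unit circle (theta = 2*pi*h/24) and
hourly counts fitted with a one-harmonic Poisson GLM; the peak phase is
`atan2(b_sin, b_cos) * 24/(2*pi)`. Concentration near sunrise is tested
separately: counts in 1-h bins of circular distance from sunrise (0-12 h)
regressed on the bin midpoint, a negative slope meaning concentration.
Night-predation probability is modelled with binomial GLMs on day of
year, midday ground temperature, both, and the two residualised variants
(each predictor replaced by its OLS residual on the other). Because
season and midday temperature are strongly collinear here (the synthetic
field is calibrated to r ~ 0.85-0.9), the residual decomposition shows
how much unique signal each carries; the fitted values of the
residualised and plain two-predictor models are identical (orthogonal
reparameterisation), which is a test invariant. Every generalized model
can be refitted with a Gaussian family as a robustness check. Ground
temperatures are summarised as per-(day-of-year, hour) order statistics
over all pooled sensors; "midday" is the local clock-hour-12 cell
(configurable — the convention is not fixed by the field protocol).

Degenerate inputs are handled explicitly: all-night (or all-day) event
sets and exactly collinear predictors raise diagnostics; an event set
concentrated in a single hour bin has no finite Poisson MLE, so the last
IRLS iterate is returned with a warning (its phase/slope direction is
still meaningful).

## Synthetic data: what it emulates and what it does not

The generator writes the assumed data-generating process forwards, with
every draw tied to one seed and the ground truth returned beside the data:

* clutch initiations uniform over a Feb-Aug season (day-of-year 32-213),
  clutch sizes mostly 4, eggs at 1.5-day intervals, 30-day incubation;
* predation as per-day Bernoulli draws at hazard 0.0095/day (optionally
  tilted over the season on the logit scale) — matching the constant
  daily hazard the estimator assumes, rather than continuous-time
  exponential, because the estimator under test is daily;
* predation hours from a mixture of a sunrise-centred von Mises bump
  (weight 0.5, concentration 2 — a visible but not dominant sunrise
  tendency) over a uniform background, with the night share following a
  seasonal logit (base 0.48, +0.03/day) and hours at true ground
  temperatures above 45 deg C redrawn (predators do not move in extreme
  heat). The bump tracks the computed sunrise, not a fixed clock hour;
* discovery lags up to 20 days (nests lost before discovery are never
  found), visits every 3.5 days by default with the evidence codes the
  fate tree consumes, 7% of nests given uninformative final evidence
  (unknown fate) and 5% failing for other causes — the study cohort's
  proportions;
* sensor traces for 52% of found nests: incubation-band nest temperature
  (37.5 +- 0.7 deg C), exponential relaxation onto ambient at the true
  predation time (2-min time constant), inside/outside humidity, roughly
  hourly transponder reads, optional 10-30 min re-warming blips 1-3 h
  after the event;
* a ground-temperature field T(doy, h) = 30 + 16*cos(seasonal) +
  10*cos(diurnal, peak 14:00) + day-level weather noise (sd 4) + sensor
  noise (sd 1.5), calibrated so summer midday medians exceed 45 deg C,
  winter midday stays below 35, and the season-midday correlation lands
  near the observed ~0.87.

Not emulated: predator behaviour or identity, renesting dynamics, spatial
structure, device dropout patterns, and observer error in evidence codes
beyond the unknown-fate fraction. Passing recovery tests therefore shows
the pipeline recovers truth *under its own assumptions*; it cannot show
robustness to, say, misclassified fates or heterogeneous hazards.

## Problem sizes in the standard runs

The stochastic checks use 200 cohorts of 444 nests for rate recovery, 100
replicates of 500 events for diel recovery, and 200 traces for the
change-point accuracy — sizes at which the binomial noise on each
reported percentage is about one point, so the whole suite and the
reproduction script each finish in about a minute.
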