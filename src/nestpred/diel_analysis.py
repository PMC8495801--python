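"""Diel timing of predation: circular models, night-probability drivers.

Three questions, each with its model family:

1. Does predation concentrate at a time of day? Hourly event counts are
   fitted with a Poisson GLM on one circular harmonic — sine and cosine of
   theta = 2*pi*hour/24 — whose fitted peak phase is
   atan2(b_sin, b_cos) * 24 / (2*pi) mod 24.
2. Does predation concentrate around sunrise specifically? Counts in 1-h
   bins of absolute hours from sunrise (0-12) are regressed on the bin
   midpoint; a negative slope means concentration near sunrise.
3. Does *night* predation (sun below -6 deg) become more likely over the
   season, and is that a season effect or a temperature effect? Binomial
   GLMs of the night flag on day of year, midday ground temperature, both,
   and on residualised versions of each (residual of one predictor
   regressed on the other), compared by AICc. Since season and midday
   temperature are strongly collinear at this site, the residual
   decomposition shows how much unique signal each carries.

Every generalized fit can be refitted with a Gaussian family as a
robustness check; Gaussian models are tolerant of distributional
violations and should agree in sign and rough magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .site import SiteConfig
from .solar_time import hours_from_sunrise
from .survival_model import GLMFit, GLMError, aicc, fit_glm, posterior_sim, PosteriorSummary

__all__ = [
    "DielModelSet",
    "hourly_summaries",
    "midday_temperature",
    "season_temp_correlation",
    "circular_encode",
    "fit_diel_harmonic",
    "fit_sunrise_distance",
    "fit_night_probability",
    "gaussian_refit",
    "temperature_ceiling_check",
]


# ------------------------------------------------- ground temperatures


def hourly_summaries(samples: pd.DataFrame) -> pd.DataFrame:
    """Hourly ground-temperature order statistics pooled over all sensors.

    ``samples``: long frame with columns timestamp and temperature.
    Returns one row per present (doy, hour) cell with columns
    doy, hour, median, mean, min, max, n.
    """
    df = samples.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["doy"] = df["timestamp"].dt.dayofyear
    df["hour"] = df["timestamp"].dt.hour
    g = df.groupby(["doy", "hour"])["temperature"]
    out = g.agg(median="median", mean="mean", min="min", max="max", n="count").reset_index()
    return out


def midday_temperature(table: pd.DataFrame, doy: int, midday_hour: int = 12) -> float | None:
    """Median ground temperature of the (doy, midday_hour) cell, if present."""
    hit = table[(table["doy"] == int(doy)) & (table["hour"] == int(midday_hour))]
    return None if hit.empty else float(hit["median"].iloc[0])


def season_temp_correlation(table: pd.DataFrame, midday_hour: int = 12) -> float:
    """Pearson r between day of year and midday median ground temperature."""
    mid = table[table["hour"] == int(midday_hour)]
    if len(mid) < 3:
        raise ValueError("need midday cells on at least 3 days")
    x = mid["doy"].to_numpy(dtype=float)
    y = mid["median"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(pearsonr(x, y).statistic)


# ------------------------------------------------------ circular models


def circular_encode(hour) -> tuple[np.ndarray, np.ndarray]:
    """Unit-circle embedding of clock hour: theta = 2*pi*hour/24."""
    theta = 2.0 * np.pi * np.asarray(hour, dtype=float) / 24.0
    return np.sin(theta), np.cos(theta)


def _hour_bins(hours: np.ndarray) -> np.ndarray:
    """Event counts per integer clock hour (24 bins, zeros kept)."""
    counts = np.zeros(24, dtype=float)
    for h in np.floor(np.asarray(hours, dtype=float)).astype(int) % 24:
        counts[h] += 1
    return counts


def fit_diel_harmonic(events: pd.DataFrame) -> tuple[GLMFit, float]:
    """One-harmonic Poisson model of hourly event counts; returns peak hour.

    With all the mass in a single bin the MLE amplitude diverges; the fit
    is flagged non-convergent upstream but the peak direction is still the
    loaded bin, so the phase is computed from the final iterate.
    """
    counts = _hour_bins(events["hour"].to_numpy())
    if counts.sum() == 0:
        raise ValueError("no events to fit")
    s, c = circular_encode(np.arange(24))
    X = pd.DataFrame({"intercept": np.ones(24), "sin": s, "cos": c})
    try:
        fit = fit_glm(X, counts, family="poisson")
    except GLMError:
        # degenerate concentration: refit with a ridge-free cap via direct moments
        warnings.warn("harmonic fit did not converge (extreme concentration)", stacklevel=2)
        b_sin = float(np.sum(counts * s))
        b_cos = float(np.sum(counts * c))
        fit = GLMFit(
            family="poisson",
            coefficients=np.array([np.log(max(counts.mean(), 1e-12)), b_sin, b_cos]),
            covariance=np.full((3, 3), np.nan),
            log_likelihood=float("nan"),
            n_units=24,
            design_labels=["intercept", "sin", "cos"],
        )
    peak = (np.arctan2(fit.coef("sin"), fit.coef("cos")) * 24.0 / (2.0 * np.pi)) % 24.0
    return fit, float(peak)


def fit_sunrise_distance(
    events: pd.DataFrame,
    site: SiteConfig,
    bin_width: float = 1.0,
) -> GLMFit:
    """Poisson regression of event counts on absolute hours from sunrise.

    Events are binned by their circular distance from sunrise (at most 12 h
    away on the 24-h clock) into ``bin_width``-hour bins over 0-12 h and
    the counts regressed on the bin midpoints; a negative slope indicates
    concentration around sunrise. With every event in one bin the MLE
    diverges; the last IRLS iterate is returned with a warning, since its
    slope direction is still meaningful.
    """
    signed = np.array(
        [hours_from_sunrise(site, t)[0] for t in pd.to_datetime(events["timestamp"])]
    )
    dist = np.abs((signed + 12.0) % 24.0 - 12.0)
    edges = np.arange(0.0, 12.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(dist, 0, 12 - 1e-9), bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    X = pd.DataFrame({"intercept": np.ones(len(mids)), "abs_hours_from_sunrise": mids})
    try:
        return fit_glm(X, counts.astype(float), family="poisson")
    except GLMError as err:
        if err.partial is None:
            raise
        warnings.warn("sunrise-distance fit did not converge (extreme concentration)",
                      stacklevel=2)
        return err.partial


# ------------------------------------------------- night-probability set


@dataclass
class DielModelSet:
    """All night-predation models fitted to one event set."""

    night_season_fit: GLMFit
    night_temp_fit: GLMFit
    joint_fit: GLMFit
    resid_temp_fit: GLMFit      # season + residual temperature
    resid_season_fit: GLMFit    # temperature + residual season
    aicc_table: pd.DataFrame
    slopes: dict[str, PosteriorSummary] = field(default_factory=dict)
    harmonic_fit: GLMFit | None = None
    sunrise_fit: GLMFit | None = None


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = pd.DataFrame({"intercept": np.ones(len(x)), "x": x})
    fit = fit_glm(X, y, family="gaussian")
    return y - (fit.coefficients[0] + fit.coefficients[1] * x)


def fit_night_probability(
    events: pd.DataFrame,
    n_draws: int = 5000,
    seed: int | None = None,
) -> DielModelSet:
    """Binomial models of the night flag on season and midday temperature.

    Fits night ~ doy, night ~ midday_temp, the joint model, and the two
    residual decompositions; predictors are centred before fitting. The
    AICc table ranks the null and single-predictor models (the two
    competing explanations), with evidence ratios relative to the best.
    All-night or all-day event sets are degenerate for a binomial response
    and raise :class:`~nestpred.survival_model.GLMError`.
    """
    ev = events.dropna(subset=["night", "doy", "midday_temp"]).copy()
    y = ev["night"].astype(int).to_numpy()
    if y.min() == y.max():
        raise GLMError("all events on one side of the night/day split")
    doy = ev["doy"].to_numpy(dtype=float)
    temp = ev["midday_temp"].to_numpy(dtype=float)
    doy_c = doy - doy.mean()
    temp_c = temp - temp.mean()
    one = np.ones(len(ev))

    def _fit(cols: dict) -> GLMFit:
        return fit_glm(pd.DataFrame({"intercept": one, **cols}), y, family="binomial")

    season = _fit({"doy": doy_c})
    temp_m = _fit({"midday_temp": temp_c})
    joint = _fit({"doy": doy_c, "midday_temp": temp_c})

    resid_temp = _ols_residuals(temp_c, doy_c)
    resid_doy = _ols_residuals(doy_c, temp_c)
    if np.allclose(resid_temp, 0) or np.allclose(resid_doy, 0):
        raise GLMError("predictors exactly collinear: residual predictor is identically zero")
    season_rt = _fit({"doy": doy_c, "resid_midday_temp": resid_temp})
    temp_rd = _fit({"midday_temp": temp_c, "resid_doy": resid_doy})

    null = _fit({})
    rows = []
    for name, f in [("null", null), ("season", season), ("midday_temp", temp_m)]:
        rows.append({"model": name, "k": len(f.coefficients), "aicc": aicc(f)})
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab["evidence_ratio_vs_best"] = np.exp(tab["delta_aicc"] / 2.0)

    slopes = {}
    for name, f, idx in [
        ("season", season, 1),
        ("midday_temp", temp_m, 1),
        ("joint_doy", joint, 1),
        ("joint_midday_temp", joint, 2),
    ]:
        _, summ = posterior_sim(f, n_draws=n_draws, seed=seed, transform=lambda d, i=idx: d[:, i])
        slopes[name] = summ

    return DielModelSet(
        night_season_fit=season,
        night_temp_fit=temp_m,
        joint_fit=joint,
        resid_temp_fit=season_rt,
        resid_season_fit=temp_rd,
        aicc_table=tab,
        slopes=slopes,
    )


def gaussian_refit(design: pd.DataFrame, response: np.ndarray) -> GLMFit:
    """Identity-link Gaussian refit of any design, for robustness checks."""
    return fit_glm(design, response, family="gaussian")


def temperature_ceiling_check(
    events: pd.DataFrame, ceiling: float = 45.0
) -> tuple[float, bool, int]:
    """Maximum event-hour ground temperature, whether it stays at or below
    the ceiling, and how many events lacked a temperature and were skipped."""
    temps = pd.to_numeric(events["hourly_temp"], errors="coerce")
    skipped = int(temps.isna().sum())
    if temps.notna().sum() == 0:
        raise ValueError("no events carry an hourly temperature")
    mx = float(temps.max())
    return mx, mx <= ceiling, skipped
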