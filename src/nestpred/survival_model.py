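"""Mayfield exposure-binomial predation rates with simulated posteriors.

The daily predation rate is the intercept of a binomial GLM in which each
nest contributes its (possibly fractional) exposure days as the binomial
denominator and a 0/1 predation event as the response — the Mayfield
estimator in logistic-exposure form, whose intercept-only MLE is exactly
sum(events) / sum(exposure days). Uncertainty comes from the flat-prior
large-sample posterior: coefficient vectors are drawn from a multivariate
normal centred at the ML estimates with the fit covariance, derived
quantities (inverse-link daily rate, the 1-(1-p)^days total-rate transform)
are computed per draw, and 95% credible intervals are the 2.5th/97.5th
percentiles of 5,000 draws. Model comparison uses AICc with n = number of
exposure rows (nests); this convention is configurable since the count of
independent units is a judgement call.

Fitting is IRLS via statsmodels (convergence at 1e-8 coefficient change,
at most 100 iterations, covariance = inverse observed information);
fractional denominators enter as variance weights on the proportion
response rather than being rounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "GLMFit",
    "PosteriorSummary",
    "MayfieldResult",
    "GLMError",
    "fit_glm",
    "posterior_sim",
    "summarize_draws",
    "mayfield_rate",
    "total_rate",
    "seasonal_rate_model",
    "aicc",
    "evidence_ratio",
]


class GLMError(RuntimeError):
    """Non-convergence, separation, or a rank-deficient design.

    When IRLS ran but failed to converge, the last iterate is attached as
    ``partial`` so degenerate-but-directional fits (e.g. all events in one
    bin) can still be inspected by callers that choose to.
    """

    partial: "GLMFit | None" = None


@dataclass
class GLMFit:
    family: str
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_units: int
    design_labels: list[str]

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.design_labels.index(label)])


@dataclass
class PosteriorSummary:
    median: float
    lo95: float
    hi95: float
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lo95 <= self.median <= self.hi95:
            raise ValueError("posterior summary out of order")

    def as_dict(self) -> dict:
        return {"median": self.median, "lo95": self.lo95, "hi95": self.hi95}


@dataclass
class MayfieldResult:
    daily_rate: PosteriorSummary
    total_rate: PosteriorSummary
    n_nests: int
    n_events: int
    total_exposure: float
    boundary: bool = False
    fit: GLMFit | None = field(default=None, repr=False)


_FAMILIES = {
    "binomial": sm.families.Binomial,
    "poisson": sm.families.Poisson,
    "gaussian": sm.families.Gaussian,
}


def fit_glm(
    design: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    denominator: np.ndarray | None = None,
    family: str = "binomial",
) -> GLMFit:
    """Maximum-likelihood GLM fit; the engine behind every model here.

    ``design`` must already contain the intercept column. For the binomial
    family with a ``denominator``, the response is the event count per unit
    and the denominator the (fractional) trial count; internally the
    proportion is fitted with the denominator as variance weights, which
    maximises the same exposure likelihood.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response lengths differ")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise GLMError("design matrix is rank deficient")

    kwargs: dict = {}
    if family == "binomial" and denominator is not None:
        denom = np.asarray(denominator, dtype=float)
        if np.any(denom <= 0):
            raise ValueError("binomial denominators must be positive")
        if np.any(y < 0) or np.any(y > denom):
            raise ValueError("binomial response must lie in [0, denominator]")
        endog = y / denom
        kwargs["var_weights"] = denom
    else:
        endog = y

    model = sm.GLM(endog, X, family=_FAMILIES[family](), **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    cov = np.asarray(res.cov_params())
    out = GLMFit(
        family=family,
        coefficients=np.asarray(res.params, dtype=float),
        covariance=cov,
        log_likelihood=float(res.llf),
        n_units=int(res.nobs),
        design_labels=list(X.columns.astype(str)),
    )
    if not (getattr(res, "converged", True) and np.all(np.isfinite(res.params))):
        err = GLMError("IRLS did not converge (possible separation)")
        err.partial = out if np.all(np.isfinite(res.params)) else None
        raise err
    if not np.all(np.isfinite(cov)):
        raise GLMError("non-finite covariance (possible separation)")
    return out


def posterior_sim(
    fit: GLMFit,
    n_draws: int = 5000,
    seed: int | None = None,
    transform=None,
) -> tuple[np.ndarray, PosteriorSummary]:
    """Draws from the flat-prior large-sample posterior of the coefficients.

    ``transform`` maps a (n_draws, k) coefficient array to the scalar
    quantity of interest per draw (default: first coefficient); summaries
    are the median and the 2.5/97.5 percentiles of the transformed draws.
    """
    if not np.all(np.isfinite(fit.covariance)):
        raise GLMError("refusing to simulate from a non-finite covariance")
    rng = np.random.default_rng(seed)
    if np.allclose(fit.covariance, 0.0):
        draws = np.tile(fit.coefficients, (n_draws, 1))
    else:
        draws = rng.multivariate_normal(fit.coefficients, fit.covariance, size=n_draws)
    values = draws[:, 0] if transform is None else np.asarray(transform(draws), dtype=float)
    summary = summarize_draws(values, seed=seed)
    return draws, summary


def summarize_draws(values: np.ndarray, seed: int | None = None) -> PosteriorSummary:
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        median=float(med), lo95=float(lo), hi95=float(hi), n_draws=len(values), seed=seed
    )


def _event_floored(tab: pd.DataFrame) -> np.ndarray:
    """Binomial denominators: a predation event consumes a whole trial day,
    so event rows with under a day of (midpoint-dated) exposure get a
    one-day floor; survivor rows keep their fractional exposure."""
    expo = tab["exposure_days"].to_numpy(dtype=float)
    return np.where(tab["event"].to_numpy() == 1, np.maximum(expo, 1.0), expo)


def total_rate(p, days: float):
    """Predation probability over a whole incubation: 1 - (1 - p)^days."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("daily rate must lie in [0, 1]")
    if days <= 0:
        raise ValueError("days must be positive")
    out = 1.0 - (1.0 - p) ** days
    return float(out) if out.ndim == 0 else out


def mayfield_rate(
    exposure_table: pd.DataFrame,
    incubation_days: float = 30.0,
    n_draws: int = 5000,
    seed: int | None = None,
) -> MayfieldResult:
    """Daily and total predation rate from an exposure table.

    Intercept-only exposure-binomial fit; the daily rate is summarised on
    the probability scale and the total rate per draw as
    ``1 - (1 - p)^incubation_days``. With zero events the MLE sits on the
    boundary and no posterior is simulated: the point estimate 0 is
    returned with ``boundary=True``.
    """
    tab = exposure_table
    if len(tab) == 0:
        raise ValueError("empty exposure table")
    events = int(tab["event"].sum())
    exposure = float(tab["exposure_days"].sum())
    if events == 0:
        warnings.warn("zero predation events: rate estimate on the boundary", stacklevel=2)
        zero = PosteriorSummary(median=0.0, lo95=0.0, hi95=0.0, n_draws=0, seed=seed)
        return MayfieldResult(zero, zero, len(tab), 0, exposure, boundary=True)

    X = pd.DataFrame({"intercept": np.ones(len(tab))})
    fit = fit_glm(X, tab["event"].to_numpy(), _event_floored(tab), "binomial")
    draws, _ = posterior_sim(fit, n_draws=n_draws, seed=seed)
    p_draws = expit(draws[:, 0])
    daily = summarize_draws(p_draws, seed=seed)
    total = summarize_draws(total_rate(p_draws, incubation_days), seed=seed)
    return MayfieldResult(daily, total, len(tab), events, exposure, fit=fit)


def seasonal_rate_model(
    exposure_table: pd.DataFrame,
    n_draws: int = 5000,
    seed: int | None = None,
) -> tuple[GLMFit, PosteriorSummary]:
    """Does the daily predation rate change over the season?

    Exposure-binomial fit with the centred observation-period midpoint
    (day of year) as the single predictor; returns the fit and the
    posterior summary of the slope. Centring stabilises IRLS and leaves
    predictions unchanged.
    """
    tab = exposure_table
    doy = tab["midpoint_doy"].to_numpy(dtype=float)
    X = pd.DataFrame({"intercept": np.ones(len(tab)), "midpoint_doy_c": doy - doy.mean()})
    fit = fit_glm(X, tab["event"].to_numpy(), _event_floored(tab), "binomial")
    _, slope = posterior_sim(fit, n_draws=n_draws, seed=seed, transform=lambda d: d[:, 1])
    return fit, slope


def aicc(fit: GLMFit, n: int | None = None) -> float:
    """AICc = -2 LL + 2k + 2k(k+1)/(n-k-1), n defaulting to exposure rows."""
    k = len(fit.coefficients)
    n = fit.n_units if n is None else n
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    return -2.0 * fit.log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def evidence_ratio(aicc_a: float, aicc_b: float) -> float:
    """How many times less likely model a is than model b: exp((a-b)/2)."""
    return float(np.exp((aicc_a - aicc_b) / 2.0))
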