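"""Four-parameter logistic ripening kinetics on the thermal-time axis.

Total soluble solids S (°Brix) of a ripening berry follow a sigmoid in
cumulative growing degree days x:

    S(x) = Smin + (Smax - Smin) / (1 + exp(b * (x - x0)))

Smin and Smax are the lower and upper asymptotes (°Brix), x0 the thermal
time at the half-rise, and b the slope parameter.  Under this
parameterization an accumulation (increasing) curve requires b < 0.

Two derived quantities summarize a fitted curve:

* transition width — the GDD interval between the curve's 25% and 75%
  span crossings, 2·ln(3)/|b|;
* maximum accumulation rate — Smax divided by the transition width
  (°Brix per GDD), a secant slope through the steepest part of the curve.

Cultivars whose observations are not sigmoidal over the sampled range
(no convergence, wrong sign, negligible span, or a transition wider than
the data) are flagged rather than silently fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "FitOptions",
    "LogisticFit",
    "RateEstimate",
    "logistic_value",
    "fit_logistic",
    "fit_cultivars",
    "reject_fit",
    "transition_width",
    "max_brix_rate",
]

LN3 = math.log(3.0)


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class FitOptions:
    """Configuration for the multi-start logistic fit.

    n_starts local optimizations are run from the data-driven initials,
    each perturbed by Gaussian noise with scale ``perturb`` relative to
    the initial values; the best residual sum of squares wins.
    """

    n_starts: int = 8
    perturb: float = 0.2
    tol: float = 1e-10
    seed: int = 0
    span_floor_brix: float = 2.0
    use_span_numerator: bool = False


@dataclass
class LogisticFit:
    smin: float
    smax: float
    b: float
    x0: float
    rss: float
    n_obs: int
    converged: bool
    accepted: bool = False
    rejection_reason: str = ""
    cultivar: str = ""

    @property
    def span(self) -> float:
        return self.smax - self.smin


@dataclass(frozen=True)
class RateEstimate:
    transition_width: float  # degree-days
    max_rate: float  # °Brix per degree-day


def logistic_value(fit, gdd):
    """Evaluate the sigmoid at ``gdd`` (scalar or array), overflow-safe."""
    x = np.asarray(gdd, dtype=float)
    # 1/(1+exp(z)) == expit(-z); expit saturates instead of overflowing
    val = fit.smin + (fit.smax - fit.smin) * expit(-fit.b * (x - fit.x0))
    if np.ndim(gdd) == 0:
        return float(val)
    return val


def _initials(gdd: np.ndarray, brix: np.ndarray) -> np.ndarray:
    smin0 = float(brix.min())
    smax0 = float(brix.max())
    span = max(smax0 - smin0, 1e-6)
    gdd_range = float(gdd.max() - gdd.min())
    # x0 at the observation closest to the median Brix level
    x0_0 = float(gdd[np.argmin(np.abs(brix - np.median(brix)))])
    # secant slope across the data, mapped to b via max slope |b|*span/4
    secant = (brix[np.argmax(gdd)] - brix[np.argmin(gdd)]) / gdd_range
    b0 = -4.0 * secant / span
    if b0 == 0.0:
        b0 = -1.0 / gdd_range
    return np.array([smin0, smax0, b0, x0_0])


def fit_logistic(
    gdd, brix, options: FitOptions | None = None, cultivar: str = ""
) -> LogisticFit:
    """Least-squares fit of the four-parameter logistic to (gdd, brix) points.

    Requires at least 5 observations spanning a nonzero GDD range.
    Acceptance (`accepted`, `rejection_reason`) is set by :func:`reject_fit`.
    """
    options = options or FitOptions()
    gdd = np.asarray(gdd, dtype=float)
    brix = np.asarray(brix, dtype=float)
    if gdd.shape != brix.shape:
        raise FitError("gdd and brix must have the same length")
    if gdd.size < 5:
        raise FitError(f"need >= 5 observations to fit a 4-parameter curve, got {gdd.size}")
    if np.ptp(gdd) == 0:
        raise FitError("degenerate design: all observations at the same GDD")

    def resid(theta):
        smin, smax, b, x0 = theta
        return smin + (smax - smin) * expit(-b * (gdd - x0)) - brix

    base = _initials(gdd, brix)
    rng = np.random.default_rng(options.seed)
    best = None
    converged = False
    for i in range(options.n_starts):
        start = base.copy()
        if i > 0:
            scale = options.perturb * np.maximum(np.abs(base), 1e-3)
            start = base + rng.normal(0.0, scale)
        try:
            sol = least_squares(
                resid, start, method="lm", ftol=options.tol, xtol=1e-12, gtol=1e-12,
                max_nfev=20000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success:
            converged = True
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))

    if best is None:
        fit = LogisticFit(np.nan, np.nan, np.nan, np.nan, np.inf, gdd.size, False,
                          cultivar=cultivar)
        return reject_fit(fit, gdd, options)

    rss, theta, _ = best
    smin, smax, b, x0 = theta
    # canonical orientation: if the optimizer landed on the mirrored
    # solution (smin>smax with b>0), swap to the equivalent curve
    if smin > smax:
        smin, smax, b = smax, smin, -b
    fit = LogisticFit(
        smin=float(smin), smax=float(smax), b=float(b), x0=float(x0),
        rss=float(rss), n_obs=int(gdd.size), converged=converged, cultivar=cultivar,
    )
    return reject_fit(fit, gdd, options)


def reject_fit(fit: LogisticFit, gdd, options: FitOptions | None = None) -> LogisticFit:
    """Apply the sigmoid-plausibility screen and set accepted/rejection_reason.

    A fit is rejected when the optimizer failed, the slope has the wrong
    sign (b >= 0, a flat or decreasing series), the fitted span is below
    the configurable floor, or the transition width exceeds the observed
    GDD range (the data never resolve the S-shape).
    """
    options = options or FitOptions()
    gdd = np.asarray(gdd, dtype=float)
    reason = ""
    if not fit.converged or not np.isfinite([fit.smin, fit.smax, fit.b, fit.x0]).all():
        reason = "did-not-converge"
    elif fit.b >= 0 or fit.span < options.span_floor_brix:
        reason = "non-sigmoidal"
    else:
        width = 2.0 * LN3 / abs(fit.b)
        if width > float(np.ptp(gdd)):
            reason = "transition-wider-than-data"
    return replace(fit, accepted=(reason == ""), rejection_reason=reason)


def transition_width(fit: LogisticFit) -> float:
    """GDD between the 25% and 75% crossings of the fitted span: 2·ln3/|b|."""
    if fit.b == 0 or not np.isfinite(fit.b):
        raise FitError("transition width undefined for b = 0")
    return 2.0 * LN3 / abs(fit.b)


def max_brix_rate(fit: LogisticFit, use_span_numerator: bool = False) -> RateEstimate:
    """Maximum Brix accumulation rate, Smax / transition width (°Brix per GDD).

    The conventional numerator is the upper asymptote Smax; with
    ``use_span_numerator=True`` the rise Smax - Smin is used instead.
    """
    width = transition_width(fit)
    if width <= 0:
        raise FitError("non-positive transition width")
    numerator = fit.span if use_span_numerator else fit.smax
    return RateEstimate(transition_width=width, max_rate=numerator / width)


def fit_cultivars(
    observations: pd.DataFrame, options: FitOptions | None = None
) -> pd.DataFrame:
    """Fit one curve per cultivar, pooling observations across vines.

    ``observations`` needs columns ``cultivar``, ``gdd``, ``brix``.
    Returns one row per cultivar with the fitted parameters, acceptance
    flag, and (for accepted fits) transition width and max rate.
    """
    options = options or FitOptions()
    rows = []
    for cultivar, grp in observations.groupby("cultivar", sort=True):
        fit = fit_logistic(grp["gdd"], grp["brix"], options, cultivar=str(cultivar))
        row = {
            "cultivar": cultivar,
            "smin": fit.smin,
            "smax": fit.smax,
            "b": fit.b,
            "x0": fit.x0,
            "rss": fit.rss,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "accepted": fit.accepted,
            "rejection_reason": fit.rejection_reason,
            "transition_width": np.nan,
            "max_rate": np.nan,
        }
        if fit.accepted:
            est = max_brix_rate(fit, options.use_span_numerator)
            row["transition_width"] = est.transition_width
            row["max_rate"] = est.max_rate
        rows.append(row)
    return pd.DataFrame(rows)
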