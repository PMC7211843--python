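"""Generalized Pareto excess model for peaks-over-threshold analysis.

Given a high threshold ``t``, extreme value theory says the excess
``Y = X - t`` of an observation above ``t`` approximately follows a
generalized Pareto distribution (GPD),

    H(y) = 1 - (1 + gamma * y / sigma) ** (-1 / gamma),   y > 0,

on the set where ``1 + gamma * y / sigma > 0`` (and the exponential form
``1 - exp(-y / sigma)`` at ``gamma = 0``).  The shape ``gamma`` controls the
tail: ``gamma < 0`` means a short tail with finite upper support bound
``-sigma / gamma`` for the excesses — the case of interest when estimating a
ceiling such as the maximum attainable crop yield.

This module provides the distribution functions (wrapping
:mod:`scipy.stats`' ``genpareto``), the construction of exceedance sets from
raw samples, and three estimators of ``(gamma, sigma)``: maximum likelihood
(the primary estimator), the Dekkers–Einmahl–de Haan moment estimator and
the Hosking–Wallis probability-weighted-moment estimator (robustness
cross-checks, also used as ML starting values).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "GPDParams",
    "ExceedanceSet",
    "GPDFit",
    "FitError",
    "gpd_cdf",
    "gpd_pdf",
    "gpd_quantile",
    "gpd_sample",
    "gpd_loglik",
    "select_exceedances",
    "fit_ml",
    "fit_moment",
    "fit_pwm",
]

# Switch to the exponential (gamma = 0) likelihood branch below this |gamma|.
_GAMMA_SWITCH = 1e-6


class FitError(RuntimeError):
    """Estimation failed; ``diagnostics`` carries optimizer details."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class GPDParams:
    """Shape/scale pair of a GPD excess distribution.

    ``gamma < 0``: bounded excess support ``[0, -sigma/gamma]``;
    ``gamma = 0``: exponential tail; ``gamma > 0``: heavy tail.
    """

    gamma: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.gamma):
            raise ValueError(f"gamma must be finite, got {self.gamma}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def endpoint(self) -> float:
        """Upper support bound of the excess distribution (inf if gamma >= 0)."""
        if self.gamma < 0:
            return -self.sigma / self.gamma
        return math.inf

    def _dist(self):
        # exponential branch: genpareto loses accuracy for |c| near the
        # float epsilon, and the gamma -> 0 limit is the exponential law
        if abs(self.gamma) < _GAMMA_SWITCH:
            return stats.expon(loc=0.0, scale=self.sigma)
        return stats.genpareto(c=self.gamma, loc=0.0, scale=self.sigma)


@dataclass(frozen=True)
class ExceedanceSet:
    """The ``k`` highest observations of a sample, as excesses over ``t_k``.

    ``threshold`` is the (k+1)-th highest order statistic, ``excesses`` the k
    highest values minus the threshold (all strictly positive), ``n`` the
    size of the full sample and ``t0`` its maximum.
    """

    threshold: float
    excesses: np.ndarray
    k: int
    n: int
    t0: float

    def __post_init__(self):
        y = np.asarray(self.excesses, dtype=float)
        object.__setattr__(self, "excesses", y)
        if y.ndim != 1 or y.size != self.k:
            raise ValueError(f"expected {self.k} excesses, got shape {y.shape}")
        if y.size == 0:
            raise ValueError("empty exceedance set")
        if y.min() <= 0:
            raise ValueError("all excesses must be strictly positive")
        if not math.isclose(self.t0, self.threshold + y.max(), rel_tol=0, abs_tol=1e-8):
            raise ValueError("t0 must equal threshold + max(excesses)")
        if not 0 < self.k <= self.n:
            raise ValueError(f"invalid k={self.k} for n={self.n}")


@dataclass(frozen=True)
class GPDFit:
    """A fitted exceedance model.

    ``cov`` is the asymptotic covariance of ``(gamma_hat, sigma_hat)`` — the
    (1/k) V matrix of the ML theory, delta-scaled to the scale estimate — or
    ``None`` when ``gamma_hat <= -1/2`` (outside the regular regime).
    """

    params: GPDParams
    exceedances: ExceedanceSet
    loglik: float
    cov: Optional[np.ndarray]
    converged: bool
    method: str = "ml"

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "method": self.method,
            "gamma": float(self.params.gamma),
            "sigma": float(self.params.sigma),
            "k": int(self.exceedances.k),
            "n": int(self.exceedances.n),
            "threshold": float(self.exceedances.threshold),
            "t0": float(self.exceedances.t0),
            "loglik": float(self.loglik),
            "cov": None if self.cov is None else [[float(v) for v in row] for row in self.cov],
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# Distribution functions
# ---------------------------------------------------------------------------

def _validate_nonneg(y):
    arr = np.asarray(y, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("excess values must be non-negative")
    return arr


def gpd_cdf(y, params: GPDParams):
    """GPD distribution function of an excess ``y >= 0``.

    Returns 1 for values at or beyond the support endpoint when gamma < 0;
    continuous in gamma at 0.
    """
    arr = _validate_nonneg(y)
    out = params._dist().cdf(arr)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def gpd_pdf(y, params: GPDParams):
    """GPD density of an excess ``y >= 0`` (0 beyond the endpoint)."""
    arr = _validate_nonneg(y)
    out = params._dist().pdf(arr)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def gpd_quantile(p, params: GPDParams):
    """Quantile of the excess distribution for ``p`` in ``[0, 1)``."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() >= 1):
        raise ValueError("probabilities must lie in [0, 1)")
    out = params._dist().ppf(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def gpd_sample(params: GPDParams, size: int, rng) -> np.ndarray:
    """Draw ``size`` excesses by inverse transform under a seeded stream.

    ``rng`` is a :class:`numpy.random.Generator` or anything accepted by
    :func:`numpy.random.default_rng`.
    """
    rng = np.random.default_rng(rng)
    return np.asarray(gpd_quantile(rng.random(size), params))


def gpd_loglik(excesses, gamma: float, sigma: float) -> float:
    """GPD log-likelihood of an excess sample; ``-inf`` outside the support."""
    y = np.asarray(excesses, dtype=float)
    if sigma <= 0 or not np.isfinite(sigma) or not np.isfinite(gamma):
        return -math.inf
    k = y.size
    if abs(gamma) < _GAMMA_SWITCH:
        return -k * math.log(sigma) - float(y.sum()) / sigma
    z = gamma * y / sigma
    w = 1.0 + z
    if w.min() <= 0:
        return -math.inf
    return -k * math.log(sigma) - (1.0 + 1.0 / gamma) * float(np.log1p(z).sum())


# ---------------------------------------------------------------------------
# Exceedance construction
# ---------------------------------------------------------------------------

def select_exceedances(values, k: int) -> ExceedanceSet:
    """Top-``k`` excesses over the (k+1)-th highest order statistic.

    ``values`` may be a 1-d array of yields or a farm-max sample frame with a
    ``max_yield`` column.  Values tied with the threshold would leave fewer
    than ``k`` strictly positive excesses, which is rejected (the model is
    defined on the k *highest* values, strictly above the threshold).
    """
    if hasattr(values, "columns"):
        values = values["max_yield"]
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    xs = np.sort(x)[::-1]
    threshold = float(xs[k])
    excesses = xs[:k] - threshold
    if excesses.min() <= 0:
        raise ValueError(
            f"ties at the threshold t_k={threshold}: the {k} highest values are "
            "not all strictly above the (k+1)-th highest; choose a different k"
        )
    return ExceedanceSet(
        threshold=threshold,
        excesses=np.sort(excesses),
        k=k,
        n=n,
        t0=float(xs[0]),
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _ml_cov(gamma: float, sigma: float, k: int) -> Optional[np.ndarray]:
    # (1/k) V of the ML asymptotics, delta-scaled from sigma_hat/sigma to
    # sigma_hat; undefined for gamma <= -1/2.
    if gamma <= -0.5:
        return None
    one = 1.0 + gamma
    v = np.array(
        [
            [one**2, -one * sigma],
            [-one * sigma, (1.0 + one**2) * sigma**2],
        ]
    )
    return v / k


def _penalized_nll(theta, y):
    gamma, logs = theta
    if not (np.isfinite(gamma) and np.isfinite(logs)) or abs(logs) > 50:
        return 1e12
    if abs(gamma) >= 5.0:
        return 1e8 * (1.0 + abs(gamma) - 5.0)
    sigma = math.exp(logs)
    k = y.size
    if abs(gamma) < _GAMMA_SWITCH:
        return k * logs + float(y.sum()) / sigma
    z = gamma * y / sigma
    wmin = 1.0 + float(z.min()) if gamma < 0 else 1.0
    if wmin <= 1e-12:
        # graded penalty so the simplex can find its way back into support
        return 1e8 * (1.0 + min(-wmin + 1e-12, 1e4))
    return k * logs + (1.0 + 1.0 / gamma) * float(np.log1p(z).sum())


def _feasible_start(gamma: float, sigma: float, ymax: float):
    gamma = float(np.clip(gamma, -4.5, 4.5))
    if gamma < 0 and -sigma / gamma <= ymax:
        sigma = 1.05 * (-gamma) * ymax  # push the implied endpoint past the data
    return (gamma, math.log(sigma))


def _starting_points(exc: ExceedanceSet):
    y = exc.excesses
    ymax = float(y.max())
    starts = []
    try:
        p = fit_pwm(exc)
        starts.append(_feasible_start(p.gamma, p.sigma, ymax))
    except (FitError, ValueError):
        pass
    try:
        p = fit_moment(exc)
        starts.append(_feasible_start(p.gamma, p.sigma, ymax))
    except (FitError, ValueError):
        pass
    starts.append((0.1, math.log(float(y.mean()))))
    return starts


def fit_ml(exceedances: ExceedanceSet) -> GPDFit:
    """Maximum-likelihood GPD fit of an exceedance set.

    Optimizes the penalized log-likelihood in ``(gamma, log sigma)`` with a
    Nelder–Mead simplex from multiple starts (PWM, moment, exponential-like),
    since the likelihood can be multimodal near the non-regular region.  A
    warning is issued when ``gamma_hat <= -1/2``, where the asymptotic
    normal theory (and hence ``cov``) is unavailable.
    """
    y = exceedances.excesses
    k = y.size
    if k < 2:
        raise FitError(f"need at least 2 excesses, got {k}")
    if np.ptp(y) == 0:
        raise FitError("degenerate excesses: all values identical")

    starts = _starting_points(exceedances)
    # deterministic fallback perturbations around the first start
    g0, s0 = starts[0]
    restarts = [(g0 + dg, s0 + ds) for dg in (-0.4, 0.4) for ds in (-0.7, 0.7)]

    best = None
    for theta0 in starts + restarts:
        res = minimize(
            _penalized_nll,
            np.asarray(theta0, dtype=float),
            args=(y,),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if theta0 is starts[-1] and best.fun < 1e7:
            break  # regular case: no need for the fallback restarts

    if best is None or best.fun >= 1e7 or not np.isfinite(best.fun):
        raise FitError(
            "ML optimization failed to locate a feasible optimum",
            diagnostics={"best_fun": None if best is None else float(best.fun),
                         "starts": starts},
        )

    gamma = float(best.x[0])
    sigma = float(math.exp(best.x[1]))
    loglik = gpd_loglik(y, gamma, sigma)
    if not np.isfinite(loglik):
        raise FitError("optimum lies outside the support", diagnostics={"x": list(best.x)})
    if gamma <= -0.5:
        warnings.warn(
            f"gamma_hat = {gamma:.3f} <= -1/2: ML asymptotic normality does not "
            "apply; confidence intervals are unavailable for this fit",
            stacklevel=2,
        )
    return GPDFit(
        params=GPDParams(gamma=gamma, sigma=sigma),
        exceedances=exceedances,
        loglik=float(loglik),
        cov=_ml_cov(gamma, sigma, k),
        converged=bool(best.success),
    )


def fit_moment(exceedances: ExceedanceSet) -> GPDParams:
    """Dekkers–Einmahl–de Haan moment estimator from the top order statistics.

    Uses the log-spacings of the k highest observations over the threshold,
    so it needs the observations on their original (positive) scale.
    """
    if exceedances.k < 4:
        raise FitError(f"moment estimator needs k >= 4, got {exceedances.k}")
    t = exceedances.threshold
    if t <= 0:
        raise FitError("moment estimator requires a positive threshold")
    logs = np.log1p(exceedances.excesses / t)  # log X_(i) - log t_k
    m1 = float(logs.mean())
    m2 = float((logs**2).mean())
    if m2 <= 0 or m1 <= 0:
        raise FitError("degenerate log-spacings")
    ratio = 1.0 - m1**2 / m2
    if ratio <= 0:
        raise FitError("moment estimator undefined: constant order statistics")
    gamma_minus = 1.0 - 0.5 / ratio
    gamma = m1 + gamma_minus
    sigma = t * m1 * (1.0 - gamma_minus)
    return GPDParams(gamma=gamma, sigma=sigma)


def fit_pwm(exceedances: ExceedanceSet) -> GPDParams:
    """Hosking–Wallis probability-weighted-moment estimator.

    With ``b0`` the sample mean of the excesses and ``b1`` the unbiased
    estimate of ``E[Y (1 - F(Y))]``, the estimator is
    ``gamma = 2 - b0 / (b0 - 2 b1)`` and ``sigma = 2 b0 b1 / (b0 - 2 b1)``.
    """
    if exceedances.k < 4:
        raise FitError(f"PWM estimator needs k >= 4, got {exceedances.k}")
    y = np.sort(exceedances.excesses)
    k = y.size
    b0 = float(y.mean())
    w = (k - 1 - np.arange(k)) / (k - 1)
    b1 = float((y * w).mean())
    denom = b0 - 2.0 * b1
    if denom <= 0 or b1 <= 0:
        raise FitError("PWM estimator undefined for this sample")
    return GPDParams(gamma=2.0 - b0 / denom, sigma=2.0 * b0 * b1 / denom)
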