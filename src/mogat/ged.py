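"""Symmetric generalized Gaussian (generalized error distribution) fitting.

Density: f(x) = beta / (2 alpha Gamma(1/beta)) * exp(-(|x - mu| / alpha)^beta)

beta = 2 is the Gaussian case (with sigma^2 = alpha^2 / 2) and beta = 1
is Laplace.  Fitted to prediction residuals to characterize the error
distribution of a regressor: mu measures bias, alpha spread, beta
tail weight/peakedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class GEDFitError(RuntimeError):
    """Raised when the likelihood maximization cannot proceed or fails."""

    def __init__(self, message: str, init: tuple | None = None):
        super().__init__(message)
        self.init = init


@dataclass
class GEDParams:
    """Location, scale (> 0), and shape (> 0) of the fitted distribution."""

    mu: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")


def ged_logpdf(x, mu: float, alpha: float, beta: float):
    return stats.gennorm.logpdf(x, beta, loc=mu, scale=alpha)


def sample_ged(n: int, mu: float, alpha: float, beta: float,
               rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw n variates from the generalized error distribution."""
    return stats.gennorm.rvs(beta, loc=mu, scale=alpha, size=n,
                             random_state=np.random.default_rng(rng))


def fit_ged(residuals, min_n: int = 10) -> GEDParams:
    """Maximum-likelihood fit of (mu, alpha, beta).

    Optimizes over (mu, log alpha, log beta) so the positivity
    constraints hold by construction, starting from moment matching
    (mu = sample mean; beta = 2; alpha from alpha^2 = 2 var, the
    Gaussian-case relation).  Requires at least ``min_n`` residuals and
    nonzero spread.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < min_n:
        raise GEDFitError(f"need at least {min_n} residuals, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise GEDFitError("residuals contain non-finite values")
    mu0 = float(np.mean(x))
    var = float(np.var(x))
    if var < 1e-20 or np.ptp(x) == 0.0:
        raise GEDFitError("degenerate residuals: zero spread (alpha -> 0)",
                          init=(mu0, 0.0, 2.0))
    alpha0 = np.sqrt(2.0 * var)
    theta0 = np.array([mu0, np.log(alpha0), np.log(2.0)])

    def nll(theta):
        mu, log_a, log_b = theta
        return -np.sum(ged_logpdf(x, mu, np.exp(log_a), np.exp(log_b)))

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 5000, "maxfev": 5000})
    if not res.success or not np.all(np.isfinite(res.x)):
        raise GEDFitError(f"likelihood maximization failed: {res.message}",
                          init=tuple(theta0))
    mu, log_a, log_b = res.x
    return GEDParams(mu=float(mu), alpha=float(np.exp(log_a)),
                     beta=float(np.exp(log_b)))
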