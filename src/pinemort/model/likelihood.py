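"""Zero-inflated binomial likelihood and the mortality linear predictor.

The cell-level response is a mixture: with probability ``p`` a cell produces
zero dead trees regardless of its covariates (an independent, unmodelled
process), otherwise the dead count is Binomial(n, pi) with the per-cell
mortality probability pi given by a logit-linear model plus a per-site
spatial Gaussian-process offset.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import binom

__all__ = ["linear_predictor", "zib_logpmf", "zib_rvs"]


def linear_predictor(
    beta: np.ndarray, X: np.ndarray, gp_value: np.ndarray | float = 0.0
) -> np.ndarray:
    """logit(pi) = X @ beta + GP offset.

    ``X`` must carry the intercept column first and the 13 covariate /
    interaction columns in coefficient order (see :mod:`pinemort.design`).
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"expected {beta.shape[0]}"
        )
    return X @ beta + gp_value


def zib_logpmf(y, n, pi, p) -> np.ndarray:
    """Log pmf of the zero-inflated binomial, stable in log space.

    ``log[ p * 1{y=0} + (1-p) * C(n,y) pi^y (1-pi)^(n-y) ]``; the ``y = 0``
    branch uses log-sum-exp. Arrays broadcast.
    """
    y = np.asarray(y)
    n = np.asarray(n)
    if np.any(y > n) or np.any(y < 0):
        raise ValueError("require 0 <= y <= n")
    pi = np.asarray(pi, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("zero-inflation probability must be in [0, 1]")

    log_b = binom.logpmf(y, n, pi)
    with np.errstate(divide="ignore"):
        out = np.log1p(-p) + log_b
        # y == 0: log( p + (1-p) (1-pi)^n )
        zero_term = np.logaddexp(np.log(p), np.log1p(-p) + n * np.log1p(-pi))
    out = np.where(y == 0, zero_term, out)
    return out if out.ndim else float(out)


def zib_rvs(n, pi, p, rng: np.random.Generator) -> np.ndarray:
    """Draw zero-inflated binomial counts (vectorized over cells)."""
    n = np.asarray(n)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), n.shape)
    counts = rng.binomial(n, pi)
    zeroed = rng.random(n.shape) < p
    return np.where(zeroed, 0, counts)


# -- analytic gradient pieces used by the posterior ------------------------


def zib_loglik_grads(y, n, eta, u, zero_inflation: bool, lchoose=None):
    """Per-cell log-likelihood, d/d eta, and d/d u (u = logit p).

    eta is the linear predictor (logit pi). Returns (loglik_sum, g_eta, g_u);
    ``g_u`` is a scalar (None when zero inflation is off). ``lchoose`` lets
    callers precompute the log binomial coefficients.
    """
    pi = special.expit(eta)
    p = special.expit(u) if zero_inflation else 0.0
    log1m_pi = -np.logaddexp(0.0, eta)  # log(1 - pi), stable
    log_pi = eta + log1m_pi             # log(pi)
    if lchoose is None:
        lchoose = (
            special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
        )
    log_b = lchoose + y * log_pi + (n - y) * log1m_pi

    if not zero_inflation:
        ll = float(np.sum(log_b))
        return ll, y - n * pi, None

    log_p = -np.logaddexp(0.0, -u)  # log p
    log_1mp = -np.logaddexp(0.0, u)  # log (1-p)
    is0 = y == 0
    logB = log_1mp + n * log1m_pi  # log[(1-p)(1-pi)^n]
    logf = np.logaddexp(log_p, logB)  # mixture mass at zero
    ll = float(np.sum(np.where(is0, logf, log_1mp + log_b)))

    # d/d eta: y>0 -> y - n pi ; y=0 -> -n pi exp(logB - logf)
    g_eta = np.where(is0, -n * pi * np.exp(logB - logf), y - n * pi)
    # d/d u: y>0 -> -p ; y=0 -> p(1-p)(1 - (1-pi)^n)/f
    g_u0 = p * (1.0 - p) * -np.expm1(n * log1m_pi) * np.exp(-logf)
    g_u = float(np.sum(np.where(is0, g_u0, -p)))
    return ll, g_eta, g_u
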