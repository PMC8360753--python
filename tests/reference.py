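"""Independent reference implementations used as test oracles.

Everything here recomputes quantities by a route different from the
package code: diagonal-precision (lasso-form) and ridge-shifted
(elastic-net-form) conditional parameters written from their own
formulas, quadrature-normalized 1-D densities, and batch-means standard
errors for autocorrelated chains.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d


# --- Bayesian-Lasso-form conditional parameters (diagonal precision) -------

def lasso_beta_params(X, y, sigma2, tau2, r):
    """mu and Sigma of the beta conditional when the prior precision is
    purely diagonal: A = X'X + r*diag(1/tau^2)."""
    A = X.T @ X + r * np.diag(1.0 / tau2)
    Ainv = np.linalg.inv(A)
    return Ainv @ X.T @ y, sigma2 * Ainv


def lasso_sigma2_params(X, y, beta, tau2, r, a, b):
    n, p = X.shape
    resid = y - X @ beta
    quad = r * np.sum(beta**2 / tau2)
    return 0.5 * (n + p) + a, 0.5 * (resid @ resid + quad) + b


def lasso_tau2_params(beta, sigma2, r, lambda2):
    """(chi_j, psi) of each independent GIG conditional."""
    return r * beta**2 / sigma2, lambda2


def lasso_r_params(beta, sigma2, tau2, c, d):
    p = beta.shape[0]
    return 0.5 * p + c, np.sum(beta**2 / tau2) / (2.0 * sigma2) + d


def lasso_lambda2_params(tau2, e, f):
    return tau2.shape[0] + e, 0.5 * tau2.sum() + f


# --- Bayesian-Elastic-Net-form (diagonal + ridge identity) -----------------

def enet_beta_params(X, y, sigma2, tau2, r):
    A = X.T @ X + r * (np.diag(1.0 / tau2) + np.eye(len(tau2)))
    Ainv = np.linalg.inv(A)
    return Ainv @ X.T @ y, sigma2 * Ainv


def enet_sigma2_params(X, y, beta, tau2, r, a, b):
    n, p = X.shape
    resid = y - X @ beta
    quad = r * (np.sum(beta**2 / tau2) + beta @ beta)
    return 0.5 * (n + p) + a, 0.5 * (resid @ resid + quad) + b


def enet_r_params(beta, sigma2, tau2, c, d):
    p = beta.shape[0]
    quad = np.sum(beta**2 / tau2) + beta @ beta
    return 0.5 * p + c, quad / (2.0 * sigma2) + d


# --- quadrature-normalized densities for KS checks -------------------------

def quadrature_cdf(log_density, lo, hi, n_grid=20001):
    """Numerically normalized CDF of exp(log_density) on [lo, hi].

    Returns a callable CDF (linear interpolation on a fine grid).
    """
    xs = np.linspace(lo, hi, n_grid)
    lp = np.array([log_density(x) for x in xs])
    lp -= lp.max()
    dens = np.exp(lp)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(xs))])
    cdf /= cdf[-1]
    return interp1d(xs, cdf, bounds_error=False, fill_value=(0.0, 1.0))


# --- chain standard errors --------------------------------------------------

def batch_means_se(x, n_batches=50):
    """Standard error of the mean of an autocorrelated sequence."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    b = x[: n_batches * m].reshape(n_batches, m).mean(axis=1)
    return float(b.std(ddof=1) / np.sqrt(n_batches))
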