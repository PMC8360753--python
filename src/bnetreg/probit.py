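"""Binary responses via probit data augmentation.

A binary label y_i is modeled as the sign of a latent Gaussian variable
z_i = X_i beta + eps_i, eps_i ~ N(0, sigma^2): y_i = 1 iff z_i > 0, so
P(y_i = 1 | beta, sigma^2) = Phi(X_i beta / sigma).  Conditional on the
labels, each z_i is a truncated normal — truncation to (0, inf) when
y_i = 1, to (-inf, 0] otherwise — and the draws are independent across
observations, so no joint truncated-multivariate routine is needed.
Replacing y with the current z turns every Gaussian-model conditional
into the matching probit-model conditional unchanged.

sigma^2 keeps its inverse-gamma update by default even though probit
models are conventionally identified by fixing sigma^2 = 1; pass
``fix_sigma2=True`` (or set it on :class:`~bnetreg.gibbs.ChainConfig`)
for the pinned variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionDataset
from .gibbs import ChainConfig, ChainResult, run_chain
from .graph import NormalizedLaplacian
from .model import Hyperparameters, ModelState

__all__ = ["LatentResponse", "sample_latent", "run_chain_binary", "predict_probability"]


@dataclass(frozen=True)
class LatentResponse:
    """Latent Gaussian variables paired with the binary labels they encode."""

    z: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        pos, neg = self.y == 1, self.y == 0
        if not ((self.z[pos] > 0).all() and (self.z[neg] <= 0).all()):
            raise ValueError("latent variables violate their sign constraints")


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        bad = np.unique(y[~np.isin(y, (0, 1))])
        raise ValueError(f"binary response must be coded 0/1; found values {bad.tolist()}")
    return y.astype(int)


def _draw_latent(beta, sigma2, X, y, rng):
    mean = X @ beta
    sd = np.sqrt(sigma2)
    # standardized truncation bounds; scipy's truncnorm is tail-safe for
    # |mean|/sd far beyond 6
    lo = np.where(y == 1, -mean / sd, -np.inf)
    hi = np.where(y == 1, np.inf, -mean / sd)
    z = stats.truncnorm.rvs(lo, hi, loc=mean, scale=sd, random_state=rng)
    # the closed boundary z = 0 for y = 0 has probability zero; clip any
    # rounding excursions back to the constraint
    z = np.where((y == 0) & (z > 0), 0.0, z)
    z = np.where((y == 1) & (z <= 0), np.nextafter(0.0, 1.0), z)
    return z


def sample_latent(state: ModelState, data: ExpressionDataset,
                  rng: np.random.Generator) -> LatentResponse:
    """Draw the truncated-normal latent variables given the current state."""
    y = _check_binary(data.y)
    z = _draw_latent(state.beta, state.sigma2, data.X, y, rng)
    return LatentResponse(z=z, y=y)


def run_chain_binary(
    data: ExpressionDataset,
    L: NormalizedLaplacian,
    hp: Hyperparameters | None = None,
    cfg: ChainConfig | None = None,
    init: ModelState | None = None,
) -> ChainResult:
    """Gibbs sampler for the probit model.

    Each sweep first refreshes the latent z given the current state, then
    performs the five Gaussian-model updates with z as the response.
    """
    y = _check_binary(data.y)

    def latent(state: ModelState, rng: np.random.Generator) -> np.ndarray:
        return _draw_latent(state.beta, state.sigma2, data.X, y, rng)

    return run_chain(data, L, hp=hp, cfg=cfg, init=init, response_override=latent)


def predict_probability(beta: np.ndarray, sigma2: float, Xnew: np.ndarray) -> np.ndarray:
    """P(y = 1) = Phi(X beta / sigma) for rows of ``Xnew``.

    ``Xnew`` must be on the training standardization scale.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != beta.shape[0]:
        raise ValueError(f"Xnew has {Xnew.shape[1]} columns but beta has length {beta.shape[0]}")
    return stats.norm.cdf(Xnew @ beta / np.sqrt(sigma2))
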