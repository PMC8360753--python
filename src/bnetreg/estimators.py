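"""Scikit-learn-style estimators wrapping the Gibbs sampler.

:class:`NetworkBayesRegressor` (Gaussian response) and
:class:`NetworkBayesProbitClassifier` (binary response) fit the
network-constrained shrinkage model by MCMC and expose posterior-mean
coefficients, credible intervals and a gene ranking as fitted
attributes.  Both compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import ExpressionDataset, standardize
from .gibbs import ChainConfig, run_chain
from .graph import GeneNetwork, NormalizedLaplacian, align_to_genes, build_normalized_laplacian
from .model import Hyperparameters
from .probit import predict_probability, run_chain_binary
from .selection import select_top_k, summarize_chain

__all__ = ["NetworkBayesRegressor", "NetworkBayesProbitClassifier"]


def _resolve_laplacian(network, feature_names, p) -> NormalizedLaplacian:
    if network is None:
        return NormalizedLaplacian.zeros(feature_names)
    if isinstance(network, GeneNetwork):
        net = align_to_genes(network, feature_names)
        return build_normalized_laplacian(net)
    if isinstance(network, NormalizedLaplacian):
        L = network
    else:
        L = NormalizedLaplacian(matrix=np.asarray(network, dtype=float),
                                node_order=tuple(feature_names))
    if L.n_genes != p:
        raise ValueError(f"Laplacian is {L.n_genes} x {L.n_genes} but X has {p} features")
    if list(L.node_order) != list(feature_names):
        L = NormalizedLaplacian(matrix=L.matrix, node_order=tuple(feature_names))
    return L


class _NetworkBayesBase(BaseEstimator):
    def __init__(
        self,
        network=None,
        n_iter=6000,
        burn_in=None,
        thin=1,
        a=0.01, b=0.01, c=0.01, d=0.01, e=0.01, f=0.01,
        gig_index=1.0,
        ci_level=0.95,
        standardize=True,
        random_state=0,
    ):
        self.network = network
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.a = a
        self.b = b
        self.c = c
        self.d = d
        self.e = e
        self.f = f
        self.gig_index = gig_index
        self.ci_level = ci_level
        self.standardize = standardize
        self.random_state = random_state

    _fix_sigma2 = False
    _binary = False

    def _fit(self, X, y, feature_names=None):
        X, y = check_X_y(X, y, y_numeric=not self._binary)
        n, p = X.shape
        if feature_names is None:
            feature_names = getattr(self, "feature_names_in_", None)
            if feature_names is None:
                feature_names = [f"g{j}" for j in range(p)]
        feature_names = [str(g) for g in feature_names]

        if self.standardize:
            Xs, means, sds = standardize(X)
        else:
            Xs, means, sds = np.asarray(X, float), np.zeros(p), np.ones(p)
        self.X_mean_, self.X_sd_ = means, sds

        data = ExpressionDataset(
            X=Xs, y=y, gene_ids=feature_names,
            sample_ids=[f"s{i}" for i in range(n)],
            standardized=self.standardize,
        )
        hp = Hyperparameters(a=self.a, b=self.b, c=self.c, d=self.d, e=self.e, f=self.f)
        cfg = ChainConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            seed=self.random_state, gig_index=self.gig_index,
            fix_sigma2=self._fix_sigma2,
        )
        L = _resolve_laplacian(self.network, feature_names, p)
        runner = run_chain_binary if self._binary else run_chain
        self.chain_ = runner(data, L, hp=hp, cfg=cfg)
        self.ranking_ = summarize_chain(self.chain_, level=self.ci_level)
        self.coef_ = self.chain_.beta.mean(axis=0)
        self.sigma2_ = float(self.chain_.sigma2.mean())
        self.laplacian_ = L
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        return self

    def _transform_X(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} features; expected {self.n_features_in_}")
        return (X - self.X_mean_) / self.X_sd_

    def top_genes(self, k: int) -> list[str]:
        """The k genes with largest |posterior mean coefficient|."""
        check_is_fitted(self, "ranking_")
        return select_top_k(self.ranking_, k)


class NetworkBayesRegressor(RegressorMixin, _NetworkBayesBase):
    """Bayesian network-constrained shrinkage regression (Gaussian response).

    Parameters
    ----------
    network : GeneNetwork, NormalizedLaplacian, (p, p) array, or None
        Gene-interaction prior.  A :class:`GeneNetwork` is aligned to the
        feature names at fit time; ``None`` means no network (lasso-type
        shrinkage only).
    n_iter, burn_in, thin : int
        Chain length (default 6000), burn-in (default half) and thinning.
    a, b, c, d, e, f : float
        Prior shapes/rates for sigma^2, r and lambda^2 (default 0.01).
    gig_index : float
        Index of the GIG conditional for the latent scales (default 1).
    ci_level : float
        Credible-interval level for the gene ranking (default 0.95).
    standardize : bool
        Standardize columns of X at fit time (default True).
    random_state : int
        Seed; fits are bitwise reproducible.

    Attributes
    ----------
    coef_ : (p,) array — posterior mean coefficients.
    sigma2_ : float — posterior mean noise variance.
    ranking_ : GeneRanking — per-gene summary with credible intervals.
    chain_ : ChainResult — retained posterior draws.
    """

    def fit(self, X, y, feature_names=None):
        return self._fit(X, y, feature_names=feature_names)

    def predict(self, X):
        return self._transform_X(X) @ self.coef_


class NetworkBayesProbitClassifier(ClassifierMixin, _NetworkBayesBase):
    """Probit classifier with the network-constrained shrinkage prior.

    Binary labels must be coded 0/1.  ``fix_sigma2=True`` pins the latent
    noise variance at 1 (the conventional probit identification); by
    default it is sampled like every other parameter.  Other parameters
    and fitted attributes match :class:`NetworkBayesRegressor`.
    """

    def __init__(
        self,
        network=None,
        n_iter=6000,
        burn_in=None,
        thin=1,
        a=0.01, b=0.01, c=0.01, d=0.01, e=0.01, f=0.01,
        gig_index=1.0,
        ci_level=0.95,
        standardize=True,
        random_state=0,
        fix_sigma2=False,
    ):
        super().__init__(
            network=network, n_iter=n_iter, burn_in=burn_in, thin=thin,
            a=a, b=b, c=c, d=d, e=e, f=f, gig_index=gig_index,
            ci_level=ci_level, standardize=standardize, random_state=random_state,
        )
        self.fix_sigma2 = fix_sigma2

    _binary = True

    @property
    def _fix_sigma2(self):
        return self.fix_sigma2

    def fit(self, X, y, feature_names=None):
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be coded 0/1")
        self.classes_ = np.array([0, 1])
        return self._fit(X, y.astype(float), feature_names=feature_names)

    def predict_proba(self, X):
        p1 = predict_probability(self.coef_, self.sigma2_, self._transform_X(X))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self._transform_X(X) @ self.coef_ / np.sqrt(self.sigma2_)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
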