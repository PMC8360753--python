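"""Full-conditional samplers: distributional correctness and chain behavior.

Each 1-D conditional is checked against the quadrature-normalized density
read directly off the log joint; the multivariate beta conditional against
its closed-form Gaussian moments; and the sampler reductions with L = 0
and L = I against independently written lasso-form / elastic-net-form
conditional parameters.
"""

import numpy as np
import pytest
from scipy import stats

import reference as ref
from bnetreg.data import ExpressionDataset, standardize
from bnetreg.gibbs import (
    ChainConfig,
    _gig_rvs_scalar,
    gibbs_sweep,
    run_chain,
    sample_beta,
    sample_lambda2,
    sample_r,
    sample_sigma2,
    sample_tau2,
)
from bnetreg.graph import NormalizedLaplacian
from bnetreg.model import Hyperparameters, ModelState, compute_precision, log_joint
from bnetreg.simulate import SimulationScenario, simulate


class TestChainConfig:
    def test_defaults(self):
        cfg = ChainConfig()
        assert cfg.n_iter == 6000 and cfg.resolved_burn_in == 3000 and cfg.thin == 1

    @pytest.mark.parametrize("kw", [dict(n_iter=0), dict(burn_in=10, n_iter=10),
                                    dict(burn_in=-1), dict(thin=0)])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            ChainConfig(**kw)


class TestSampleBeta:
    def test_zero_design_gives_prior_mean_and_covariance(self, star_laplacian, rng):
        """With X = 0 the conditional is the prior N(0, (sigma2/r) Lambda^{-1})."""
        n, p = 12, 5
        state = ModelState(beta=np.zeros(p), sigma2=2.0, tau2=np.full(p, 1.5),
                           r=3.0, lambda2=1.0)
        X = np.zeros((n, p))
        y = rng.standard_normal(n)
        data = ExpressionDataset.__new__(ExpressionDataset)  # bypass checks for X=0
        data.X, data.y = X, y
        data.gene_ids = [f"g{i}" for i in range(p)]
        data.sample_ids = [f"s{i}" for i in range(n)]
        data.standardized = True
        draws = np.array([sample_beta(state, data, star_laplacian, rng)
                          for _ in range(20000)])
        Lam = compute_precision(state.tau2, star_laplacian).Lambda
        cov_expected = state.sigma2 / state.r * np.linalg.inv(Lam)
        se = np.sqrt(np.diag(cov_expected) / draws.shape[0])
        assert (np.abs(draws.mean(axis=0)) < 4 * se).all()
        np.testing.assert_allclose(np.cov(draws.T), cov_expected, atol=0.02)

    def test_moments_match_closed_form(self, rng):
        n, p = 30, 10
        X, _, _ = standardize(rng.standard_normal((n, p)))
        y = rng.standard_normal(n)
        data = ExpressionDataset(X=X, y=y, gene_ids=[f"g{i}" for i in range(p)],
                                 sample_ids=[f"s{i}" for i in range(n)], standardized=True)
        L = NormalizedLaplacian.zeros(data.gene_ids)
        state = ModelState(beta=np.zeros(p), sigma2=1.2, tau2=rng.uniform(0.5, 2, p),
                           r=1.7, lambda2=1.0)
        draws = np.array([sample_beta(state, data, L, rng) for _ in range(20000)])
        A = X.T @ X + state.r * np.diag(1.0 / state.tau2)
        mu = np.linalg.solve(A, X.T @ y)
        Sigma = state.sigma2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(Sigma) / draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - mu) < 4 * se).all()


class TestSampleSigma2:
    def test_zero_beta_rate_is_half_yty_plus_b(self, small_dataset, star_laplacian, rng):
        hp = Hyperparameters(a=2.0, b=0.5)
        state = ModelState.initial(5)
        draws = np.array([sample_sigma2(state, small_dataset, star_laplacian, hp, rng)
                          for _ in range(30000)])
        n, p = small_dataset.X.shape
        shape = (n + p) / 2 + hp.a
        rate = small_dataset.y @ small_dataset.y / 2 + hp.b
        expected_mean = rate / (shape - 1)
        sd = rate / ((shape - 1) * np.sqrt(shape - 2))
        assert abs(draws.mean() - expected_mean) < 4 * sd / np.sqrt(len(draws))

    def test_ks_against_quadrature_of_log_joint(self, small_dataset, star_laplacian,
                                                valid_state, rng):
        import dataclasses
        hp = Hyperparameters(a=1.0, b=1.0, c=1.0, d=1.0, e=1.0, f=1.0)
        draws = np.array([sample_sigma2(valid_state, small_dataset, star_laplacian, hp, rng)
                          for _ in range(10000)])

        def logdens(s2):
            st = dataclasses.replace(valid_state, sigma2=s2)
            return log_joint(st, small_dataset, star_laplacian, hp)

        cdf = ref.quadrature_cdf(logdens, draws.min() / 3, draws.max() * 3)
        res = stats.ks_1samp(draws, cdf)
        assert res.pvalue > 0.01


class TestSampleTau2:
    def test_zero_beta_reduces_to_exponential(self, star_laplacian, rng):
        state = ModelState(beta=np.zeros(5), sigma2=1.0, tau2=np.ones(5),
                           r=1.0, lambda2=2.5)
        draws = np.concatenate([sample_tau2(state, star_laplacian, rng)
                                for _ in range(4000)])
        res = stats.ks_1samp(draws, stats.expon(scale=2.0 / 2.5).cdf)
        assert res.pvalue > 0.01

    def test_ks_against_quadrature_of_log_joint(self, small_dataset, star_laplacian,
                                                valid_state):
        import dataclasses
        hp = Hyperparameters()
        j = 0
        rng = np.random.default_rng(3)
        draws = np.array([sample_tau2(valid_state, star_laplacian, rng)[j]
                          for _ in range(10000)])

        def logdens(t):
            tau2 = valid_state.tau2.copy()
            tau2[j] = t
            st = dataclasses.replace(valid_state, tau2=tau2)
            return log_joint(st, small_dataset, star_laplacian, hp)

        cdf = ref.quadrature_cdf(logdens, draws.min() / 5, draws.max() * 3)
        res = stats.ks_1samp(draws, cdf)
        assert res.pvalue > 0.01

    def test_stochastic_dominance_as_lambda2_decreases(self, star_laplacian, rng):
        """Smaller lambda2 => stochastically larger tau_j^2."""
        base = dict(beta=np.full(5, 0.8), sigma2=1.0, tau2=np.ones(5), r=1.0)
        lo = ModelState(**base, lambda2=0.5)
        hi = ModelState(**base, lambda2=3.0)
        d_lo = np.array([sample_tau2(lo, star_laplacian, rng)[0] for _ in range(10000)])
        d_hi = np.array([sample_tau2(hi, star_laplacian, rng)[0] for _ in range(10000)])
        grid = np.quantile(np.concatenate([d_lo, d_hi]), np.linspace(0.02, 0.98, 25))
        cdf_lo = np.array([(d_lo <= g).mean() for g in grid])
        cdf_hi = np.array([(d_hi <= g).mean() for g in grid])
        assert (cdf_lo <= cdf_hi + 0.02).all()

    def test_gig_sampler_matches_density_across_regimes(self, rng):
        """The log-concave rejection GIG sampler vs quadrature, including
        the tiny-omega regime where generic samplers fail."""
        for lam_idx, omega in [(1.0, 1e-5), (1.0, 0.5), (1.0, 50.0), (0.5, 2.0)]:
            draws = np.array([_gig_rvs_scalar(lam_idx, omega, rng) for _ in range(5000)])
            logd = np.log(draws)
            cdf = ref.quadrature_cdf(
                lambda t: lam_idx * t - omega * np.cosh(t),
                logd.min() - 2, logd.max() + 2,
            )
            assert stats.ks_1samp(logd, cdf).pvalue > 0.01


class TestSampleRAndLambda2:
    def test_r_zero_beta_recovers_prior_moments(self, star_laplacian, rng):
        hp = Hyperparameters(c=2.0, d=1.5)
        state = ModelState.initial(5)
        draws = np.array([sample_r(state, star_laplacian, hp, rng) for _ in range(30000)])
        shape, rate = 5 / 2 + hp.c, hp.d
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 4 * se

    def test_r_mean_matches_shape_over_rate(self, star_laplacian, valid_state, rng):
        hp = Hyperparameters(c=1.0, d=1.0)
        draws = np.array([sample_r(valid_state, star_laplacian, hp, rng)
                          for _ in range(30000)])
        Lam = compute_precision(valid_state.tau2, star_laplacian).Lambda
        shape = 5 / 2 + hp.c
        rate = valid_state.beta @ Lam @ valid_state.beta / (2 * valid_state.sigma2) + hp.d
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 4 * se

    def test_lambda2_mean_matches_shape_over_rate(self, valid_state, rng):
        hp = Hyperparameters(e=1.0, f=0.5)
        draws = np.array([sample_lambda2(valid_state, hp, rng) for _ in range(30000)])
        shape = 5 + hp.e
        rate = valid_state.tau2.sum() / 2 + hp.f
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 4 * se

    def test_lambda2_conditional_mean_decreases_with_tau2(self, rng):
        hp = Hyperparameters(e=1.0, f=1.0)
        s1 = ModelState(beta=np.zeros(5), sigma2=1.0, tau2=np.ones(5), r=1.0, lambda2=1.0)
        s2 = ModelState(beta=np.zeros(5), sigma2=1.0, tau2=2 * np.ones(5), r=1.0, lambda2=1.0)
        d1 = np.array([sample_lambda2(s1, hp, rng) for _ in range(5000)])
        d2 = np.array([sample_lambda2(s2, hp, rng) for _ in range(5000)])
        assert d2.mean() < d1.mean()


class TestSpecialCaseReductions:
    """With L = 0 the conditionals coincide with the Bayesian-Lasso-form
    ones; with L = I, with the Bayesian-Elastic-Net-form ones."""

    @pytest.fixture
    def setup(self, rng):
        n, p = 15, 4
        X, _, _ = standardize(rng.standard_normal((n, p)))
        y = rng.standard_normal(n)
        state = ModelState(beta=rng.normal(size=p), sigma2=0.9,
                           tau2=rng.uniform(0.5, 2, p), r=1.4, lambda2=0.8)
        return X, y, state

    def test_lasso_form_parameters(self, setup):
        X, y, st = setup
        hp = Hyperparameters(a=1.0, b=2.0, c=0.5, d=0.7, e=1.1, f=1.3)
        Lam = compute_precision(st.tau2, NormalizedLaplacian.zeros(list("abcd"))).Lambda
        mu_ref, Sig_ref = ref.lasso_beta_params(X, y, st.sigma2, st.tau2, st.r)
        A = X.T @ X + st.r * Lam
        np.testing.assert_allclose(np.linalg.solve(A, X.T @ y), mu_ref, atol=1e-10)
        np.testing.assert_allclose(st.sigma2 * np.linalg.inv(A), Sig_ref, atol=1e-10)

        sh_ref, ra_ref = ref.lasso_sigma2_params(X, y, st.beta, st.tau2, st.r, hp.a, hp.b)
        resid = y - X @ st.beta
        sh = (15 + 4) / 2 + hp.a
        ra = 0.5 * (resid @ resid + st.r * st.beta @ Lam @ st.beta) + hp.b
        assert sh == pytest.approx(sh_ref, abs=1e-10) and ra == pytest.approx(ra_ref, abs=1e-10)

        chi_ref, psi_ref = ref.lasso_tau2_params(st.beta, st.sigma2, st.r, st.lambda2)
        np.testing.assert_allclose(st.r * st.beta**2 / st.sigma2, chi_ref, atol=1e-12)
        assert st.lambda2 == psi_ref

        shr_ref, rar_ref = ref.lasso_r_params(st.beta, st.sigma2, st.tau2, hp.c, hp.d)
        assert 4 / 2 + hp.c == pytest.approx(shr_ref, abs=1e-12)
        assert st.beta @ Lam @ st.beta / (2 * st.sigma2) + hp.d == pytest.approx(rar_ref, abs=1e-10)

        shl_ref, ral_ref = ref.lasso_lambda2_params(st.tau2, hp.e, hp.f)
        assert 4 + hp.e == shl_ref and st.tau2.sum() / 2 + hp.f == pytest.approx(ral_ref)

    def test_elastic_net_form_parameters(self, setup):
        X, y, st = setup
        hp = Hyperparameters(a=1.0, b=2.0, c=0.5, d=0.7)
        Li = NormalizedLaplacian.identity(list("abcd"))
        Lam = compute_precision(st.tau2, Li).Lambda
        mu_ref, Sig_ref = ref.enet_beta_params(X, y, st.sigma2, st.tau2, st.r)
        A = X.T @ X + st.r * Lam
        np.testing.assert_allclose(np.linalg.solve(A, X.T @ y), mu_ref, atol=1e-10)
        np.testing.assert_allclose(st.sigma2 * np.linalg.inv(A), Sig_ref, atol=1e-10)

        sh_ref, ra_ref = ref.enet_sigma2_params(X, y, st.beta, st.tau2, st.r, hp.a, hp.b)
        resid = y - X @ st.beta
        ra = 0.5 * (resid @ resid + st.r * st.beta @ Lam @ st.beta) + hp.b
        assert ra == pytest.approx(ra_ref, abs=1e-10)

        shr_ref, rar_ref = ref.enet_r_params(st.beta, st.sigma2, st.tau2, hp.c, hp.d)
        assert st.beta @ Lam @ st.beta / (2 * st.sigma2) + hp.d == pytest.approx(rar_ref, abs=1e-10)


class TestRunChain:
    def test_same_seed_bitwise_identical(self, small_dataset, star_laplacian):
        cfg = ChainConfig(n_iter=200, seed=7)
        r1 = run_chain(small_dataset, star_laplacian, cfg=cfg)
        r2 = run_chain(small_dataset, star_laplacian, cfg=cfg)
        np.testing.assert_array_equal(r1.beta, r2.beta)
        np.testing.assert_array_equal(r1.log_joint_trace, r2.log_joint_trace)

    def test_different_seed_differs(self, small_dataset, star_laplacian):
        r1 = run_chain(small_dataset, star_laplacian, cfg=ChainConfig(n_iter=100, seed=1))
        r2 = run_chain(small_dataset, star_laplacian, cfg=ChainConfig(n_iter=100, seed=2))
        assert not np.array_equal(r1.beta, r2.beta)

    def test_draw_count_respects_burn_in_and_thin(self, small_dataset, star_laplacian):
        cfg = ChainConfig(n_iter=100, burn_in=40, thin=3, seed=0)
        res = run_chain(small_dataset, star_laplacian, cfg=cfg)
        assert res.n_draws == 20  # ceil(60 / 3)

    def test_log_joint_trace_finite_on_synthetic_instance(self):
        ds = simulate(SimulationScenario(n_pathways=6, genes_per_pathway=5,
                                         n_samples=50, seed=5))
        from bnetreg.graph import build_normalized_laplacian
        L = build_normalized_laplacian(ds.network)
        res = run_chain(ds.data, L, cfg=ChainConfig(n_iter=1000, seed=4))
        assert np.isfinite(res.log_joint_trace).all()

    def test_posterior_mean_shrinks_toward_not_past_least_squares(self, rng):
        """Orthogonal-ish design, strong signal: |posterior mean| below
        |OLS| componentwise (up to MC noise), same signs."""
        n, p = 200, 4
        X, _, _ = standardize(rng.standard_normal((n, p)))
        beta = np.array([2.0, -2.0, 1.5, -1.5])
        y = X @ beta + 0.5 * rng.standard_normal(n)
        data = ExpressionDataset(X=X, y=y, gene_ids=list("abcd"),
                                 sample_ids=[f"s{i}" for i in range(n)], standardized=True)
        L = NormalizedLaplacian.zeros(data.gene_ids)
        res = run_chain(data, L, cfg=ChainConfig(n_iter=1500, seed=11))
        pm = res.posterior_mean.beta
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert (np.sign(pm) == np.sign(ols)).all()
        assert (np.abs(pm) <= np.abs(ols) + 0.02).all()

    def test_recovers_true_beta_on_model_generated_data(self):
        ds = simulate(SimulationScenario(n_samples=100, seed=17))
        from bnetreg.graph import build_normalized_laplacian
        L = build_normalized_laplacian(ds.network)
        res = run_chain(ds.data, L, cfg=ChainConfig(n_iter=1500, seed=18))
        corr = np.corrcoef(res.posterior_mean.beta, ds.true_beta)[0, 1]
        assert corr >= 0.8

    def test_update_order_is_beta_sigma2_tau2_r_lambda2(self, small_dataset,
                                                        star_laplacian, default_hp):
        """One sweep from a fixed rng replays the five draws in order."""
        rng1 = np.random.default_rng(123)
        rng2 = np.random.default_rng(123)
        st0 = ModelState.initial(5)
        out = gibbs_sweep(st0, small_dataset.X, small_dataset.y, star_laplacian,
                          default_hp, rng1)
        import dataclasses
        beta = sample_beta(st0, small_dataset, star_laplacian, rng2)
        st = dataclasses.replace(st0, beta=beta)
        sigma2 = sample_sigma2(st, small_dataset, star_laplacian, default_hp, rng2)
        st = dataclasses.replace(st, sigma2=sigma2)
        tau2 = sample_tau2(st, star_laplacian, rng2)
        st = dataclasses.replace(st, tau2=tau2)
        r = sample_r(st, star_laplacian, default_hp, rng2)
        st = dataclasses.replace(st, r=r)
        lambda2 = sample_lambda2(st, default_hp, rng2)
        np.testing.assert_array_equal(out.beta, beta)
        assert out.sigma2 == sigma2
        np.testing.assert_array_equal(out.tau2, tau2)
        assert out.r == r and out.lambda2 == lambda2
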