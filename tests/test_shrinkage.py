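"""Gibbs sampler conditionals and end-to-end fits for the three prior regimes."""

import numpy as np
import pytest
from scipy import stats

from mixint.designs import CovariateMatrix, ExposureMatrix, build_linear_design
from mixint.robit import ModelSpec
from mixint.shrinkage import (
    PriorSpec,
    run_mcmc,
    sample_coefficients,
    sample_eta_independent,
    sample_eta_shared,
    sample_globals,
    sample_theta,
)
from mixint.simulate import simulate_study

from conftest import make_linear_truth


def gamma_tv_distance(draw_fn, shape, rate, rng, n=60_000):
    """TV distance between empirical draws and the claimed Gamma density."""
    draws = np.array([draw_fn(rng) for _ in range(n)])
    hi = stats.gamma(a=shape, scale=1 / rate).ppf(0.9999)
    hist, edges = np.histogram(draws, bins=150, range=(0, hi), density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    ref = stats.gamma(a=shape, scale=1 / rate).pdf(centers)
    return 0.5 * np.sum(np.abs(hist - ref)) * (edges[1] - edges[0])


class TestCoefficientDraw:
    def test_huge_prior_precision_pins_to_zero(self, rng):
        W = rng.normal(size=(40, 4))
        draws = np.array(
            [
                sample_coefficients(rng.normal(size=40), np.ones(40), W, np.full(4, 1e6), rng)
                for _ in range(50)
            ]
        )
        assert np.max(np.abs(draws)) < 0.02

    def test_flat_prior_mean_is_least_squares(self, rng):
        """P=0, lam=1: the conditional mean equals the OLS fit of xi on W."""
        W = rng.normal(size=(50, 6))
        xi = rng.normal(size=50)
        ols = np.linalg.lstsq(W, xi, rcond=None)[0]
        draws = np.array(
            [
                sample_coefficients(xi, np.ones(50), W, np.zeros(6), rng)
                for _ in range(4000)
            ]
        )
        cov = np.linalg.inv(W.T @ W)
        se = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(draws.mean(axis=0) - ols) < 5 * se)

    def test_sample_covariance_matches_analytic(self, rng):
        W = rng.normal(size=(60, 3))
        lam = rng.gamma(2.0, 1.0, size=60)
        P = np.full(3, 0.5)
        Q = W.T @ (W * lam[:, None]) + np.diag(P)
        target = np.linalg.inv(Q)
        draws = np.array(
            [
                sample_coefficients(np.zeros(60), lam, W, P, rng)
                for _ in range(8000)
            ]
        )
        emp = np.cov(draws.T)
        assert np.max(np.abs(emp - target)) < 0.05 * np.max(np.abs(target)) + 0.01

    def test_singular_precision_rejected(self, rng):
        col = rng.normal(size=30)
        W = np.column_stack([col, col])  # collinear, zero prior precision
        with pytest.raises(ValueError, match="singular"):
            sample_coefficients(rng.normal(size=30), np.ones(30), W, np.zeros(2), rng)


class TestGammaConditionals:
    def test_eta_independent_null_block(self, rng):
        """beta_j = 0, d = 1 -> Gamma(3/2, 1) with mean 1.5."""
        draws = np.array(
            [sample_eta_independent(np.zeros(1), 1.0, rng) for _ in range(50_000)]
        )
        assert draws.mean() == pytest.approx(1.5, abs=0.02)
        tv = gamma_tv_distance(
            lambda r: sample_eta_independent(np.zeros(1), 1.0, r), 1.5, 1.0, rng, n=50_000
        )
        assert tv < 0.02

    def test_large_effect_kills_shrinkage(self, rng):
        big = np.array([100.0])
        draws = np.array([sample_eta_independent(big, 1.0, rng) for _ in range(500)])
        assert np.all(draws < 0.01)

    def test_larger_eta_means_smaller_prior_variance(self):
        # prior variance of beta_j is 1/(a eta_j): monotone decreasing in eta
        a = 2.0
        assert 1 / (a * 4.0) < 1 / (a * 1.0)

    @pytest.mark.parametrize("d", [1, 2, 4])
    def test_theta_shared_scaling(self, d, rng):
        g = np.full(d, 0.5)
        b, ej, ek = 2.0, 1.5, 3.0
        shape = 1.0 + d / 2.0
        rate = 1.0 + 0.5 * b * ej * ek * float(g @ g)
        tv = gamma_tv_distance(
            lambda r: sample_theta(g, b, ej, ek, "shared", r), shape, rate, rng, n=40_000
        )
        assert tv < 0.02

    def test_eta_shared_p14_linear_shape(self, rng):
        """p=14, d_beta=d_gamma=1, all coefficients 0 -> Gamma(8, 1)."""
        gammas = [np.zeros(1)] * 13
        draws = np.array(
            [
                sample_eta_shared(
                    0, np.zeros(1), gammas, np.ones(13), np.ones(13), 1.0, 1.0, rng
                )
                for _ in range(50_000)
            ]
        )
        assert draws.mean() == pytest.approx(8.0, abs=0.05)
        assert draws.var() == pytest.approx(8.0, abs=0.25)

    def test_eta_shared_matches_grid_conditional(self, rng):
        """p=3 instance: rate pools the main block and both interaction blocks."""
        beta_j = np.array([0.7])
        gammas = [np.array([0.4]), np.array([-0.3])]
        etas = np.array([2.0, 0.5])
        thetas = np.array([1.2, 0.8])
        a, b = 1.5, 2.0
        shape = 1.0 + (1 + 2 * 1) / 2.0
        rate = (
            1.0
            + 0.5 * a * 0.49
            + 0.5 * b * etas[0] * thetas[0] * 0.16
            + 0.5 * b * etas[1] * thetas[1] * 0.09
        )
        tv = gamma_tv_distance(
            lambda r: sample_eta_shared(0, beta_j, gammas, etas, thetas, a, b, r),
            shape,
            rate,
            rng,
            n=40_000,
        )
        assert tv < 0.02

    def test_globals_null_shapes(self, rng):
        """All coefficients 0, linear p=14: a ~ Gamma(8, 1), b shape 46.5."""
        p = 14
        pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
        beta_blocks = [np.zeros(1)] * p
        gamma_blocks = [np.zeros(1)] * len(pairs)
        draws = np.array(
            [
                sample_globals(
                    beta_blocks, gamma_blocks, np.ones(p), np.ones(len(pairs)),
                    pairs, "shared", rng,
                )
                for _ in range(30_000)
            ]
        )
        assert draws[:, 0].mean() == pytest.approx(8.0, abs=0.06)
        assert draws[:, 1].mean() == pytest.approx(46.5, abs=0.2)


class TestRunMcmc:
    def _fit(self, study, prior_kind, seed=11, iters=600, burn=200):
        X = ExposureMatrix(study.exposures_true, study.exposures.chem_names)
        model = ModelSpec(
            parameterization="linear", iterations=iters, burn_in=burn, seed=seed
        )
        return run_mcmc(study.y, X, study.covariates, model, PriorSpec(kind=prior_kind))

    def test_fixed_seed_bit_identical(self, small_study):
        d1 = self._fit(small_study, "shared")
        d2 = self._fit(small_study, "shared")
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.eta, d2.eta)

    def test_vague_recovers_strong_truth(self, small_study):
        """n=500, p=2, true logit effects (1.0, -0.8): posterior within 3 SDs."""
        d = self._fit(small_study, "vague", iters=1500, burn=500)
        truth = np.array([1.0, -0.8])
        means = d.beta_logit.mean(axis=0)
        sds = d.beta_logit.std(axis=0)
        assert np.all(np.abs(means - truth) < 3 * sds)

    def test_vague_approximates_maximum_likelihood(self):
        """Posterior means within 0.1 of a logistic MLE at n=2000 (logit scale)."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = make_linear_truth(2000, 3, nonzero_main={0: 0.5, 1: -0.5}, nonzero_inter={(0, 1): 0.4})
        study = simulate_study(cfg, seed=21)
        d = self._fit(study, "vague", iters=2000, burn=500)
        D = build_linear_design(
            ExposureMatrix(study.exposures_true, study.exposures.chem_names)
        )
        W = np.hstack([study.covariates.values, D.main, D.interaction])
        ml = sm.Logit(study.y, W).fit(disp=0)
        post = np.concatenate(
            [d.alpha_logit.mean(0), d.beta_logit.mean(0), d.gamma_logit.mean(0)]
        )
        assert np.max(np.abs(post - ml.params)) < 0.1

    def test_shared_shrinks_null_interactions_harder_than_independent(self):
        """Heredity: with both parents null, the shared prior's posterior second
        moment for gamma_jk is smaller than the independent prior's (averaged
        over replicate fits)."""
        m2 = {"independent": [], "shared": []}
        for rep in range(6):
            cfg = make_linear_truth(300, 3, nonzero_main={2: 0.8})
            study = simulate_study(cfg, seed=100 + rep)
            for kind in m2:
                d = self._fit(study, kind, seed=rep, iters=500, burn=200)
                k01 = d.pairs.index((0, 1))  # both parents truly null
                m2[kind].append(np.mean(d.gamma[:, k01] ** 2))
        assert np.mean(m2["shared"]) < np.mean(m2["independent"])

    def test_nonfinite_dimensions_rejected(self, small_study):
        X = ExposureMatrix(small_study.exposures_true, small_study.exposures.chem_names)
        model = ModelSpec(iterations=10, burn_in=2, seed=0)
        with pytest.raises(ValueError, match="disagree"):
            run_mcmc(
                small_study.y[:-1], X, small_study.covariates, model, PriorSpec(kind="vague")
            )

    def test_draws_long_format_round_trip(self, small_study):
        d = self._fit(small_study, "shared", iters=300, burn=100)
        df = d.to_dataframe()
        assert set(df.columns) == {"iteration", "parameter", "value", "group", "scale"}
        wide = df[(df.group == "beta") & (df.scale == "logit")].pivot(
            index="iteration", columns="parameter", values="value"
        )
        np.testing.assert_allclose(
            wide[d.main_names].to_numpy(), d.beta_logit, rtol=1e-12
        )
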