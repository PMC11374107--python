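"""Latent-class functional model: memberships, weights, class coefficients."""

import numpy as np
import pytest

from mixint.designs import CovariateMatrix, ExposureMatrix
from mixint.latent_functional import (
    LatentClassConfig,
    class_probability_table,
    risk_curves,
    run_latentfun_mcmc,
    sample_class_coefficients,
    sample_membership,
    sample_weights,
)
from mixint.robit import ROBIT_LOGIT_SCALE
from mixint.simulate import simulate_study

from conftest import make_linear_truth


class TestSampleWeights:
    def test_concentrated_counts(self, rng):
        draws = np.array(
            [sample_weights(np.array([50, 0, 0]), rng) for _ in range(2000)]
        )
        assert draws[:, 0].mean() > 0.9

    def test_zero_counts_uniform(self, rng):
        draws = np.array([sample_weights(np.zeros(4), rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.01)

    def test_mean_matches_dirichlet_moments(self, rng):
        counts = np.array([3.0, 1.0, 0.0])
        draws = np.array([sample_weights(counts, rng) for _ in range(30_000)])
        expected = (1.0 + counts) / (1.0 + counts).sum()
        np.testing.assert_allclose(draws.mean(axis=0), expected, atol=0.01)


class TestSampleMembership:
    def test_single_class_always_label_zero(self, rng):
        blk = rng.normal(size=(20, 2))
        lab = sample_membership(
            blk, rng.normal(size=20), np.ones(20), rng.normal(size=(1, 2)),
            np.array([1.0]), rng,
        )
        assert lab == 0

    def test_identical_coefficients_follow_weights(self, rng):
        """Likelihood cancels, so P(label = 0) = omega_0."""
        blk = rng.normal(size=(30, 2))
        coefs = np.tile(rng.normal(size=2), (2, 1))
        w = np.array([0.3, 0.7])
        labs = [
            sample_membership(blk, rng.normal(size=30), np.ones(30), coefs, w, rng)
            for _ in range(5000)
        ]
        assert np.mean(np.array(labs) == 0) == pytest.approx(0.3, abs=0.03)

    def test_matches_enumerated_conditional(self, rng):
        """Sampling frequencies match the directly enumerated categorical law."""
        n, c, L = 40, 2, 3
        blk = rng.normal(size=(n, c))
        resid = rng.normal(size=n)
        lam = rng.gamma(2.0, 1.0, size=n)
        coefs = rng.normal(size=(L, c))
        w = np.array([0.5, 0.3, 0.2])
        logp = np.array(
            [
                np.log(w[l]) - 0.5 * np.sum(lam * (resid - blk @ coefs[l]) ** 2)
                for l in range(L)
            ]
        )
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        draws = np.array(
            [sample_membership(blk, resid, lam, coefs, w, rng) for _ in range(20_000)]
        )
        freq = np.bincount(draws, minlength=L) / draws.size
        np.testing.assert_allclose(freq, probs, atol=0.015)


class TestSampleClassCoefficients:
    def test_empty_class_draws_from_prior(self, rng):
        draws = np.array(
            [
                sample_class_coefficients([], np.zeros(5), np.ones(5), 10.0, rng, c=3)
                for _ in range(5000)
            ]
        )
        assert draws.std(axis=0) == pytest.approx([10.0] * 3, rel=0.06)

    def test_single_member_flat_prior_mean_is_least_squares(self, rng):
        W = rng.normal(size=(80, 3))
        resid = rng.normal(size=80)
        ls = np.linalg.lstsq(W, resid, rcond=None)[0]
        draws = np.array(
            [
                sample_class_coefficients([W], resid, np.ones(80), 1e6, rng)
                for _ in range(3000)
            ]
        )
        se = np.sqrt(np.diag(np.linalg.inv(W.T @ W)) / 3000)
        assert np.all(np.abs(draws.mean(axis=0) - ls) < 5 * se)

    def test_duplicate_members_equal_one_member_with_doubled_block(self, rng):
        """Summing member blocks: class {W, W} == single member with block 2W."""
        W = rng.normal(size=(30, 2))
        resid, lam = rng.normal(size=30), rng.gamma(2.0, 1.0, size=30)
        r1 = np.random.default_rng(9)
        r2 = np.random.default_rng(9)
        d_two = sample_class_coefficients([W, W], resid, lam, 10.0, r1)
        d_one = sample_class_coefficients([2 * W], resid, lam, 10.0, r2)
        np.testing.assert_allclose(d_two, d_one, rtol=1e-12)


@pytest.fixture(scope="module")
def two_class_study():
    """p=6 chemicals in two true dose-response classes (slopes +0.8 / -0.8)."""
    cfg = make_linear_truth(
        1000, 6, nonzero_main={0: 0.8, 1: 0.8, 2: 0.8, 3: -0.8, 4: -0.8, 5: -0.8}
    )
    return simulate_study(cfg, seed=5)


@pytest.fixture(scope="module")
def two_class_fit(two_class_study):
    st = two_class_study
    X = ExposureMatrix(st.exposures_true, st.exposures.chem_names)
    config = LatentClassConfig(L=5, M=5, c=3, iterations=1200, burn_in=500, seed=2)
    return run_latentfun_mcmc(st.y, X, st.covariates, config)


class TestRunLatentFun:
    def test_deterministic_given_seed(self, two_class_study):
        st = two_class_study
        X = ExposureMatrix(st.exposures_true, st.exposures.chem_names)
        cfg = LatentClassConfig(L=2, M=2, c=2, iterations=60, burn_in=20, seed=4)
        d1 = run_latentfun_mcmc(st.y, X, st.covariates, cfg)
        d2 = run_latentfun_mcmc(st.y, X, st.covariates, cfg)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.g, d2.g)

    def test_recovers_two_class_partition(self, two_class_fit):
        """Modal co-assignment separates the +slope and -slope chemicals."""
        co = np.zeros((6, 6))
        for row in two_class_fit.g:
            co += row[:, None] == row[None, :]
        co /= two_class_fit.n_draws
        within = [co[a, b] for grp in ([0, 1, 2], [3, 4, 5]) for a in grp for b in grp if a < b]
        across = [co[a, b] for a in (0, 1, 2) for b in (3, 4, 5)]
        assert min(within) > 0.8
        assert max(across) < 0.2

    def test_superfluous_classes_nearly_empty(self, two_class_fit):
        table = class_probability_table(two_class_fit)
        assert table["omega"].iloc[3:].sum() < 0.02  # occupancy beyond rank 3
        assert table["psi"].iloc[3:].sum() < 0.02

    def test_effective_coefficients_are_class_lookups(self, two_class_fit):
        d = two_class_fit
        eff = d.effective_main_coefficients()
        s, j = 7, 3
        np.testing.assert_array_equal(eff[s, j], d.beta[s, d.g[s, j]])

    def test_label_permutation_leaves_predictor_invariant(self, two_class_fit, rng):
        """Permuting class labels with matching coefficient rows changes nothing
        observable: the effective coefficients are identical."""
        d = two_class_fit
        perm = rng.permutation(d.config.L)
        beta_p = d.beta[:, perm, :]
        g_p = np.argsort(perm)[d.g]  # relabelled assignments
        eff_orig = d.effective_main_coefficients()
        eff_perm = np.take_along_axis(beta_p, g_p[:, :, None], axis=1)
        np.testing.assert_array_equal(eff_orig, eff_perm)

    def test_invalid_class_counts_rejected(self, two_class_study):
        st = two_class_study
        X = ExposureMatrix(st.exposures_true, st.exposures.chem_names)
        with pytest.raises(ValueError, match="L <= p"):
            run_latentfun_mcmc(
                st.y, X, st.covariates, LatentClassConfig(L=7, M=2, iterations=10, burn_in=2)
            )


class TestClassProbabilityTable:
    def test_single_class_probability_one(self, two_class_study):
        st = two_class_study
        X = ExposureMatrix(st.exposures_true, st.exposures.chem_names)
        cfg = LatentClassConfig(L=1, M=1, c=1, iterations=60, burn_in=20, seed=0)
        d = run_latentfun_mcmc(st.y, X, st.covariates, cfg)
        table = class_probability_table(d)
        assert table["omega"].iloc[0] == 1.0
        assert table["psi"].iloc[0] == 1.0

    def test_occupancies_sum_to_one(self, two_class_fit):
        table = class_probability_table(two_class_fit)
        assert table["omega"].sum() == pytest.approx(1.0)
        assert table["psi"].sum() == pytest.approx(1.0)
        assert table["omega_weight"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_weights_sorted_descending(self, two_class_fit):
        table = class_probability_table(two_class_fit)
        assert (np.diff(table["omega"]) <= 1e-12).all()


class TestEquivalenceAndCurves:
    def test_single_class_linear_collapses_to_pooled_logistic(self):
        """L=M=1, c=1 ties every chemical to one slope: the fit matches a
        logistic MLE on the pooled (summed) standardized columns."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = make_linear_truth(1500, 3, nonzero_main={0: 0.5, 1: 0.5, 2: 0.5})
        st = simulate_study(cfg, seed=12)
        X = ExposureMatrix(st.exposures_true, st.exposures.chem_names)
        lcfg = LatentClassConfig(L=1, M=1, c=1, iterations=1500, burn_in=500, seed=3)
        d = run_latentfun_mcmc(st.y, X, st.covariates, lcfg)
        xs = st.exposures_true / np.abs(st.exposures_true).max(axis=0)
        from mixint.designs import build_linear_design

        D = build_linear_design(X)
        zs = D.interaction / np.abs(D.interaction).max(axis=0)
        Us = st.covariates.values.copy()
        Us[:, 1:] = (Us[:, 1:] - Us[:, 1:].mean(0)) / Us[:, 1:].std(0)
        W = np.column_stack([Us, xs.sum(axis=1), zs.sum(axis=1)])
        ml = sm.Logit(st.y, W).fit(disp=0)
        beta_logit = d.beta[:, 0, 0].mean() * ROBIT_LOGIT_SCALE
        gamma_logit = d.gamma[:, 0, 0].mean() * ROBIT_LOGIT_SCALE
        assert beta_logit == pytest.approx(ml.params[-2], abs=0.1)
        assert gamma_logit == pytest.approx(ml.params[-1], abs=0.1)

    def test_zero_coefficient_draws_flat_zero_curve(self, two_class_fit):
        d = two_class_fit
        saved = d.beta.copy(), d.gamma.copy()
        try:
            d.beta[:] = 0.0
            d.gamma[:] = 0.0
            curve = risk_curves(d, "main", 0, np.linspace(*d.x_range[0], 5))
            np.testing.assert_array_equal(curve["mean"], 0.0)
            np.testing.assert_array_equal(curve["upper"] - curve["lower"], 0.0)
        finally:
            d.beta[:], d.gamma[:] = saved

    def test_linear_truth_recovered_within_hpd(self, two_class_fit, two_class_study):
        """Chemical 0 has true logit slope +0.8 and a linear dose-response;
        the posterior curve's HPD band covers the straight line."""
        d = two_class_fit
        grid = np.linspace(-1.5, 1.5, 7)
        curve = risk_curves(d, "main", 0, grid)
        truth = 0.8 * grid
        assert np.all(curve["lower"] <= truth + 1e-9)
        assert np.all(curve["upper"] >= truth - 1e-9)

    def test_extrapolation_warns(self, two_class_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            risk_curves(two_class_fit, "main", 0, np.linspace(-100, 100, 3))
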