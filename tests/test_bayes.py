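"""Conjugate NIG regression: exact identities, oracles, and estimator API."""

import numpy as np
import pytest
from scipy import integrate, stats

from treecomp.bayes import (
    BayesianLinearRegression,
    FitResult,
    MvtParams,
    NIGParams,
    marginal_beta,
    marginal_sigma,
    nig_update,
    posterior_predictive,
    predictive_marginals,
    residuals,
    rmse,
)


def scalar_oracle():
    """Hand-computed posterior for X = (1,1,1)', y = (1,2,3), NIG(0,1,1,1).

    Worked through the update equations with plain arithmetic:
    precision = 1 + 3 = 4, mu* = 6/4, V* = 1/4, a* = 1 + 3/2 = 5/2,
    b* = 1 + (0 + 14 - (6/4)^2 * 4)/2 = 1 + (14 - 9)/2 = 7/2.
    """
    prior = NIGParams(np.array([0.0]), np.array([[1.0]]), 1.0, 1.0)
    X = np.ones((3, 1))
    y = np.array([1.0, 2.0, 3.0])
    return prior, X, y, (1.5, 0.25, 2.5, 3.5)


class TestNigUpdate:
    def test_empty_data_returns_prior(self):
        prior = NIGParams(np.zeros(2), np.eye(2), 1.0, 2.0)
        post = nig_update(prior, np.empty((0, 2)), np.empty(0))
        np.testing.assert_array_equal(post.mu, prior.mu)
        np.testing.assert_array_equal(post.V, prior.V)
        assert (post.a, post.b) == (prior.a, prior.b)

    def test_scalar_hand_computed_example(self):
        prior, X, y, (mu, V, a, b) = scalar_oracle()
        post = nig_update(prior, X, y)
        assert post.mu[0] == pytest.approx(mu)
        assert post.V[0, 0] == pytest.approx(V)
        assert post.a == pytest.approx(a)
        assert post.b == pytest.approx(b)

    def test_flat_prior_limit_is_least_squares(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        prior = NIGParams(np.zeros(2), 1e8 * np.eye(2), 0.01, 0.01)
        post = nig_update(prior, X, y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(post.mu, beta_ols, atol=1e-6)

    def test_sequential_equals_batch(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=20)
        prior = NIGParams(np.zeros(3), 4.0 * np.eye(3), 2.0, 1.0)
        batch = nig_update(prior, X, y)
        seq = nig_update(nig_update(prior, X[:8], y[:8]), X[8:], y[8:])
        np.testing.assert_allclose(seq.mu, batch.mu, atol=1e-8)
        np.testing.assert_allclose(seq.V, batch.V, atol=1e-8)
        assert seq.a == pytest.approx(batch.a, abs=1e-12)
        assert seq.b == pytest.approx(batch.b, abs=1e-8)

    def test_posterior_b_positive_and_a_grows(self, rng):
        prior = NIGParams(np.zeros(2), np.eye(2), 0.01, 0.01)
        X = rng.normal(size=(30, 2))
        y = X @ np.array([2.0, -1.0])  # perfect fit stresses b* cancellation
        post = nig_update(prior, X, y)
        assert post.b > 0
        assert post.a == prior.a + 15.0

    def test_dimension_mismatch_errors(self):
        prior = NIGParams(np.zeros(2), np.eye(2), 1.0, 1.0)
        with pytest.raises(ValueError):
            nig_update(prior, np.ones((3, 2)), np.ones(4))
        with pytest.raises(ValueError):
            nig_update(prior, np.ones((3, 3)), np.ones(3))


class TestMarginals:
    def test_beta_marginal_parameters(self):
        nig = NIGParams(np.array([1.0, 2.0]), 2.0 * np.eye(2), 3.0, 3.0)
        t = marginal_beta(nig)
        np.testing.assert_array_equal(t.loc, nig.mu)
        np.testing.assert_allclose(t.shape, nig.V)  # a == b -> shape = V
        assert t.dof == 6.0

    def test_sigma_marginal_is_prior_pair(self):
        nig = NIGParams(np.zeros(1), np.eye(1), 1.5, 2.5)
        assert marginal_sigma(nig) == (1.5, 2.5)

    def test_beta_density_matches_quadrature_over_sigma2(self):
        """t marginal at a point == integral of the joint NIG over sigma^2."""
        prior, X, y, _ = scalar_oracle()
        post = nig_update(prior, X, y)
        t = marginal_beta(post)
        point = float(post.mu[0])

        def joint(s2):
            norm = stats.norm.pdf(point, loc=post.mu[0], scale=np.sqrt(s2 * post.V[0, 0]))
            ig = stats.invgamma.pdf(s2, post.a, scale=post.b)
            return norm * ig

        quad, _ = integrate.quad(joint, 0, np.inf)
        assert np.exp(t.logpdf([point])) == pytest.approx(quad, rel=1e-6)

    def test_sigma_posterior_mean_matches_monte_carlo(self, rng):
        prior, X, y, _ = scalar_oracle()
        post = nig_update(prior, X, y)
        a, b = marginal_sigma(post)
        draws = stats.invgamma.rvs(a, scale=b, size=10**6, random_state=rng)
        assert b / (a - 1) == pytest.approx(draws.mean(), rel=0.01)


class TestPosteriorPredictive:
    def test_zero_row_gives_prior_predictive_scale(self):
        nig = NIGParams(np.array([2.0]), np.array([[3.0]]), 2.0, 4.0)
        pred = posterior_predictive(nig, np.zeros((1, 1)))
        assert pred.loc[0] == 0.0
        assert pred.shape[0, 0] == pytest.approx(nig.b / nig.a)
        assert pred.dof == 2 * nig.a

    def test_location_is_linear_predictor(self):
        prior, X, y, _ = scalar_oracle()
        post = nig_update(prior, X, y)
        pred = posterior_predictive(post, X)
        np.testing.assert_allclose(pred.loc, X @ post.mu)

    def test_marginals_agree_with_full_joint(self, rng):
        post = nig_update(
            NIGParams(np.zeros(2), np.eye(2), 2.0, 2.0),
            rng.normal(size=(12, 2)),
            rng.normal(size=12),
        )
        Xnew = rng.normal(size=(4, 2))
        full = posterior_predictive(post, Xnew)
        loc, scale, dof = predictive_marginals(post, Xnew)
        np.testing.assert_allclose(loc, full.loc)
        np.testing.assert_allclose(scale, np.sqrt(np.diag(full.shape)))
        assert dof == full.dof

    def test_mean_and_variance_match_joint_sampling(self, rng):
        """MC oracle: draw (beta, sigma^2) from the posterior, then y."""
        prior, X, y, _ = scalar_oracle()
        post = nig_update(prior, X, y)
        xnew = np.array([[1.0]])
        n_mc = 200_000
        s2 = stats.invgamma.rvs(post.a, scale=post.b, size=n_mc, random_state=rng)
        beta = post.mu[0] + np.sqrt(s2 * post.V[0, 0]) * rng.standard_normal(n_mc)
        y_draw = beta + np.sqrt(s2) * rng.standard_normal(n_mc)
        pred = posterior_predictive(post, xnew)
        var = pred.cov()[0, 0]
        mc_mean_se = y_draw.std() / np.sqrt(n_mc)
        assert pred.loc[0] == pytest.approx(y_draw.mean(), abs=3 * mc_mean_se)
        mc_var_se = np.var((y_draw - y_draw.mean()) ** 2) ** 0.5 / np.sqrt(n_mc)
        assert var == pytest.approx(y_draw.var(), abs=3 * mc_var_se)


class TestRmse:
    def test_perfect_fit_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_analytic_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_two_pass_computation(self, rng):
        y = rng.normal(size=100)
        yhat = rng.normal(size=100)
        total = 0.0
        for a, b in zip(y, yhat):
            total += (a - b) ** 2
        assert rmse(y, yhat) == pytest.approx(np.sqrt(total / 100))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestResiduals:
    def test_perfect_fit_and_row_count(self, small_forest):
        _, _, _, asm = small_forest
        ds = asm.dataset
        fit = FitResult(
            posterior=NIGParams(np.zeros(1), np.eye(1), 1.0, 1.0),
            fitted=ds.y.copy(),
            rmse_insample=0.0,
        )
        tab = residuals(fit, ds)
        assert len(tab) == len(ds)
        np.testing.assert_allclose(tab["residual"], 0.0)

    def test_constant_model_flat_prior_residual_mean_zero(self, rng):
        """OLS orthogonality: intercept-only residuals average to zero."""
        n = 50
        y = rng.normal(0.2, 0.1, size=n)
        post = nig_update(
            NIGParams(np.zeros(1), np.array([[1e8]]), 0.01, 0.01), np.ones((n, 1)), y
        )
        resid = y - (np.ones((n, 1)) @ post.mu)
        assert resid.mean() == pytest.approx(0.0, abs=1e-6)


class TestEstimatorApi:
    def test_fit_predict_and_params_round_trip(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([0.5, -1.0, 2.0]) + 0.1 * rng.standard_normal(40)
        est = BayesianLinearRegression(V0=1e6)
        assert est.get_params()["V0"] == 1e6
        est.set_params(V0=1e8).fit(X, y)
        assert est.posterior_.p == 3
        np.testing.assert_allclose(est.predict(X), X @ est.coef_)
        iv = est.coef_interval(0.95)
        assert iv.shape == (3, 2)
        assert np.all(iv[:, 0] < est.coef_) and np.all(est.coef_ < iv[:, 1])

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = BayesianLinearRegression(a0=0.5)
        assert clone(est).get_params() == est.get_params()
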