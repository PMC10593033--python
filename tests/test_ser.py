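"""Single-effect regression: closed form vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

from susie2 import SERInput, fit_ser, log_bayes_factor


def quadrature_log_bf(x, y, sigma2, sigma02):
    """Oracle: log BF by 1-D numerical integration over the effect size.

    BF = int N(y; x b, sigma2 I) N(b; 0, sigma02) db / N(y; 0, sigma2 I);
    the null likelihood is factored out inside the integrand for numerical
    stability, so the integral itself is the Bayes factor.
    """

    def integrand(b):
        ll_ratio = (2 * (x @ y) * b - (x @ x) * b**2) / (2 * sigma2)
        return np.exp(ll_ratio) * norm.pdf(b, 0.0, np.sqrt(sigma02))

    lim = 12 * np.sqrt(sigma02)
    val, _ = quad(integrand, -lim, lim, limit=200)
    return np.log(val)


def enumeration_alpha(X, y, sigma2, sigma02, prior):
    """Oracle: posterior over single-causal-variant models by enumerating
    the p marginal likelihoods N(y; 0, sigma2 I + sigma02 x_j x_j^T)."""
    n, p = X.shape
    logml = np.empty(p)
    for j in range(p):
        cov = sigma2 * np.eye(n) + sigma02 * np.outer(X[:, j], X[:, j])
        logml[j] = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
    w = np.log(prior) + logml
    w -= w.max()
    a = np.exp(w)
    return a / a.sum()


class TestLogBayesFactor:
    def test_zero_prior_variance_is_null(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        assert log_bayes_factor(x, y, sigma2=1.3, sigma02=0.0) == 0.0

    def test_orthogonal_data_penalizes_model(self):
        # x'y = 0 carries no signal, so the larger model can only lose
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert log_bayes_factor(x, y, sigma2=1.0, sigma02=0.5) < 0.0

    def test_constant_predictor_convention(self, rng):
        y = rng.standard_normal(6)
        assert log_bayes_factor(np.zeros(6), y, 1.0, 0.7) == 0.0

    @pytest.mark.parametrize("sigma2,sigma02", [(1.0, 0.5), (0.7, 2.0)])
    def test_matches_quadrature(self, rng, sigma2, sigma02):
        x = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        x = (x - x.mean()) / x.std()
        y = rng.standard_normal(5) + 0.6 * x
        lbf = log_bayes_factor(x, y, sigma2, sigma02)
        assert lbf == pytest.approx(
            quadrature_log_bf(x, y, sigma2, sigma02), abs=1e-8
        )

    def test_rejects_bad_hyperparameters(self, rng):
        x, y = rng.standard_normal((2, 5))
        with pytest.raises(ValueError):
            log_bayes_factor(x, y, sigma2=0.0, sigma02=1.0)
        with pytest.raises(ValueError):
            log_bayes_factor(x, y, sigma2=1.0, sigma02=-1.0)
        with pytest.raises(ValueError):
            log_bayes_factor(np.array([np.nan, 1.0]), y[:2], 1.0, 1.0)


class TestFitSER:
    def test_degenerate_prior_wins_regardless_of_data(self, toy_regression):
        X, y, _ = toy_regression
        prior = np.zeros(X.shape[1])
        prior[3] = 1.0
        fit = fit_ser(SERInput(X=X, y=y, prior=prior))
        assert fit.alpha[3] == pytest.approx(1.0)
        assert np.all(fit.alpha[np.arange(8) != 3] == 0.0)

    def test_duplicate_columns_split_mass_symmetrically(self, rng):
        X = rng.standard_normal((30, 4))
        X[:, 1] = X[:, 0]
        y = X[:, 0] + 0.3 * rng.standard_normal(30)
        fit = fit_ser(SERInput(X=X, y=y))
        assert fit.alpha[0] == pytest.approx(fit.alpha[1], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 4
        X = rng.standard_normal((n, p))
        y = 0.5 * X[:, 2] + rng.standard_normal(n)
        prior = rng.dirichlet(np.ones(p))
        inp = SERInput(X=X, y=y, sigma2=1.0, sigma02=0.4, prior=prior)
        fit = fit_ser(inp)
        oracle = enumeration_alpha(inp.X, inp.y, 1.0, 0.4, prior)
        np.testing.assert_allclose(fit.alpha, oracle, atol=1e-8)
        assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-10)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 50))
            p = int(rng.integers(1, 8))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            inp = SERInput(X=X, y=y, sigma2=0.8, sigma02=1.1)
            fit = fit_ser(inp)
            oracle = enumeration_alpha(
                inp.X, inp.y, 0.8, 1.1, np.full(p, 1.0 / p)
            )
            np.testing.assert_allclose(fit.alpha, oracle, atol=1e-8)

    def test_prior_renormalized_with_warning(self, toy_regression):
        X, y, _ = toy_regression
        with pytest.warns(UserWarning, match="renormalizing"):
            fit = fit_ser(SERInput(X=X, y=y, prior=np.full(8, 2.0)))
        assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-10)

    def test_negative_prior_rejected(self, toy_regression):
        X, y, _ = toy_regression
        prior = np.full(8, 0.2)
        prior[0] = -0.4
        with pytest.raises(ValueError, match="negative"):
            SERInput(X=X, y=y, prior=prior)

    def test_posterior_variance_positive_when_slab_open(self, toy_regression):
        X, y, _ = toy_regression
        fit = fit_ser(SERInput(X=X, y=y, sigma02=0.3))
        assert np.all(fit.sigma1_sq > 0)


class TestSERProperties:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        sigma02=st.floats(0.01, 3.0),
        j=st.integers(0, 5),
    )
    def test_normalization_and_prior_monotonicity(self, seed, sigma02, j):
        """alpha sums to one, and raising pi_j never lowers alpha_j."""
        rng = np.random.default_rng(seed)
        n, p = 25, 6
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        base = np.full(p, 1.0 / p)
        fit = fit_ser(SERInput(X=X, y=y, sigma02=sigma02, prior=base))
        assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-10)
        boosted = base.copy()
        boosted[j] *= 5.0
        boosted /= boosted.sum()
        fit2 = fit_ser(SERInput(X=X, y=y, sigma02=sigma02, prior=boosted))
        assert fit2.alpha[j] >= fit.alpha[j] - 1e-12

    def test_scaling_law(self, rng):
        """Scaling y -> s*y with sigma2 -> s^2 sigma2, sigma02 -> s^2 sigma02
        leaves alpha unchanged (X standardized either way)."""
        n, p, s = 40, 5, 3.7
        X = rng.standard_normal((n, p))
        y = X[:, 1] + rng.standard_normal(n)
        f1 = fit_ser(SERInput(X=X, y=y, sigma2=1.0, sigma02=0.5))
        f2 = fit_ser(
            SERInput(X=X, y=s * y, sigma2=s**2, sigma02=0.5 * s**2)
        )
        np.testing.assert_allclose(f1.alpha, f2.alpha, atol=1e-12)
        np.testing.assert_allclose(f1.mu1 * s, f2.mu1, atol=1e-10)
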