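"""SuSiE/IBSS: reductions, enumeration oracles, credible sets, invariants."""

import numpy as np
import pytest
from itertools import combinations, product

from scipy.special import logsumexp
from scipy.stats import multivariate_normal, spearmanr

from susie2 import (
    SERInput,
    SuSiEConfig,
    combine_pips,
    credible_sets,
    fit_ser,
    fit_susie,
    suggest_K,
)
from susie2.ser import _center_standardize

from conftest import assert_monotone_objective


def bma_pip_subsets(X, y, sigma2, sigma02, max_size):
    """Oracle: exact Bayesian model averaging over all causal subsets of
    size <= max_size with independent N(0, sigma02) effects and a uniform
    prior over subsets; PIP_j = sum of posterior weights of models
    containing j."""
    n, p = X.shape
    logml, models = [], []
    for size in range(max_size + 1):
        for S in combinations(range(p), size):
            cov = sigma2 * np.eye(n)
            for j in S:
                cov += sigma02 * np.outer(X[:, j], X[:, j])
            logml.append(
                multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
            )
            models.append(S)
    w = np.array(logml)
    w = np.exp(w - logsumexp(w))
    pip = np.zeros(p)
    for wt, S in zip(w, models):
        for j in S:
            pip[j] += wt
    return pip / w.sum()


def susie_prior_bma_pip(X, y, sigma2, sigma02, K):
    """Oracle: exact posterior under the sum-of-single-effects prior by
    enumerating all p^K ordered effect assignments."""
    n, p = X.shape
    logml = np.empty([p] * K)
    for idx in product(range(p), repeat=K):
        cov = sigma2 * np.eye(n)
        for j in idx:
            cov += sigma02 * np.outer(X[:, j], X[:, j])
        logml[idx] = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
    w = np.exp(logml - logsumexp(logml))
    w /= w.sum()
    pip = np.zeros(p)
    for idx in product(range(p), repeat=K):
        for j in set(idx):
            pip[j] += w[idx]
    return pip


class TestReductions:
    def test_k1_equals_ser(self, toy_regression):
        """With one effect and fixed hyperparameters, SuSiE is exactly SER."""
        X, y, _ = toy_regression
        cfg = SuSiEConfig(
            K=1, estimate_sigma2=False, estimate_sigma02=False,
            sigma2=1.0, sigma02=0.5,
        )
        fit = fit_susie(X, y, config=cfg)
        ser = fit_ser(SERInput(X=X, y=y, sigma2=1.0, sigma02=0.5))
        np.testing.assert_allclose(fit.pip, ser.alpha, atol=1e-12)
        assert_monotone_objective(fit)

    def test_k_truncated_to_p_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="truncating"):
            fit = fit_susie(X, y, config=SuSiEConfig(K=8))
        assert fit.alpha.shape[0] == 3


class TestNullData:
    def test_pure_noise_reports_nothing(self):
        """Noise-only data: no credible sets pass purity and no variant is
        confidently included — confirmed against exhaustive BMA."""
        rng = np.random.default_rng(11)
        n, p = 100, 8
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        fit = fit_susie(X, y, config=SuSiEConfig(K=3))
        assert fit.credible_sets == []
        assert fit.pip.max() < 0.95
        assert_monotone_objective(fit)
        Xs, ys = _center_standardize(X, y, True, True)
        oracle = bma_pip_subsets(Xs, ys, 1.0, 0.2, max_size=3)
        assert oracle.max() < 0.95


class TestSignalRecovery:
    def test_two_strong_signals_match_bma_oracle(self):
        """Top-PIP variants equal the truth; PIPs rank-correlate with the
        exact sum-of-single-effects posterior."""
        rng = np.random.default_rng(5)
        n, p = 120, 8
        X = rng.standard_normal((n, p))
        y = 0.35 * X[:, 2] - 0.3 * X[:, 5] + rng.standard_normal(n)
        cfg = SuSiEConfig(
            K=2, estimate_sigma2=False, estimate_sigma02=False,
            sigma2=1.0, sigma02=0.5,
        )
        fit = fit_susie(X, y, config=cfg)
        assert set(np.argsort(fit.pip)[-2:]) == {2, 5}
        Xs, ys = _center_standardize(X, y, True, True)
        oracle = bma_pip_subsets(Xs, ys, 1.0, 0.5, max_size=2)
        assert set(np.argsort(oracle)[-2:]) == {2, 5}
        rho, _ = spearmanr(fit.pip, oracle)
        assert rho >= 0.9
        assert_monotone_objective(fit)

    def test_strong_signals_match_ordered_assignment_oracle(self):
        """With strong effects, IBSS PIPs agree with the exact posterior
        under the sum-of-single-effects prior itself (all p^K ordered
        effect assignments enumerated)."""
        rng = np.random.default_rng(5)
        n, p = 200, 8
        X = rng.standard_normal((n, p))
        y = 0.9 * X[:, 2] - 0.7 * X[:, 5] + rng.standard_normal(n)
        cfg = SuSiEConfig(
            K=2, estimate_sigma2=False, estimate_sigma02=False,
            sigma2=1.0, sigma02=0.5,
        )
        fit = fit_susie(X, y, config=cfg)
        Xs, ys = _center_standardize(X, y, True, True)
        oracle = susie_prior_bma_pip(Xs, ys, 1.0, 0.5, K=2)
        np.testing.assert_allclose(fit.pip, oracle, atol=1e-6)


class TestCombinePips:
    def test_single_alpha_unchanged(self, rng):
        a = rng.dirichlet(np.ones(6))
        np.testing.assert_allclose(combine_pips([a]), a)

    def test_half_half_gives_three_quarters(self):
        a = np.array([0.5, 0.0])
        assert combine_pips([a, a])[0] == pytest.approx(0.75)
        assert combine_pips([a, a])[1] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_pips([])

    def test_bounds_against_individual_alphas(self, rng):
        A = rng.dirichlet(np.ones(10), size=4)
        pip = combine_pips(list(A))
        assert np.all(pip >= A.max(axis=0) - 1e-12)
        assert np.all(pip <= A.sum(axis=0) + 1e-12)


class TestCredibleSets:
    def test_cumulative_prefix(self):
        alpha = np.array([[0.90, 0.05, 0.03, 0.02]])
        R = np.eye(4)
        (cs,) = credible_sets(alpha, R, rho=0.95, purity_threshold=0.0)
        assert set(cs.variant_indices) == {0, 1}
        assert cs.claimed_coverage >= 0.95

    def test_uniform_alpha_takes_95_members(self):
        alpha = np.full((1, 100), 0.01)
        (cs,) = credible_sets(alpha, np.eye(100), rho=0.95,
                              purity_threshold=0.0)
        assert len(cs) == 95

    def test_low_purity_set_dropped(self):
        alpha = np.array([[0.5, 0.48, 0.02]])
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.1
        assert credible_sets(alpha, R, rho=0.95, purity_threshold=0.5) == []

    def test_purity_requires_r(self):
        alpha = np.array([[0.5, 0.5]])
        with pytest.raises(ValueError, match="required"):
            credible_sets(alpha, None, rho=0.95, purity_threshold=0.5)

    def test_duplicate_sets_reported_once(self):
        alpha = np.array([[0.99, 0.01], [0.99, 0.01]])
        sets = credible_sets(alpha, np.eye(2), rho=0.95, purity_threshold=0.0)
        assert len(sets) == 1


class TestSuggestK:
    def test_null_data_returns_one(self, rng):
        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        assert suggest_K(X, y) == 1

    def test_single_strong_signal(self, rng):
        X = rng.standard_normal((300, 10))
        y = 1.2 * X[:, 4] + rng.standard_normal(300)
        K = suggest_K(X, y)
        assert K in (1, 2)

    def test_three_independent_signals(self):
        rng = np.random.default_rng(42)
        n = 800
        X = rng.standard_normal((n, 12))
        y = (
            0.8 * X[:, 1] + 0.8 * X[:, 5] + 0.8 * X[:, 9]
            + rng.standard_normal(n)
        )
        # each marginal z-score is far beyond 8
        assert suggest_K(X, y) == 3


class TestInvariants:
    def test_permutation_equivariance(self, toy_regression):
        X, y, _ = toy_regression
        p = X.shape[1]
        prior = np.arange(1, p + 1, dtype=float)
        prior /= prior.sum()
        perm = np.random.default_rng(0).permutation(p)
        f1 = fit_susie(X, y, prior=prior, config=SuSiEConfig(K=3))
        f2 = fit_susie(
            X[:, perm], y, prior=prior[perm], config=SuSiEConfig(K=3)
        )
        np.testing.assert_allclose(f1.pip[perm], f2.pip, atol=1e-9)

    def test_objective_monotone_across_random_fits(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 120, 15
            X = rng.standard_normal((n, p))
            beta = np.zeros(p)
            beta[: seed + 1] = 0.5
            y = X @ beta + rng.standard_normal(n)
            fit = fit_susie(X, y, config=SuSiEConfig(K=5))
            assert_monotone_objective(fit)

    def test_nonconvergence_warns_not_raises(self, toy_regression):
        X, y, _ = toy_regression
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_susie(
                X, y, config=SuSiEConfig(K=3, max_iter=1, tol=1e-12)
            )
        assert fit.converged is False
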