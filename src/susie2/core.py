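"""Sum of single effects (SuSiE) regression fitted by IBSS.

The SuSiE model stacks ``K`` single-effect regressions additively,

.. math::

    y = X b + e, \\qquad b = \\sum_{k=1}^K b_k, \\qquad
    b_k = \\lambda_k c_k, \\quad c_k \\sim \\mathrm{Mult}(1, \\pi),
    \\quad \\lambda_k \\sim N(0, \\sigma_{0k}^2),

and is fitted by iterative Bayesian stepwise selection (IBSS): each effect
``b_k`` is updated by fitting an exact SER model to the residual obtained
by removing the posterior-mean contributions of all other effects.  The
combined per-variant posterior inclusion probability is
``PIP_j = 1 - prod_k (1 - alpha_kj)``, and each effect yields a level-rho
credible set: the smallest top-alpha prefix with cumulative posterior mass
>= rho, reported only if its members are in sufficiently strong mutual LD
(purity filter).

Everything here is expressed in sufficient statistics (X'X, X'y, y'y, n),
which makes the individual-level and summary-statistics code paths
algebraically identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .ser import SERFit, _center_standardize, _lbf_suff, _ser_posterior, _validate_prior
from scipy.special import logsumexp

__all__ = [
    "SuSiEConfig",
    "SuSiEFit",
    "CredibleSet",
    "fit_susie",
    "fit_susie_suff",
    "combine_pips",
    "credible_sets",
    "suggest_K",
]


@dataclass
class SuSiEConfig:
    """Hyperparameters and fitting policy for a SuSiE fit.

    Parameters
    ----------
    K
        Assumed number of single effects. SuSiE is robust to overstating K;
        inactive effects shrink to zero prior variance.
    max_iter, tol
        IBSS stops when the variational objective (ELBO) changes by less
        than ``tol`` between sweeps, or after ``max_iter`` sweeps.
    estimate_sigma2, estimate_sigma02
        Estimate the residual variance (ELBO-maximizing update each sweep)
        and the per-effect prior variances (1-D empirical-Bayes
        maximization, floored at 0).  When disabled, ``sigma2`` /
        ``sigma02`` are held at their initial values.
    sigma2, sigma02
        Initial (or fixed) values; ``None`` defaults to ``var(y)`` and
        ``0.2 * var(y)`` respectively.
    coverage_rho
        Credible-set coverage level rho.
    purity_threshold
        Minimum absolute pairwise correlation required among members of a
        reported credible set.
    ld_ridge
        Diagonal ridge applied to LD matrices in summary mode.
    """

    K: int = 10
    max_iter: int = 200
    tol: float = 1e-4
    estimate_sigma2: bool = True
    estimate_sigma02: bool = True
    sigma2: float | None = None
    sigma02: float | None = None
    coverage_rho: float = 0.95
    purity_threshold: float = 0.5
    ld_ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.coverage_rho < 1:
            raise ValueError("coverage_rho must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CredibleSet:
    """A level-rho credible set produced by one single effect."""

    variant_indices: np.ndarray  # sorted by decreasing alpha
    effect_index: int
    claimed_coverage: float
    min_abs_corr: float

    def __len__(self) -> int:
        return len(self.variant_indices)


@dataclass
class SuSiEFit:
    """Fitted SuSiE model.

    ``alpha``/``mu1``/``sigma1_sq`` are (K, p) stacks of per-effect SER
    posteriors; ``pip`` combines the active effects as
    ``1 - prod_k (1 - alpha_kj)``.  ``active[k]`` is False for effects whose
    prior variance was shrunk to zero (their alpha equals the prior and
    they contribute neither PIPs nor credible sets).
    """

    alpha: np.ndarray
    mu1: np.ndarray
    sigma1_sq: np.ndarray
    pip: np.ndarray
    sigma2: float
    sigma02: np.ndarray
    credible_sets: list[CredibleSet]
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    prior: np.ndarray
    active: np.ndarray
    lbf_model: np.ndarray = field(default=None)  # per-effect log BF vs null

    @property
    def ser_fits(self) -> list[SERFit]:
        """Per-effect SER posteriors as SERFit records."""
        return [
            SERFit(
                alpha=self.alpha[k],
                mu1=self.mu1[k],
                sigma1_sq=self.sigma1_sq[k],
                log_bf=None,
                log_bf_model=None if self.lbf_model is None else self.lbf_model[k],
            )
            for k in range(self.alpha.shape[0])
        ]


def combine_pips(alphas: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Combine per-effect PIP vectors: ``1 - prod_k (1 - alpha_k)``."""
    A = np.atleast_2d(np.asarray(alphas, dtype=float))
    if A.size == 0 or len(A) == 0:
        raise ValueError("combine_pips requires at least one alpha vector")
    if np.any(A < -1e-12) or np.any(A > 1 + 1e-12):
        raise ValueError("alpha entries must lie in [0, 1]")
    return 1.0 - np.prod(1.0 - np.clip(A, 0.0, 1.0), axis=0)


def _single_cs(alpha_k: np.ndarray, rho: float) -> tuple[np.ndarray, float]:
    """Smallest top-alpha prefix with cumulative mass >= rho.

    Ties in alpha are broken by variant index for determinism.
    """
    p = alpha_k.size
    order = np.lexsort((np.arange(p), -alpha_k))
    csum = np.cumsum(alpha_k[order])
    cut = int(np.searchsorted(csum, rho - 1e-12)) + 1
    cut = min(cut, p)
    return order[:cut], float(csum[cut - 1])


def _purity(members: np.ndarray, R: np.ndarray | None) -> float:
    if len(members) == 1:
        return 1.0
    if R is None:
        raise ValueError(
            "an LD/correlation matrix R is required for purity filtering"
        )
    sub = np.abs(R[np.ix_(members, members)])
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].min())


def credible_sets(
    fit: "SuSiEFit | np.ndarray",
    R: np.ndarray | None,
    rho: float = 0.95,
    purity_threshold: float = 0.5,
) -> list[CredibleSet]:
    """Level-rho credible sets from a fitted SuSiE model.

    One candidate set per active effect (smallest top-alpha prefix with
    cumulative mass >= rho); sets whose minimum absolute pairwise
    correlation falls below ``purity_threshold`` are discarded, and
    duplicate sets across effects are reported once.
    """
    if isinstance(fit, SuSiEFit):
        alphas = fit.alpha
        active = fit.active
    else:
        alphas = np.atleast_2d(np.asarray(fit, dtype=float))
        active = np.ones(len(alphas), dtype=bool)
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    out: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for k in range(len(alphas)):
        if not active[k]:
            continue
        members, cov = _single_cs(alphas[k], rho)
        key = frozenset(int(j) for j in members)
        if key in seen:
            continue
        if purity_threshold > 0 or R is not None:
            purity = _purity(members, R)
        else:
            purity = 1.0
        if purity < purity_threshold:
            continue
        seen.add(key)
        out.append(
            CredibleSet(
                variant_indices=members,
                effect_index=k,
                claimed_coverage=cov,
                min_abs_corr=purity,
            )
        )
    return out


def _optimize_prior_variance(
    d: np.ndarray,
    XtR: np.ndarray,
    sigma2: float,
    log_pi: np.ndarray,
    current: float,
    vy: float,
) -> float:
    """Empirical-Bayes update of one effect's prior variance.

    Maximizes the SER model log Bayes factor ``log sum_j pi_j BF_j(v)``
    over v >= 0.  Candidates are v = 0 (null), the current value, and a
    bounded 1-D optimum on the log scale; the null wins unless a positive
    candidate strictly beats it, which floors inactive effects at exactly
    zero.  Including the current value makes the update monotone in the
    ELBO.
    """

    def f(v: float) -> float:
        return float(logsumexp(log_pi + _lbf_suff(d, XtR, sigma2, v)))

    lo, hi = np.log(1e-10 * vy + 1e-300), np.log(1e3 * vy + 1e-300)
    res = minimize_scalar(
        lambda lv: -f(np.exp(lv)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-2},  # 1% on the log scale is ample for an EB point estimate
    )
    candidates = [float(np.exp(res.x))]
    if current > 0:
        candidates.append(current)
    best_v, best_f = 0.0, 0.0  # f(0) = log sum pi_j = 0
    for v in candidates:
        fv = f(v)
        if fv > best_f:
            best_v, best_f = v, fv
    return best_v


def _kl_effect(
    alpha: np.ndarray,
    mu1: np.ndarray,
    s1: np.ndarray,
    pi: np.ndarray,
    sigma02: float,
) -> float:
    """Exact KL(q_k || prior_k) over the pair (c, lambda).

    q_k factorizes as alpha (categorical) times a Gaussian per category;
    the prior is pi times N(0, sigma02).  Effects with sigma02 = 0 hold
    q = prior, so their KL is zero.
    """
    if sigma02 <= 0:
        return 0.0
    mask = alpha > 0
    a = alpha[mask]
    kl_cat = float(np.sum(a * (np.log(a) - np.log(pi[mask]))))
    kl_gauss = 0.5 * np.sum(
        a
        * (
            np.log(sigma02 / s1[mask])
            + (s1[mask] + mu1[mask] ** 2) / sigma02
            - 1.0
        )
    )
    return kl_cat + float(kl_gauss)


def fit_susie_suff(
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    prior: np.ndarray | None = None,
    config: SuSiEConfig | None = None,
    R: np.ndarray | None = None,
) -> SuSiEFit:
    """Fit SuSiE from sufficient statistics (X'X, X'y, y'y, n) by IBSS.

    ``R`` is the correlation matrix used for credible-set purity; if
    omitted it is derived from ``XtX``.  The variational objective (ELBO)
    is recorded each sweep and is non-decreasing.
    """
    config = config or SuSiEConfig()
    XtX = np.asarray(XtX, dtype=float)
    Xty = np.asarray(Xty, dtype=float)
    p = Xty.size
    if XtX.shape != (p, p):
        raise ValueError("XtX must be p x p and match Xty")
    if p == 0:
        raise ValueError("no variants supplied")
    pi = (
        np.full(p, 1.0 / p)
        if prior is None
        else _validate_prior(np.asarray(prior, float), p)
    )
    K = config.K
    if K > p:
        warnings.warn(f"K={K} exceeds p={p}; truncating K to p")
        K = p
    log_pi = np.full(p, -np.inf)
    log_pi[pi > 0] = np.log(pi[pi > 0])
    d = np.ascontiguousarray(np.diag(XtX)).astype(float)
    vy = yty / n
    sigma2 = float(config.sigma2) if config.sigma2 is not None else vy
    s02_init = (
        float(config.sigma02) if config.sigma02 is not None else 0.2 * vy
    )
    sigma02 = np.full(K, s02_init)
    alpha = np.tile(pi, (K, 1))
    mu1 = np.zeros((K, p))
    mu2 = np.zeros((K, p))
    s1sq = np.zeros((K, p))
    lbf_model = np.zeros(K)
    XtXB = np.zeros((K, p))  # XtX @ (alpha_k * mu1_k) per effect
    XtXb_tot = np.zeros(p)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        for k in range(K):
            XtR = Xty - XtXb_tot + XtXB[k]
            if config.estimate_sigma02:
                sigma02[k] = _optimize_prior_variance(
                    d, XtR, sigma2, log_pi, sigma02[k], vy
                )
            if sigma02[k] > 0:
                a, m1, s1, _, lbf_m = _ser_posterior(
                    d, XtR, sigma2, sigma02[k], log_pi
                )
            else:
                a, m1, s1 = pi.copy(), np.zeros(p), np.zeros(p)
                lbf_m = 0.0
            alpha[k], mu1[k], s1sq[k] = a, m1, s1
            mu2[k] = m1**2 + s1
            lbf_model[k] = lbf_m
            new = XtX @ (a * m1)
            XtXb_tot += new - XtXB[k]
            XtXB[k] = new
        # expected residual sum of squares under the variational posterior
        bbar = np.sum(alpha * mu1, axis=0)
        erss = (
            yty
            - 2.0 * bbar @ Xty
            + bbar @ XtXb_tot
            - float(np.einsum("kj,kj->", alpha * mu1, XtXB))
            + float(np.sum(alpha * mu2 * d))
        )
        erss = max(erss, 1e-300)
        kl = sum(
            _kl_effect(alpha[k], mu1[k], s1sq[k], pi, sigma02[k])
            for k in range(K)
        )
        elbo = (
            -0.5 * n * np.log(2.0 * np.pi * sigma2)
            - erss / (2.0 * sigma2)
            - kl
        )
        trace.append(float(elbo))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
        if config.estimate_sigma2:
            sigma2 = max(erss / n, 1e-12)
    if not converged:
        warnings.warn(
            f"IBSS did not converge in {config.max_iter} iterations"
        )
    active = sigma02 > 0
    if active.any():
        pip = combine_pips(alpha[active])
    else:
        pip = np.zeros(p)
    if R is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.sqrt(np.outer(d, d))
            R = np.divide(XtX, scale, out=np.zeros_like(XtX), where=scale > 0)
    fit = SuSiEFit(
        alpha=alpha,
        mu1=mu1,
        sigma1_sq=s1sq,
        pip=pip,
        sigma2=float(sigma2),
        sigma02=sigma02,
        credible_sets=[],
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
        prior=pi,
        active=active,
        lbf_model=lbf_model,
    )
    fit.credible_sets = credible_sets(
        fit, R, rho=config.coverage_rho, purity_threshold=config.purity_threshold
    )
    return fit


def fit_susie(
    X: np.ndarray,
    y: np.ndarray,
    prior: np.ndarray | None = None,
    config: SuSiEConfig | None = None,
    center: bool = True,
    standardize: bool = True,
) -> SuSiEFit:
    """Fit SuSiE to individual-level data by IBSS.

    ``y`` and the columns of ``X`` are centered; columns of ``X`` are
    standardized to unit variance by default.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be n x p and y length n")
    X, y = _center_standardize(X, y, center, standardize)
    n = X.shape[0]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    return fit_susie_suff(XtX, Xty, yty, n, prior=prior, config=config)


def suggest_K(
    X: np.ndarray,
    y: np.ndarray,
    prior: np.ndarray | None = None,
    config: SuSiEConfig | None = None,
    K_max: int = 10,
) -> int:
    """Smallest K at which the number of credible sets stops increasing.

    Fits with K = 1, 2, ... and stops as soon as the count of
    purity-passing credible sets fails to grow, returning the previous K.
    """
    config = config or SuSiEConfig()
    prev = None
    for K in range(1, K_max + 1):
        cfg = SuSiEConfig(
            **{**config.__dict__, "K": K}
        )
        n_cs = len(fit_susie(X, y, prior=prior, config=cfg).credible_sets)
        if prev is not None and n_cs <= prev:
            return K - 1
        prev = n_cs
    return K_max
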