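"""Single-effect regression (SER): the Bayesian building block of SuSiE.

The SER model assumes exactly one of ``p`` candidate predictors carries a
nonzero effect:

.. math::

    y = X b + e, \\qquad e \\sim N(0, \\sigma^2 I_n),

    b = \\lambda c, \\qquad c \\sim \\mathrm{Mult}(1, \\pi),
    \\qquad \\lambda \\sim N(0, \\sigma_0^2),

where ``pi`` is the prior probability that each variable is the effect
variable and ``sigma2``/``sigma02`` are fixed hyperparameters (residual
variance and prior effect variance).  The posterior is available in closed
form: the indicator ``c`` is multinomial with weights

.. math::

    \\alpha_j = \\frac{\\pi_j \\, \\mathrm{BF}_j}{\\sum_{j'} \\pi_{j'}
    \\mathrm{BF}_{j'}},

where ``BF_j`` is the Bayes factor of the univariate regression of ``y`` on
``x_j`` against the null model ``b = 0``, and the effect size given
``c_j = 1`` is Gaussian with posterior mean ``mu1[j]`` and variance
``sigma1_sq[j]``.  ``alpha`` is the vector of per-variant posterior
inclusion probabilities (PIPs) for a single causal signal.

All arithmetic is carried out in log space with log-sum-exp normalization
so that the posterior is computable at GWAS scale (p in the tens of
thousands) without underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["SERInput", "SERFit", "log_bayes_factor", "fit_ser"]


def _validate_prior(prior: np.ndarray, p: int) -> np.ndarray:
    """Validate and normalize a prior inclusion-probability vector."""
    pi = np.asarray(prior, dtype=float)
    if pi.shape != (p,):
        raise ValueError(f"prior has shape {pi.shape}, expected ({p},)")
    if not np.all(np.isfinite(pi)):
        raise ValueError("prior contains non-finite entries")
    if np.any(pi < 0):
        raise ValueError("prior contains negative entries")
    total = pi.sum()
    if total <= 0:
        raise ValueError("prior sums to zero")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"prior sums to {total:.6g}; renormalizing to 1", stacklevel=3
        )
    return pi / total


def _center_standardize(
    X: np.ndarray, y: np.ndarray, center: bool, standardize: bool
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    if center:
        X -= X.mean(axis=0)
        y = y - y.mean()
    if standardize:
        sd = X.std(axis=0)
        nz = sd > 0
        X[:, nz] /= sd[nz]  # constant columns stay as-is (zero after centering)
    return X, y


@dataclass
class SERInput:
    """Data and hyperparameters for a single-effect regression.

    ``y`` and the columns of ``X`` are centered internally (the model has no
    intercept); columns of ``X`` are standardized to unit variance by
    default (``standardize=False`` disables this).  ``prior`` defaults to
    the uniform vector ``(1/p, ..., 1/p)``.
    """

    X: np.ndarray
    y: np.ndarray
    sigma2: float = 1.0
    sigma02: float = 1.0
    prior: np.ndarray | None = None
    center: bool = True
    standardize: bool = True
    pi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if X.shape[1] < 1:
            raise ValueError("X must have at least one column (p >= 1)")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least two samples (n >= 2)")
        if y.shape != (n,):
            raise ValueError(f"y has shape {y.shape}, expected ({n},)")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X/y contain non-finite values")
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise ValueError("sigma2 must be finite and > 0")
        if not np.isfinite(self.sigma02) or self.sigma02 < 0:
            raise ValueError("sigma02 must be finite and >= 0")
        self.X, self.y = _center_standardize(X, y, self.center, self.standardize)
        if self.prior is None:
            self.pi = np.full(p, 1.0 / p)
        else:
            self.pi = _validate_prior(self.prior, p)


@dataclass
class SERFit:
    """Exact SER posterior: ``SER(X, y, sigma2, sigma02) = (alpha, mu1, sigma1_sq)``.

    Attributes
    ----------
    alpha
        Posterior inclusion probabilities; sums to 1.
    mu1, sigma1_sq
        Posterior mean / variance of the effect size given ``c_j = 1``.
    log_bf
        Per-variant log Bayes factor against the null.
    log_bf_model
        Log of the prior-weighted average Bayes factor (evidence for the
        SER model versus the null).
    """

    alpha: np.ndarray
    mu1: np.ndarray
    sigma1_sq: np.ndarray
    log_bf: np.ndarray
    log_bf_model: float


def _lbf_suff(
    xtx: np.ndarray, xty: np.ndarray, sigma2: float, sigma02: float
) -> np.ndarray:
    """Vectorized log Bayes factor from per-variant sufficient statistics.

    Marginally ``y ~ N(0, sigma2 I + sigma02 x x^T)`` under the univariate
    model, giving

        lbf = 0.5 log(sigma2 / (sigma2 + sigma02 xtx))
              + 0.5 sigma02 (x^T y)^2 / (sigma2 (sigma2 + sigma02 xtx)).

    Zero-variance predictors (xtx == 0) get lbf = 0 by convention: they
    carry no information, so the prior decides.
    """
    out = np.zeros_like(np.asarray(xtx, dtype=float))
    if sigma02 <= 0:
        return out
    mask = xtx > 0
    v = sigma2 + sigma02 * xtx[mask]
    out[mask] = 0.5 * np.log(sigma2 / v) + 0.5 * sigma02 * xty[mask] ** 2 / (
        sigma2 * v
    )
    return out


def _ser_posterior(
    xtx: np.ndarray,
    xty: np.ndarray,
    sigma2: float,
    sigma02: float,
    log_pi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Closed-form SER posterior from sufficient statistics.

    ``log_pi`` must be the log of a normalized prior, with ``-inf`` at
    zero-prior entries.  Returns (alpha, mu1, sigma1_sq, log_bf,
    log_bf_model).
    """
    lbf = _lbf_suff(xtx, xty, sigma2, sigma02)
    with np.errstate(invalid="ignore"):
        logw = log_pi + lbf
    log_bf_model = float(logsumexp(logw))
    alpha = np.exp(logw - log_bf_model)
    alpha[np.isneginf(logw)] = 0.0
    alpha /= alpha.sum()
    if sigma02 > 0:
        # posterior precision = xtx/sigma2 + 1/sigma02; constant columns
        # fall back to the prior
        sigma1_sq = np.where(
            xtx > 0, sigma02 * sigma2 / (sigma2 + sigma02 * xtx), sigma02
        )
        mu1 = sigma1_sq * xty / sigma2
    else:
        sigma1_sq = np.zeros_like(alpha)
        mu1 = np.zeros_like(alpha)
    return alpha, mu1, sigma1_sq, lbf, log_bf_model


def log_bayes_factor(
    x: np.ndarray, y: np.ndarray, sigma2: float, sigma02: float
) -> float:
    """Log Bayes factor of ``y = x b + e`` with ``b ~ N(0, sigma02)`` vs ``b = 0``.

    Computed in closed form from the sufficient statistics ``x^T x`` and
    ``x^T y``.  ``sigma02 = 0`` collapses the alternative onto the null and
    returns 0; an all-zero ``x`` returns 0 by the same no-information
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x/y contain non-finite values")
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError("sigma2 must be finite and > 0")
    if not np.isfinite(sigma02) or sigma02 < 0:
        raise ValueError("sigma02 must be finite and >= 0")
    xtx = np.array([float(x @ x)])
    xty = np.array([float(x @ y)])
    return float(_lbf_suff(xtx, xty, sigma2, sigma02)[0])


def fit_ser(inp: SERInput) -> SERFit:
    """Exact posterior for the single-effect regression model."""
    X, y = inp.X, inp.y
    xtx = np.einsum("ij,ij->j", X, X)
    xty = X.T @ y
    log_pi = np.full(xtx.shape, -np.inf)
    pos = inp.pi > 0
    log_pi[pos] = np.log(inp.pi[pos])
    alpha, mu1, s1, lbf, lbf_model = _ser_posterior(
        xtx, xty, inp.sigma2, inp.sigma02, log_pi
    )
    return SERFit(
        alpha=alpha, mu1=mu1, sigma1_sq=s1, log_bf=lbf, log_bf_model=lbf_model
    )
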