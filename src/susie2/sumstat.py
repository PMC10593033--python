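"""Fine-mapping from GWAS summary statistics.

SuSiE only touches the data through the sufficient statistics
(X'X, X'y, y'y, n).  Under the standardized-variable convention (columns
of X scaled to x_j'x_j = n; trait variance ``var_y``) these can be
reconstructed exactly from per-variant z-scores, the sample size, and an
LD correlation matrix R:

    X'X = n R,          y'y = n var_y,
    x_j'y = sign(z_j) sqrt( z_j^2 n y'y / (n - 2 + z_j^2) ),

where the inversion assumes z-scores are the usual OLS t-statistics of the
marginal regressions (residual df = n - 2).  With the in-sample R this
reproduces the individual-level fit to numerical precision; with an
external reference panel R the fit degrades gracefully, which is the
realistic use case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SuSiEConfig, SuSiEFit, fit_susie_suff
from .ser import _center_standardize

__all__ = [
    "SummaryData",
    "zscores",
    "summary_from_individual",
    "regularize_ld",
    "sufficient_stats_from_summary",
    "fit_susie_ss",
]


def zscores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marginal OLS z-scores (bhat / se, residual df = n - 2) per column.

    ``X`` columns are centered/standardized and ``y`` centered, matching
    the conventions of the individual-level fitters.
    """
    X, y = _center_standardize(
        np.asarray(X, float), np.asarray(y, float), True, True
    )
    n = X.shape[0]
    xtx = np.einsum("ij,ij->j", X, X)
    xty = X.T @ y
    yty = float(y @ y)
    with np.errstate(divide="ignore", invalid="ignore"):
        bhat = xty / xtx
        rss = yty - xty**2 / xtx
        se = np.sqrt(rss / (n - 2) / xtx)
        z = np.where(xtx > 0, bhat / se, 0.0)
    return z


@dataclass
class SummaryData:
    """Per-variant association summaries plus an LD matrix.

    Either ``z`` or the pair (``bhat``, ``shat``) must be supplied; the
    latter is converted to z-scores.  ``R`` is the p x p LD correlation
    matrix (symmetric, unit diagonal) in the same variant order; ``n`` is
    the GWAS sample size and ``var_y`` the trait variance (1 for a
    standardized trait).
    """

    R: np.ndarray
    n: int
    z: np.ndarray | None = None
    bhat: np.ndarray | None = None
    shat: np.ndarray | None = None
    var_y: float = 1.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = self.R.shape[0]
        if self.R.shape != (p, p):
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("R must have unit diagonal")
        if self.z is None:
            if self.bhat is None or self.shat is None:
                raise ValueError("supply z, or both bhat and shat")
            bhat = np.asarray(self.bhat, float)
            shat = np.asarray(self.shat, float)
            if np.any(shat <= 0):
                raise ValueError("shat must be positive")
            self.z = bhat / shat
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (p,):
            raise ValueError("z length must match R")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")
        if self.n <= 2:
            raise ValueError("n must exceed 2")
        if self.var_y <= 0:
            raise ValueError("var_y must be positive")


def regularize_ld(R: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Add a diagonal ridge to R and rescale so the diagonal stays 1."""
    R = np.asarray(R, dtype=float)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0:
        return R
    p = R.shape[0]
    return (R + ridge * np.eye(p)) / (1.0 + ridge)


def sufficient_stats_from_summary(
    data: SummaryData,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Reconstruct (X'X, X'y, y'y, n) from summary data.

    Exact when R is the in-sample correlation of standardized X and the
    z-scores are df = n - 2 OLS statistics; see the module docstring for
    the algebra.

    Raises a numerical error (with advice to increase the ridge) if R has
    eigenvalues below -1e-8 after regularization.
    """
    n = int(data.n)
    z = data.z
    yty = n * data.var_y
    XtX = n * data.R
    min_eig = float(np.linalg.eigvalsh(data.R)[0])
    if min_eig < -1e-8:
        raise np.linalg.LinAlgError(
            f"LD matrix is not PSD (min eigenvalue {min_eig:.3g}); "
            "increase the ridge regularization (SuSiEConfig.ld_ridge)"
        )
    Xty = np.sign(z) * np.sqrt(z**2 * n * yty / (n - 2 + z**2))
    return XtX, Xty, float(yty), n


def summary_from_individual(X: np.ndarray, y: np.ndarray) -> SummaryData:
    """In-sample summary data (z-scores + LD) from individual-level data."""
    X, y = _center_standardize(
        np.asarray(X, float), np.asarray(y, float), True, True
    )
    n = X.shape[0]
    R = (X.T @ X) / n
    np.fill_diagonal(R, 1.0)  # exact for standardized, non-constant columns
    return SummaryData(R=R, n=n, z=zscores(X, y), var_y=float(y @ y) / n)


def fit_susie_ss(
    data: SummaryData,
    prior: np.ndarray | None = None,
    config: SuSiEConfig | None = None,
) -> SuSiEFit:
    """Fit SuSiE from summary statistics.

    Runs the identical IBSS loop on sufficient statistics reconstructed
    from (z, n, R).  The (ridge-regularized) R is also used for
    credible-set purity.
    """
    config = config or SuSiEConfig()
    R = regularize_ld(data.R, config.ld_ridge)
    reg = SummaryData(R=R, n=data.n, z=data.z, var_y=data.var_y)
    XtX, Xty, yty, n = sufficient_stats_from_summary(reg)
    return fit_susie_suff(
        XtX, Xty, yty, n, prior=prior, config=config, R=R
    )
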