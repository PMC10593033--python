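"""Generative simulator: block-LD genotypes, expression, and a trait.

Genotypes are a threshold-Gaussian haplotype-block surrogate for real LD:
within each block of ``ld_block_size`` variants, two latent haplotype
vectors follow an AR(1) Gaussian process with lag-one correlation
``ld_rho``; each is thresholded at a per-variant minor-allele-frequency
quantile, and the genotype is their sum (0/1/2).  Blocks are mutually
independent and columns are standardized.

Phenotypes follow an additive two-layer model over ``L`` risk loci whose
windows partition the variant space.  Per locus ``l``, ``M_e`` causal
eQTL SNPs drive a gene expression level

    Y_el = sum_i beta_eli X_i + e_l,

with genetic variance ``h2_e`` and Var(Y_el) = 1.  The trait combines a
direct genetic component over ``M_t`` causal SNPs (``M_t / L`` per locus,
half of each locus's eQTL SNPs being trait-causal too), a mediated
component proportional to the heritable part of each expression level
(weights ``gamma``), and noise:

    Y_t = direct + mediated + e_0,    Var(Y_t) = 1,

with the genetic (direct + mediated) share equal to ``h2_t`` and the
mediated fraction of the genetic variance set by ``mediated_share``.
Components are rescaled to exact empirical variances, since LD among
causal SNPs would otherwise break the unit-variance constraint.  Causal
SNPs therefore affect the trait directly, through expression, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "population_mafs",
    "locus_windows",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "reference_genotypes",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    Defaults mirror a single-chromosome GWAS cohort: n=10,000 samples,
    p=20,000 SNPs, L=10 risk loci, 30 trait-causal SNPs equally split
    across loci, 4 causal eQTL SNPs per locus (half of them also
    trait-causal), trait heritability 0.3 (mid-grid), expression
    heritability 0.3 (a typical cis value), equal mediation weights, and a
    reference panel a quarter the size of the variant count.  Experiments
    pass smaller n/p explicitly.
    """

    n: int = 10_000
    p: int = 20_000
    L: int = 10
    M_e: int = 4
    M_t: int = 30
    h2_t: float = 0.3
    h2_e: float = 0.3
    mediated_share: float = 0.5
    gamma: np.ndarray | None = None
    ld_block_size: int = 50
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int | None = None  # default p // 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1 or self.L < 1:
            raise ValueError("n, p, L must be positive (n >= 2)")
        if self.M_t % self.L != 0:
            raise ValueError("M_t must be divisible by L")
        if self.M_e % 2 != 0:
            raise ValueError("M_e must be even (half are trait-causal)")
        if self.M_e // 2 > self.M_t // self.L:
            raise ValueError("M_e/2 cannot exceed the per-locus causal count")
        if not (0 < self.h2_t < 1 and 0 < self.h2_e < 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        if not 0 <= self.mediated_share <= 1:
            raise ValueError("mediated_share must lie in [0, 1]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        win = self.p // self.L
        need = self.M_e + (self.M_t // self.L - self.M_e // 2)
        if win < need:
            raise ValueError(
                f"locus window size {win} too small for {need} causal SNPs"
            )
        if self.gamma is not None:
            g = np.asarray(self.gamma, float)
            if g.shape != (self.L,):
                raise ValueError("gamma must have length L")
            self.gamma = g

    @property
    def n_ref_effective(self) -> int:
        return self.n_ref if self.n_ref is not None else max(self.p // 4, 2)


@dataclass
class SimulatedDataset:
    """One draw from the generative model, with causal bookkeeping."""

    X: np.ndarray                      # n x p, standardized
    expression: list[np.ndarray]       # L vectors of length n
    trait: np.ndarray                  # length n
    causal_eqtl: list[np.ndarray]      # per-locus eQTL-causal indices
    causal_trait: np.ndarray           # all trait-causal indices (global)
    locus_windows: list[np.ndarray]    # per-locus variant index ranges
    beta_eqtl: list[np.ndarray]        # per-locus eQTL effects (window-dense)
    beta_trait: np.ndarray             # effective trait effects, length p
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def shared_causal(self) -> np.ndarray:
        """Trait-causal SNPs that are also eQTL-causal (mediated + direct)."""
        eq = np.concatenate(self.causal_eqtl)
        return np.intersect1d(self.causal_trait, eq)

    @property
    def effect_support(self) -> np.ndarray:
        """All SNPs with a nonzero effective trait coefficient.

        The union of the M_t trait-causal set and the eQTL-causal SNPs,
        whose effects reach the trait through expression.  Regressing the
        trait on this design recovers h2_t; power/type-I bookkeeping uses
        ``causal_trait`` (the M_t set) as the truth, mirroring how the
        criteria are defined.
        """
        return np.flatnonzero(self.beta_trait)


def _standardize_columns(G: np.ndarray) -> np.ndarray:
    G = G.astype(float)
    G -= G.mean(axis=0)
    sd = G.std(axis=0)
    nz = sd > 0
    G[:, nz] /= sd[nz]
    return G


def _genotype_block(
    rng: np.random.Generator, n: int, m: int, rho: float, maf: np.ndarray
) -> np.ndarray:
    """Thresholded AR(1) latent-Gaussian genotypes for one block."""
    thresh = norm.ppf(maf)  # allele present when latent < threshold
    g = np.zeros((n, m))
    for _ in range(2):  # two haplotypes
        z = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        z[:, 0] = eps[:, 0]
        s = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + s * eps[:, j]
        g += z < thresh
    return g


def population_mafs(config: SimulationConfig) -> np.ndarray:
    """Per-variant minor-allele frequencies of the simulated population.

    Drawn once per config seed so that study and reference panels sample
    the same population.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xAF)))
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.p)


def simulate_genotypes(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Standardized n x p genotype matrix with independent AR(1) LD blocks.

    ``n`` overrides the config sample size (used for reference panels).
    If the last block would be shorter than ``ld_block_size``, it is
    truncated.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
    n = n if n is not None else config.n
    p, bs = config.p, config.ld_block_size
    mafs = population_mafs(config)
    G = np.empty((n, p))
    start = 0
    while start < p:
        m = min(bs, p - start)
        G[:, start : start + m] = _genotype_block(
            rng, n, m, config.ld_rho, mafs[start : start + m]
        )
        start += m
    return _standardize_columns(G)


def _scale_to_var(v: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) genetic component")
    f = np.sqrt(target_var) / sd
    return v * f, f


def locus_windows(p: int, L: int) -> list[np.ndarray]:
    """Partition variant indices 0..p-1 into L contiguous windows."""
    edges = np.linspace(0, p, L + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(L)]


def simulate_phenotypes(
    X: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw expression levels and the trait given standardized genotypes."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(2)[1]
        )
    n, p = X.shape
    L = config.L
    windows = locus_windows(p, L)
    m_per = config.M_t // L
    gamma = (
        np.ones(L) if config.gamma is None else np.asarray(config.gamma, float)
    )

    expression: list[np.ndarray] = []
    causal_eqtl: list[np.ndarray] = []
    beta_eqtl: list[np.ndarray] = []
    eqtl_coef = np.zeros(p)      # heritable-expression coefficients, gamma-weighted
    causal_trait: list[np.ndarray] = []

    for l, win in enumerate(windows):
        idx = rng.choice(win, size=config.M_e, replace=False)
        beta = rng.normal(0.0, np.sqrt(config.h2_e / config.M_e), config.M_e)
        g_raw = X[:, idx] @ beta
        g, f = _scale_to_var(g_raw, config.h2_e)
        noise = rng.normal(0.0, np.sqrt(1.0 - config.h2_e), n)
        expression.append(g + noise)
        causal_eqtl.append(np.sort(idx))
        bvec = np.zeros(p)
        bvec[idx] = beta * f
        beta_eqtl.append(bvec[win])
        eqtl_coef += gamma[l] * bvec
        # trait-causal: half the eQTL SNPs plus fresh SNPs from the window
        shared = rng.choice(idx, size=config.M_e // 2, replace=False)
        pool = np.setdiff1d(win, idx)
        fresh = rng.choice(pool, size=m_per - config.M_e // 2, replace=False)
        causal_trait.append(np.concatenate([shared, fresh]))

    causal = np.sort(np.concatenate(causal_trait))
    beta_t = np.zeros(p)
    beta_t[causal] = rng.normal(
        0.0, np.sqrt(config.h2_t / config.M_t), config.M_t
    )

    m = config.mediated_share
    direct_raw = X @ beta_t
    mediated_raw = X @ eqtl_coef
    coef = np.zeros(p)
    g_parts = np.zeros(n)
    if m < 1:
        dscaled, fd = _scale_to_var(direct_raw, 1.0 - m)
        g_parts += dscaled
        coef += fd * beta_t
    if m > 0:
        mscaled, fm = _scale_to_var(mediated_raw, m)
        g_parts += mscaled
        coef += fm * eqtl_coef
    g_tot, ft = _scale_to_var(g_parts, config.h2_t)
    coef *= ft
    noise = rng.normal(0.0, np.sqrt(1.0 - config.h2_t), n)
    trait = g_tot + noise

    return SimulatedDataset(
        X=X,
        expression=expression,
        trait=trait,
        causal_eqtl=causal_eqtl,
        causal_trait=causal,
        locus_windows=windows,
        beta_eqtl=beta_eqtl,
        beta_trait=coef,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes plus phenotypes in one deterministic draw."""
    ss = np.random.SeedSequence(config.seed).spawn(2)
    X = simulate_genotypes(config, rng=np.random.default_rng(ss[0]))
    return simulate_phenotypes(X, config, rng=np.random.default_rng(ss[1]))


def reference_genotypes(
    config: SimulationConfig, n_ref: int | None = None
) -> np.ndarray:
    """Independent genotype draw from the same LD process (reference panel)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 0x5EED)).spawn(1)[0]
    )
    n_ref = n_ref if n_ref is not None else config.n_ref_effective
    return simulate_genotypes(config, n=n_ref, rng=rng)
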