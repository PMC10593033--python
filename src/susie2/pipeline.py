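"""Two-stage eQTL-informed fine-mapping (SuSiE-squared).

Stage one fits a SuSiE model per gene with expression as the response and
a uniform prior, yielding per-variant eQTL posterior inclusion
probabilities PIPe = 1 - prod_k (1 - alpha_k).  Stage two fits SuSiE for
the trait of interest with PIPe-derived prior inclusion probabilities, so
variants with eQTL support are prioritized when the trait data cannot
distinguish tightly linked candidates.

Practical details the model leaves open:

* zero eQTL PIPs are absorbing under the SER posterior (alpha_j = 0
  whenever pi_j = 0), so priors are floored at ``floor_eps`` (default
  1/(10 p)) before renormalization — the data can always overrule the
  prior;
* variants covered by several overlapping gene windows combine their
  PIPe values as ``1 - prod_g (1 - PIPe_g)``, the same algebra used to
  combine effects;
* the prior is renormalized to sum to one, consistent with its role as a
  multinomial parameter (the SER posterior is invariant to this scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import SuSiEConfig, SuSiEFit, fit_susie
from .sumstat import SummaryData, fit_susie_ss

__all__ = [
    "PriorSource",
    "PriorVector",
    "EqtlStageResult",
    "SuSiE2Result",
    "uniform_prior",
    "fit_eqtl_stage",
    "build_prior",
    "run_susie2",
]


class PriorSource(str, Enum):
    UNIFORM = "uniform"
    EQTL_PIP = "eqtl_pip"
    USER = "user"


@dataclass
class PriorVector:
    """Per-variant prior inclusion probabilities for the trait stage."""

    pi: np.ndarray
    source: PriorSource = PriorSource.USER
    floor_eps: float = 0.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < 0) or not np.all(np.isfinite(self.pi)):
            raise ValueError("prior entries must be finite and >= 0")
        total = self.pi.sum()
        if total <= 0:
            raise ValueError("prior sums to zero")
        self.pi = self.pi / total


def uniform_prior(p: int) -> PriorVector:
    """The uniform prior pi = (1/p, ..., 1/p)."""
    return PriorVector(pi=np.full(p, 1.0 / p), source=PriorSource.UNIFORM)


@dataclass
class EqtlStageResult:
    """Per-gene SuSiE fits on expression, with PIPe vectors.

    ``windows[g]`` maps gene g's local variant axis into the global
    variant index space; ``pips[g]`` lives on the local axis.
    """

    fits: list[SuSiEFit]
    pips: list[np.ndarray]
    windows: list[np.ndarray]
    gene_names: list[str]


@dataclass
class SuSiE2Result:
    """Trait-stage fit plus the prior and eQTL provenance that produced it."""

    trait_fit: SuSiEFit
    prior: PriorVector
    eqtl: EqtlStageResult | None


def fit_eqtl_stage(
    X: np.ndarray,
    expression: list[np.ndarray],
    gene_variant_maps: list[np.ndarray] | None = None,
    config: SuSiEConfig | None = None,
    gene_names: list[str] | None = None,
) -> EqtlStageResult:
    """Fit one uniform-prior SuSiE per gene on its expression level.

    ``gene_variant_maps[g]`` gives the (global) variant indices of gene
    g's cis window; ``None`` uses the full variant range for every gene.
    Genes with empty windows are skipped with a warning.
    """
    config = config or SuSiEConfig()
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if gene_variant_maps is None:
        gene_variant_maps = [np.arange(p)] * len(expression)
    if len(gene_variant_maps) != len(expression):
        raise ValueError("one variant window per expression vector required")
    names = gene_names or [f"gene{g}" for g in range(len(expression))]
    fits, pips, windows, kept = [], [], [], []
    for g, (expr, win) in enumerate(zip(expression, gene_variant_maps)):
        win = np.asarray(win, dtype=int)
        if win.size == 0:
            warnings.warn(f"gene {names[g]} has an empty variant window; skipped")
            continue
        if np.any(win < 0) or np.any(win >= p):
            raise ValueError(f"gene {names[g]} window indexes outside 0..p-1")
        fit = fit_susie(X[:, win], np.asarray(expr, float), config=config)
        fits.append(fit)
        pips.append(fit.pip)
        windows.append(win)
        kept.append(names[g])
    return EqtlStageResult(fits=fits, pips=pips, windows=windows, gene_names=kept)


def build_prior(
    eqtl: EqtlStageResult,
    p: int,
    floor_eps: float | None = None,
    mode: str = "all",
    selected_genes: list[int] | list[str] | None = None,
) -> PriorVector:
    """Turn eQTL-stage PIPs into a trait-stage prior over p variants.

    ``mode="all"`` uses every gene; ``mode="partial"`` uses only
    ``selected_genes`` (indices or names; default the first gene),
    modeling the setting where eQTL information is available for a single
    risk locus.  Variants covered by used genes receive their (combined)
    PIPe; uncovered variants keep the uniform baseline 1/p.  All entries
    are floored at ``floor_eps`` (default 1/(10 p)) and the vector is
    normalized to sum to one.
    """
    if floor_eps is None:
        floor_eps = 1.0 / (10.0 * p)
    if floor_eps <= 0:
        raise ValueError(
            "floor_eps must be > 0: a zero prior excludes a variant outright"
        )
    if mode not in ("all", "partial"):
        raise ValueError("mode must be 'all' or 'partial'")
    if mode == "partial":
        sel = selected_genes if selected_genes is not None else [0]
        use = [
            g if isinstance(g, (int, np.integer)) else eqtl.gene_names.index(g)
            for g in sel
        ]
    else:
        use = list(range(len(eqtl.fits)))
    acc = np.zeros(p)        # combined PIPe: 1 - prod_g (1 - PIPe_g)
    covered = np.zeros(p, dtype=bool)
    for g in use:
        win, pip = eqtl.windows[g], eqtl.pips[g]
        acc[win] = 1.0 - (1.0 - acc[win]) * (1.0 - np.clip(pip, 0.0, 1.0))
        covered[win] = True
    pi = np.where(covered, acc, 1.0 / p)
    pi = np.maximum(pi, floor_eps)
    return PriorVector(
        pi=pi / pi.sum(), source=PriorSource.EQTL_PIP, floor_eps=floor_eps
    )


def run_susie2(
    trait_data: tuple[np.ndarray, np.ndarray] | SummaryData,
    eqtl_X: np.ndarray,
    expression: list[np.ndarray],
    gene_variant_maps: list[np.ndarray] | None = None,
    config: SuSiEConfig | None = None,
    eqtl_config: SuSiEConfig | None = None,
    mode: str = "all",
    selected_genes: list[int] | list[str] | None = None,
    floor_eps: float | None = None,
    trait_variant_ids: np.ndarray | None = None,
    eqtl_variant_ids: np.ndarray | None = None,
) -> SuSiE2Result:
    """End-to-end SuSiE-squared: eQTL stage -> prior -> trait stage.

    ``trait_data`` is either an individual-level ``(X, y)`` pair or a
    :class:`~susie2.sumstat.SummaryData`.  If variant identifiers are
    supplied for both stages the universes are intersected (variants
    dropped with a warning); an empty intersection is a hard error.
    """
    config = config or SuSiEConfig()
    eqtl_config = eqtl_config or config
    eqtl_X = np.asarray(eqtl_X, dtype=float)

    if trait_variant_ids is not None or eqtl_variant_ids is not None:
        if trait_variant_ids is None or eqtl_variant_ids is None:
            raise ValueError("supply variant ids for both stages or neither")
        trait_ids = np.asarray(trait_variant_ids)
        eqtl_ids = np.asarray(eqtl_variant_ids)
        common, t_idx, e_idx = np.intersect1d(
            trait_ids, eqtl_ids, return_indices=True
        )
        if common.size == 0:
            raise ValueError("no variants shared between trait and eQTL data")
        if common.size < max(trait_ids.size, eqtl_ids.size):
            warnings.warn(
                f"restricting to {common.size} variants shared by both stages"
            )
        eqtl_X = eqtl_X[:, e_idx]
        if isinstance(trait_data, SummaryData):
            trait_data = SummaryData(
                R=trait_data.R[np.ix_(t_idx, t_idx)],
                n=trait_data.n,
                z=trait_data.z[t_idx],
                var_y=trait_data.var_y,
            )
        else:
            X, y = trait_data
            trait_data = (np.asarray(X, float)[:, t_idx], y)
        if gene_variant_maps is not None:
            pos = {int(j): i for i, j in enumerate(e_idx)}
            gene_variant_maps = [
                np.array([pos[int(j)] for j in win if int(j) in pos], dtype=int)
                for win in gene_variant_maps
            ]

    eqtl = fit_eqtl_stage(
        eqtl_X, expression, gene_variant_maps, config=eqtl_config
    )
    p = eqtl_X.shape[1]
    prior = build_prior(
        eqtl, p, floor_eps=floor_eps, mode=mode, selected_genes=selected_genes
    )
    if isinstance(trait_data, SummaryData):
        fit = fit_susie_ss(trait_data, prior=prior.pi, config=config)
    else:
        X, y = trait_data
        fit = fit_susie(np.asarray(X, float), np.asarray(y, float),
                        prior=prior.pi, config=config)
    return SuSiE2Result(trait_fit=fit, prior=prior, eqtl=eqtl)
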