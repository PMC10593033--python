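"""Simulation study: power, type-I error, and credible-set size.

The three criteria, all defined through 95% credible sets rather than PIP
thresholds:

* **power** — proportion of true effect variants included in at least one
  reported credible set;
* **type-I error rate** — proportion of non-causal variants included in at
  least one reported credible set (denominator: all non-causal candidate
  variants, which is why observed rates sit far below ``1 - rho``);
* **average size** — mean number of members per reported credible set,
  pooled within a replicate and then averaged across replicates.

``run_experiment`` sweeps a (heritability x L x LD-regime) grid for the
three methods (plain SuSiE, SuSiE2 with eQTL priors from one locus,
SuSiE2 with priors from all loci).  All methods see the identical
simulated dataset per replicate — a paired design that sharpens the
relative comparisons.  Fine-mapping runs per risk locus (the windows
partition the variant space) and credible sets are pooled across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CredibleSet, SuSiEConfig, fit_susie_suff
from .pipeline import build_prior, fit_eqtl_stage
from .simulate import (
    SimulatedDataset,
    SimulationConfig,
    reference_genotypes,
    simulate_dataset,
)
from .sumstat import SummaryData, fit_susie_ss, zscores

__all__ = [
    "EvalResult",
    "compute_power",
    "compute_type1",
    "run_experiment",
    "summarize",
    "relative_changes",
    "plot_metrics",
]

METHODS = ("susie", "susie2_partial", "susie2_all")
REGIMES = ("in_sample", "ref_panel")


@dataclass
class EvalResult:
    """Aggregated criteria for one (cell, method)."""

    power: float
    type1: float
    avg_cs_size: float
    n_cs: float
    records: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.power <= 1 and 0 <= self.type1 <= 1):
            raise ValueError("power/type1 must lie in [0, 1]")


def _cs_union(cs_list: list[CredibleSet]) -> np.ndarray:
    if not cs_list:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate([cs.variant_indices for cs in cs_list]))


def compute_power(cs_list: list[CredibleSet], causal_set: np.ndarray) -> float:
    """Fraction of causal variants captured by at least one credible set."""
    causal = np.asarray(causal_set, dtype=int)
    if causal.size == 0:
        raise ValueError("causal_set must be non-empty")
    return float(np.isin(causal, _cs_union(cs_list)).sum() / causal.size)


def compute_type1(
    cs_list: list[CredibleSet], causal_set: np.ndarray, p: int
) -> float:
    """Fraction of non-causal variants appearing in any credible set."""
    causal = np.asarray(causal_set, dtype=int)
    if p <= causal.size:
        raise ValueError("p must exceed the number of causal variants")
    union = _cs_union(cs_list)
    false = np.setdiff1d(union, causal).size
    return float(false / (p - causal.size))


def _avg_size(cs_list: list[CredibleSet]) -> float:
    return float(np.mean([len(cs) for cs in cs_list])) if cs_list else np.nan


def _locus_summary(X_loc, y, n):
    XtX = X_loc.T @ X_loc
    Xty = X_loc.T @ y
    return XtX, Xty, float(y @ y), n


def _fit_locus(
    data: SimulatedDataset,
    win: np.ndarray,
    prior_loc: np.ndarray | None,
    regime: str,
    config: SuSiEConfig,
    R_ref: np.ndarray | None,
):
    y = data.trait
    X_loc = data.X[:, win]
    n = X_loc.shape[0]
    if regime == "in_sample":
        XtX, Xty, yty, n = _locus_summary(X_loc, y - y.mean(), n)
        return fit_susie_suff(XtX, Xty, yty, n, prior=prior_loc, config=config)
    if regime == "ref_panel":
        z = zscores(X_loc, y)
        sd = SummaryData(R=R_ref, n=n, z=z, var_y=1.0)
        cfg = SuSiEConfig(**{**config.__dict__, "estimate_sigma2": False,
                             "sigma2": 1.0})
        return fit_susie_ss(sd, prior=prior_loc, config=cfg)
    raise ValueError(f"unknown LD regime {regime!r}")


def evaluate_dataset(
    data: SimulatedDataset,
    methods: tuple[str, ...] = METHODS,
    regimes: tuple[str, ...] = ("in_sample",),
    config: SuSiEConfig | None = None,
    eqtl_config: SuSiEConfig | None = None,
    partial_locus: int = 0,
    X_ref: np.ndarray | None = None,
) -> list[dict]:
    """Fit the requested methods on one simulated dataset; one row per
    (regime, method) with the three criteria."""
    config = config or SuSiEConfig()
    eqtl_config = eqtl_config or config
    p = data.X.shape[1]
    windows = data.locus_windows
    # truth set = every variant with a nonzero effective trait coefficient
    # (direct, mediated through expression, or both)
    causal = data.effect_support

    need_eqtl = any(m.startswith("susie2") for m in methods)
    priors: dict[str, np.ndarray | None] = {"susie": None}
    if need_eqtl:
        eqtl = fit_eqtl_stage(
            data.X, data.expression, windows, config=eqtl_config
        )
        if "susie2_all" in methods:
            priors["susie2_all"] = build_prior(eqtl, p, mode="all").pi
        if "susie2_partial" in methods:
            priors["susie2_partial"] = build_prior(
                eqtl, p, mode="partial", selected_genes=[partial_locus]
            ).pi

    R_ref_loc: dict[int, np.ndarray] = {}
    if "ref_panel" in regimes:
        if X_ref is None:
            X_ref = reference_genotypes(data.config)
        for i, win in enumerate(windows):
            Xr = X_ref[:, win]
            R = (Xr.T @ Xr) / Xr.shape[0]
            np.fill_diagonal(R, 1.0)
            R_ref_loc[i] = R

    rows = []
    for regime in regimes:
        for method in methods:
            prior = priors[method]
            all_cs: list[CredibleSet] = []
            for i, win in enumerate(windows):
                if prior is not None:
                    ploc = prior[win]
                    ploc = ploc / ploc.sum()
                else:
                    ploc = None
                fit = _fit_locus(
                    data, win, ploc, regime, config, R_ref_loc.get(i)
                )
                for cs in fit.credible_sets:
                    all_cs.append(
                        CredibleSet(
                            variant_indices=win[cs.variant_indices],
                            effect_index=cs.effect_index,
                            claimed_coverage=cs.claimed_coverage,
                            min_abs_corr=cs.min_abs_corr,
                        )
                    )
            rows.append(
                {
                    "regime": regime,
                    "method": method,
                    "power": compute_power(all_cs, causal),
                    "type1": compute_type1(all_cs, causal, p),
                    "avg_cs_size": _avg_size(all_cs),
                    "n_cs": len(all_cs),
                }
            )
    return rows


def run_experiment(
    h2_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    L_grid: tuple[int, ...] = (5, 10),
    regimes: tuple[str, ...] = ("in_sample",),
    methods: tuple[str, ...] = METHODS,
    n_reps: int = 40,
    seeds: list[int] | None = None,
    n: int = 2000,
    p: int = 2000,
    M_t: int = 30,
    n_ref: int | None = None,
    config: SuSiEConfig | None = None,
    sim_kwargs: dict | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Sweep the simulation grid and return a tidy per-replicate table.

    Columns: h2, L, regime, method, rep, seed, power, type1, avg_cs_size,
    n_cs, error.  All methods share each replicate's dataset (paired
    design); replicate seeds default to 1..n_reps.  Failed replicates are
    recorded with ``error`` set and the run continues.
    """
    if seeds is None:
        seeds = list(range(1, n_reps + 1))
    if len(seeds) != n_reps:
        raise ValueError("seeds must have length n_reps")
    sim_kwargs = sim_kwargs or {}
    rows = []
    for L in L_grid:
        for h2 in h2_grid:
            for rep, seed in enumerate(seeds):
                try:
                    cfg = SimulationConfig(
                        n=n, p=p, L=L, M_t=M_t, h2_t=h2, n_ref=n_ref,
                        seed=int(seed), **sim_kwargs
                    )
                    data = simulate_dataset(cfg)
                    X_ref = (
                        reference_genotypes(cfg)
                        if "ref_panel" in regimes
                        else None
                    )
                    recs = evaluate_dataset(
                        data, methods=methods, regimes=regimes,
                        config=config, X_ref=X_ref,
                    )
                    for r in recs:
                        rows.append(
                            {"h2": h2, "L": L, "rep": rep, "seed": seed,
                             "error": "", **r}
                        )
                except Exception as exc:  # record and continue
                    for regime in regimes:
                        for method in methods:
                            rows.append(
                                {"h2": h2, "L": L, "rep": rep, "seed": seed,
                                 "regime": regime, "method": method,
                                 "power": np.nan, "type1": np.nan,
                                 "avg_cs_size": np.nan, "n_cs": np.nan,
                                 "error": f"{type(exc).__name__}: {exc}"}
                            )
                if progress:
                    print(f"L={L} h2={h2} rep={rep + 1}/{n_reps}", flush=True)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean criteria per (h2, L, regime, method) cell."""
    ok = table[table["error"] == ""]
    return (
        ok.groupby(["h2", "L", "regime", "method"], as_index=False)[
            ["power", "type1", "avg_cs_size", "n_cs"]
        ]
        .mean()
        .sort_values(["regime", "L", "h2", "method"])
        .reset_index(drop=True)
    )


def relative_changes(
    table: pd.DataFrame, baseline: str = "susie", method: str = "susie2_all"
) -> pd.DataFrame:
    """Percent relative improvements of ``method`` over ``baseline``.

    Per cell: power gain 100*(P_m - P_b)/P_b, type-I reduction
    100*(T_b - T_m)/T_b, and average-size reduction 100*(S_b - S_m)/S_b,
    computed from replicate-mean metrics.
    """
    def rel(new, base, sign):
        if not np.isfinite(base) or base == 0:
            return np.nan
        return 100.0 * sign * (new - base) / base

    s = summarize(table)
    rows = []
    for (h2, L, regime), grp in s.groupby(["h2", "L", "regime"]):
        b = grp[grp["method"] == baseline].iloc[0]
        m = grp[grp["method"] == method].iloc[0]
        rows.append(
            {
                "h2": h2,
                "L": L,
                "regime": regime,
                "power_gain_pct": rel(m["power"], b["power"], +1),
                "type1_reduction_pct": rel(m["type1"], b["type1"], -1),
                "size_reduction_pct": rel(
                    m["avg_cs_size"], b["avg_cs_size"], -1
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_metrics(table: pd.DataFrame, out_dir: str) -> list[str]:
    """Write power/type1/size-vs-heritability plots, one figure per metric,
    faceted by L and LD regime.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = summarize(table)
    paths = []
    facets = sorted(set(zip(s["L"], s["regime"])))
    for metric, label in [
        ("power", "Power"),
        ("type1", "Type I error rate"),
        ("avg_cs_size", "Average credible-set size"),
    ]:
        fig, axes = plt.subplots(
            1, len(facets), figsize=(4 * len(facets), 3.2), squeeze=False,
            sharey=True,
        )
        for ax, (L, regime) in zip(axes[0], facets):
            sub = s[(s["L"] == L) & (s["regime"] == regime)]
            for method, grp in sub.groupby("method"):
                ax.plot(grp["h2"], grp[metric], marker="o", label=method)
            ax.set_title(f"L={L}, {regime}")
            ax.set_xlabel("trait heritability")
        axes[0][0].set_ylabel(label)
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
        path = str(out / f"{metric}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
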