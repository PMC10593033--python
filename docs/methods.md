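# Methods

## Models

### Single-effect regression (SER)

The atomic model assumes exactly one of *p* standardized predictors has a
nonzero coefficient:

    y = Xb + e,  e ~ N(0, σ²Iₙ),  b = λc,  c ~ Mult(1, π),  λ ~ N(0, σ₀²).

With σ² and σ₀² fixed, the posterior is closed-form. The indicator
posterior is multinomial with weights

    αⱼ = πⱼ BFⱼ / Σⱼ′ πⱼ′ BFⱼ′,

where the per-variant log Bayes factor against the null is, via the
sufficient statistics xⱼᵀxⱼ and xⱼᵀy,

    log BFⱼ = ½ log(σ² / (σ² + σ₀² xⱼᵀxⱼ)) + ½ σ₀² (xⱼᵀy)² / (σ²(σ² + σ₀² xⱼᵀxⱼ)),

and the slab posterior given cⱼ = 1 is N(μ₁ⱼ, σ₁ⱼ²) with
σ₁ⱼ² = (xⱼᵀxⱼ/σ² + 1/σ₀²)⁻¹ and μ₁ⱼ = σ₁ⱼ² xⱼᵀy / σ². All weight
arithmetic is in log space with log-sum-exp normalization, so the ratio
is computable at p in the tens of thousands. Zero-variance (constant)
columns are assigned log BF = 0: they carry no information, so the prior
decides; columns with πⱼ = 0 get αⱼ = 0 exactly.

### Sum of single effects (SuSiE) and IBSS

SuSiE stacks K single effects additively, b = Σₖ bₖ, each bₖ with its own
prior variance σ₀ₖ². Iterative Bayesian stepwise selection (IBSS) updates
each effect in turn by fitting an exact SER to the residual obtained by
subtracting the posterior-mean contributions of the other K−1 effects.
The implementation works entirely in sufficient statistics
(XᵀX, Xᵀy, yᵀy, n), which makes the individual-level and
summary-statistics paths the same code.

Per-variant posterior inclusion probabilities combine across effects as
PIPⱼ = 1 − Πₖ (1 − αₖⱼ). Each *active* effect contributes one candidate
level-ρ credible set: the smallest prefix of its α sorted descending
(ties broken by variant index) whose cumulative mass reaches ρ. A set is
reported only if its minimum absolute pairwise correlation ("purity") is
at least `purity_threshold`; duplicate sets across effects are reported
once. Without the purity filter, null data would yield near-uniform α
and meaninglessly large sets.

### Objective, convergence, and hyperparameter estimation

The fit is monitored by the variational evidence lower bound

    ELBO = −n/2 log(2πσ²) − E[‖y − Xb‖²]/(2σ²) − Σₖ KL(qₖ ‖ priorₖ),

where the KL term is evaluated in closed form over the pair (c, λ) —
categorical times Gaussian — rather than through residual bookkeeping;
this gives an exact end-of-sweep objective. IBSS stops when the ELBO
changes by less than `tol` (default 1e-4) between sweeps, or at
`max_iter` (default 200); non-convergence warns and returns
`converged=False`, it never raises.

* **σ² (residual variance)** — updated once per sweep to its
  ELBO-maximizing value E[‖y − Xb‖²]/n (default on; can be frozen).
* **σ₀ₖ² (prior effect variances)** — updated per effect by maximizing
  the SER model log Bayes factor over σ₀ₖ² ≥ 0, comparing the bounded 1-D
  optimum (on the log scale, tolerance 1% — ample for an empirical-Bayes
  point estimate) against the null σ₀ₖ² = 0 and the current value. The
  null wins unless strictly beaten, so effects unsupported by data shrink
  to exactly zero and are flagged inactive: they hold α = π, contribute
  no PIPs and no credible sets. Because the current value is always a
  candidate, every update is a monotone block-coordinate step, and the
  recorded ELBO trace is non-decreasing by construction (asserted
  throughout the test suite).

Defaults when unspecified: σ² starts at var(y), σ₀ₖ² at 0.2·var(y), K=10.
The helper `suggest_K` implements the forward heuristic of growing K from
1 and stopping once the count of purity-passing credible sets stops
increasing.

### Summary-statistics mode

Under the standardized-variable convention (xⱼᵀxⱼ = n, var(y) = var_y)
the sufficient statistics are recoverable from per-variant z-scores, the
sample size, and an LD correlation matrix R:

    XᵀX = nR,  yᵀy = n·var_y,
    xⱼᵀy = sign(zⱼ) √( zⱼ² n yᵀy / (n − 2 + zⱼ²) ),

an exact inversion when z-scores are the marginal OLS t-statistics with
residual df n − 2 (the convention `zscores` produces). With in-sample R
the summary fit reproduces the individual-level fit to ~1e-8; tests
assert 1e-6. R is ridge-regularized, (R + λI)/(1+λ) with λ = 1e-8 by
default, preserving the unit diagonal; matrices with eigenvalues below
−1e-8 after regularization raise an error advising a larger ridge. With
an external reference panel the model is misspecified, so the residual
variance is held fixed at var_y rather than estimated in that regime.
Heterogeneous per-variant sample sizes are collapsed to a single scalar
(callers pass e.g. the median); per-variant-n modeling is out of scope.

### Two-stage eQTL-informed fine-mapping

Stage one fits one uniform-prior SuSiE per gene with its expression level
as the response, producing per-variant eQTL PIPs, PIPᵉ = 1 − Πₖ(1 − αₖ).
Stage two fits the trait with prior π ∝ PIPᵉ. Three practical rules close
gaps the model itself leaves open:

* **Flooring.** πⱼ = 0 is absorbing (αⱼ = 0 regardless of data), so
  priors are floored at `floor_eps`, default 1/(10p), before
  normalization. The floor keeps the prior 10× below the uniform value,
  so it prioritizes without ever silencing a variant.
* **Overlapping genes.** Variants covered by several gene windows combine
  their PIPᵉ as 1 − Πg(1 − PIPᵉ_g) — the same algebra used to combine
  effects. Uncovered variants keep the uniform baseline 1/p.
* **Normalization.** The prior is renormalized to sum to one, consistent
  with its multinomial role; the SER posterior is invariant to this
  scale, so it is cosmetic but enforced.

A flat PIPᵉ therefore reproduces plain SuSiE exactly (tested at 1e-10).
The "partial" mode uses a single selected gene's PIPs (default: the
first), modeling eQTL information available for only one risk locus.

## Simulator

The generator emulates a biobank-scale single-chromosome study without
any real data.

**Genotypes.** Variants come in independent blocks of `ld_block_size`
(default 50). Within a block, two latent haplotype vectors follow an
AR(1) Gaussian process with lag-one correlation `ld_rho` (default 0.9);
each is thresholded at the quantile of a per-variant MAF drawn uniformly
from `maf_range` (default [0.05, 0.5]), and the genotype is the sum
(0/1/2), then standardized. MAFs are drawn once per seed so a reference
panel drawn later samples the same population. Thresholding attenuates
the latent correlation: adjacent genotype correlation is ≈0.5–0.6 at
ld_rho = 0.9–0.95 (validated in tests against a Monte-Carlo thresholding
oracle). Real biobank LD is longer-ranged and often near-perfect between
neighbors; see Limitations.

**Phenotypes.** The L risk-locus windows partition the variant space.
Per locus, M_e causal eQTL SNPs (default 4) with N(0, h2_e/M_e) effects
drive an expression level with heritability h2_e (default 0.3, a typical
cis value) and unit variance. The trait combines three components:

* direct effects on the M_t trait-causal SNPs (M_t/L per locus; half of
  each locus's eQTL SNPs are also trait-causal, the rest drawn fresh),
* a mediated component proportional to the *heritable* part of each
  expression level (equal weights by default), and
* Gaussian noise.

The three components are rescaled to variance shares
(1−σ_t²)(1−m), (1−σ_t²)m and σ_t², with h2_t = 1−σ_t² the trait
heritability and m = `mediated_share` (default 0.5). Taken literally,
adding expression terms (noise included) on top of direct N(0,(1−σ_t²)/M_t)
effects plus N(0,σ_t²) noise would push Var(Y_t) above 1 and the genetic
share below h2_t; the rescaling honors both unit variance and the
heritability simultaneously, and the genetic parts are scaled to exact
*empirical* variances because LD among causal SNPs would otherwise break
the constraint. Expression noise is folded into the trait noise budget,
so regressing Y_t on the full effect design recovers h2_t ± 0.03 at
n = 100,000 (tested).

Because mediation flows through *all* M_e eQTL SNPs, the full set of
trait-effect variants is the union of the M_t set and the eQTL-causal
SNPs: SNPs act directly, through expression, or both. Evaluation treats
this full set (`effect_support`) as the truth for power and type-I error;
`causal_trait` records the M_t bookkeeping set.

All randomness flows from the config seed through spawned child streams;
identical configs give bit-identical datasets.

## Evaluation harness

Three credible-set-based criteria (PIP thresholds are not used): power =
fraction of effect variants inside ≥1 reported credible set; type-I error
= fraction of non-effect variants inside ≥1 set (denominator: all
non-effect candidates, which is why observed rates sit orders of
magnitude below 1 − ρ); average size = mean members per reported set,
pooled within a replicate then averaged across replicates (per-replicate
records are kept so either convention is recoverable).

Fitting is per risk locus — windows partition the variants, and blocks
are independent across loci, so this matches region-based fine-mapping
practice — with credible sets pooled across loci. All methods see the
identical dataset per replicate (paired design). Two LD regimes: the
in-sample regime passes exact sufficient statistics; the reference-panel
regime passes z-scores with R estimated from an independent genotype draw
(default n_ref = p/4).

## Problem sizes used

The full-scale study the simulator emulates (n = 10,000, p = 20,000) is
deliberately scaled down in the shipped replication: n = p = 2,000,
L = 10, 30 causal SNPs, 40 paired replicates, reference panel n_ref =
500. The test suite uses smaller instances still (tens to hundreds of
variants) for oracle comparisons, because the exhaustive-enumeration
oracles grow exponentially.

## Known limitations

* The threshold-Gaussian LD surrogate produces much weaker and
  shorter-ranged LD than real biobank haplotypes. Fine-mapping is
  consequently *easier* per signal (credible sets are near-singletons,
  average size ≈ 1.1), and harder per dataset (smaller n lowers power).
  Relative method comparisons keep their direction, but magnitudes shift:
  with weak baseline power the eQTL prior is worth more (power gains and
  false-positive reductions exceed what stronger-LD data shows), and with
  singleton sets there is little set size left to reduce.
* Allele-flip QC between summary statistics and LD panels, out-of-sample
  LD shrinkage estimators, heterogeneous per-variant sample sizes, and
  colocalization-style joint causality are all out of scope.
* The eQTL stage assumes individual-level expression data; only the
  trait stage has a summary-statistics path.
* `suggest_K` implements the stated forward heuristic only; instability
  of K selection on real data is a known open issue upstream of this
  package.
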