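# Methods

This note documents the statistical model, the algorithms, the defaults
and the design decisions behind `pmrgwas`, in the spirit of a methods
supplement: enough detail to reproduce or audit every computation, plus
an honest account of what the synthetic benchmarks do and do not show.

## Penalized GLM and the five penalties

The core estimator is the penalized maximum-likelihood estimate of a
GLM with linear predictor `C·α + X·β`, where `C` (covariates, always
including an intercept) is unpenalized and the marker coefficients `β`
pay a sparsity penalty `Σ_j P(|β_j|; λ)`. Two families are supported:
logistic (Bernoulli likelihood, for case/control phenotypes) and linear
(Gaussian). For the linear family the *solver* objective uses the
unit-variance Gaussian log-likelihood (−RSS/2) so that the penalty
scale is well defined independently of the noise variance; reported
log-likelihoods and AIC values use the variance-profiled Gaussian
likelihood.

All penalties are parameterized so the primary tuning parameter
(`rate`) is the slope of the penalty at the origin. This matters for
comparability: for every family a coordinate enters the model exactly
(or, for strongly non-convex settings, at the earliest) when its score
`|x_jᵀ(y − μ)|` exceeds `rate·w_j`, so rate paths for different
families are anchored to the same entry scale and lasso solutions can
warm-start the non-convex fits.

* **lasso / adaptive lasso** — linear in |β|; the adaptive variant
  weights each coefficient by `w_j = |β̂_j,init|^(−1/2)` from a
  first-stage lasso fit (read as inverse square root: that is the only
  direction consistent with the oracle property this penalty is chosen
  for). Markers with a zero first-stage estimate get the weight of the
  smallest nonzero initial estimate so they remain selectable.
* **MCP** — quadratically tapering, derivative exactly zero beyond
  `γλ`; `γ → ∞` recovers the lasso, `γ → 1⁺` approaches best-subset
  behavior.
* **LOG** — `λ·log(1+b/η)/log(1+1/η)`, normalized so `η → ∞` recovers
  the lasso while small `η` is aggressively non-convex. The
  unnormalized `λ·log(b+η)` parameterization is equivalent up to a
  rate rescaling; the normalized form is used because it embeds the
  lasso as a limiting grid column.
* **NEG** — the negative log marginal density of the
  normal-exponential-gamma shrinkage prior, defined through its
  derivative, a ratio of parabolic cylinder functions
  `D_{−2a−2}(b/s)/D_{−2a−1}(b/s)` with the mixing shape fixed at
  `a = 1` and normalized so the slope at the origin equals `rate`;
  the second tuning parameter is the scale `s`. The exact ratio
  0/0-underflows for arguments beyond ≈20, where the asymptotic `s/b`
  tail is substituted — the known numerical fragility of this penalty.
  Penalty *values* (needed only for objectives, not for updates) are
  computed by 64-node Gauss–Legendre quadrature of the derivative.

## MM coordinate ascent

Each coordinate update maximizes the quadratic surrogate
`−(d_j/2)(β − z)² − P(|β|)`, `z = β_j + g_j/d_j`, with curvature
`d_j = Σ_i x_ij²/4` (logistic) or `Σ_i x_ij²` (linear). Because `d_j`
globally dominates the negative second derivative of the coordinate
log-likelihood, every single update is guaranteed not to decrease the
penalized objective — no step-size search and no per-update likelihood
evaluation. `debug_monotone=True` runs the reference python solver and
asserts this invariant after every update; the test suite exercises it
over random instances of all five families.

Surrogate maximizers: soft threshold (lasso), firm threshold (MCP,
with an explicit candidate comparison when `γ·d ≤ 1` where the firm
formula is invalid), closed-form quadratic roots (LOG), and a
safeguarded bracket-and-root search over the stationary points (NEG).
In all cases the exact zero is returned whenever the surrogate at zero
is maximal, so sparsity is exact, not thresholded after the fact.

Sweep schedule: covariates first (unpenalized MM updates), then the
markers in the given permutation; full sweeps alternate with
active-set passes over the currently nonzero set; convergence when no
full sweep moves any coefficient by more than 1e-5 (default), capped
at 500 sweeps (non-convergent fits are flagged and still returned).
Marker columns are mean-centered internally so λ has per-allele
meaning; coefficients are reported on the dosage scale. The
lasso/adaptive/MCP sweeps run in a numba kernel; LOG/NEG use the
python path (they are searched at far smaller scale).

## Tuning search and model selection

Convex path: start at `λ_max` (the null-fit entry threshold, computed
from the covariate-only fit), multiply by 0.8 per step (configurable),
warm-starting each fit, until `k_max` markers are selected. Adaptive
lasso runs lasso path → AIC selection → weights → weighted path.

Non-convex grid: lasso solutions at (default 5) roughly equally spaced
model sizes up to `k_max` serve as warm starts; for each, the
non-convexity increases along a shape schedule (MCP γ:
100, 30, 10, 3, 1.5; LOG η: 100, 10, 1, 0.1, 0.01; NEG s:
100, 10, 3, 1, 0.3), warm-starting each shape from the best fit at the
previous one, with (default 100) random coordinate-update orders per
grid cell to explore distinct modes. The 1D mode pins the shape (γ=30
for MCP, the permutation-tuning convention) and searches the rate only.

Model selection: among all recorded fits with
`k ≤ k_max = ⌈√(n/log n)⌉` (natural log; the sample-size-dependent
bound on how many coefficients are detectable at all), pick minimum
AIC = −2ℓ + 2(k + #covariates); ties break toward smaller k, then
first encountered. The bound, not AIC, is what prevents absurdly large
models at finite n; AIC alone would keep adding pre-screened (hence
marginally associated-looking) null markers. The final FDR control
comes from the post-hoc score threshold, not from AIC.

perm-MCP (provided as the comparator convention): the phenotype is
permuted (default 20 times), the MCP (γ=30) selection count is traced
over a decreasing rate grid, and the rate is interpolated so that the
average count equals eFPR × (number of screened markers); defaults
eFPR = 1e-3 with a 0.001 pre-screen.

## Scans, pre-screening, diagnostics

Single-marker scans use the exact F-test (linear; via
Frisch–Waugh residualization) or a per-marker Newton fit with a 1-df
LRT (logistic, numba-compiled). Monomorphic markers report p = 1 with
a warning. Perfect separation caps |coefficients| at 30 and flags the
fit; the capped LRT is still usable. The conditional scan adds the
strongest stage-1 hit per 100 kb (stage-1 cutoff default 1e-5) to the
covariates and reports each marker's better of the two p-values.

Pre-screening keeps markers with marginal p ≤ 0.01 (default): sure
screening retains relevant variables with probability tending to one,
and the joint fit is then feasible at genome scale. Genomic control
λ = median(χ²₁ quantiles of the p-values)/0.4549 is reported for the
raw scan and for the residual-QQ diagnostic (every non-selected marker
regressed on the residuals — deviance residuals for logistic — of the
unpenalized selected-marker refit). Deflation of the diagnostic λ
signals overfitting; the diagnostic is reported, never used to make an
automatic decision. Note the diagnostic presumes genome-like marker
density: with only a few thousand markers the conditioned LD
block-mates are a visible fraction of the panel and the median-based λ
is itself noisy, so λ can sit well below 1 on perfectly null data.

## Post-hoc scores

Selected markers are refitted jointly without penalty; each gets a
1-df drop-one LRT p-value. While any retained pair has |Pearson r|
(on imputed dosages) above 0.1, the member of the worst pair with the
smaller |refit coefficient| is dropped (ties: the larger marker index)
and the LRTs recomputed; every marker keeps the smallest p-value it
ever achieved. Scores are heuristic ranks, not calibrated p-values.
Association *calls* are made among retained markers only (the retained
set is what satisfies the correlation bound), at default score
thresholds 1e-7 for 2D-MCP reports and 1e-5 otherwise.

## Simulator

Genotypes: a pool of (default 1000) haplotypes over LD blocks of
5–50 markers; within a block, alleles are a latent Gaussian AR(1)
process (per-block correlation drawn from 0.999–0.9999) thresholded
at per-marker allele frequencies (block base frequency 0.05–0.45,
±0.001 per-marker jitter); blocks are independent; individuals are
two haplotypes drawn with replacement; marker spacing 2.5 kb, 1 cM/Mb.
The very high within-block correlation is deliberate: it emulates the
internal redundancy of dense genotyping arrays, where a causal
variant removed from the panel is tagged at r² ≥ 0.8 not only by its
best proxy but by most markers across the ±25 kb window a significant
association report can land on. The defaults were calibrated against
that LD audit directly (≈90% of same-block markers within ±10
positions of a causal variant exceed r² = 0.8). At looser LD the
r²-based true-positive definition (below) classifies strong,
genuinely causal-driven hits as false positives simply because the
marker the method happens to report is an under-correlated proxy —
a property of the panel, not of the method being evaluated.

Phenotypes: causal markers drawn uniformly among markers with pool
MAF ≥ 0.05; effects i.i.d. standard normal, independent of frequency
(so most rescaled effects are very small); environmental variance set
from the empirical genetic variance of a large reference draw so that
Var(genetic)/Var(liability) = h² exactly; liability threshold at the
empirical (1−K) quantile of an independent reference draw (default
100,000 liabilities), K = 0.5 by default; individuals are drawn until
the case and control quotas fill. The emitted analysis dataset
excludes the causal columns (kept separately for evaluation), so
associations must be found through LD. Marginal heritability of locus
c is 2p_c(1−p_c)β_c²/Var(liability). Everything is reproducible from
one seed, including byte-identical TPED output.

What the simulator does *not* model: population structure,
relatedness, ascertainment bias of markers, genotyping error, rare
variants, non-additive effects. Benchmarks on it show algorithmic
correctness and the relative behavior of methods under clean polygenic
architecture — not performance under confounding.

## Evaluation

A hit is a true positive if its dosage has r² ≥ 0.8 (configurable;
sensitivity analyses also use 0.5) with some causal variant; TP count
= number of distinct causal loci tagged. False-positive hits are
greedily clustered (most significant first, ±50 kb), and the FP count
is the number of clusters. Walking the ranked list, FDR at a prefix is
FP clusters/(FP clusters + TP loci) and power at a target FDR is the
best recall among prefixes meeting it.

## Benchmark problem sizes

The scaled-down power comparison in the test suite uses 20 replicate
studies at n = 2000 (1000/1000), 20,000 markers, 10 causal loci,
h² = 0.5, pre-screen 0.1 (≈2,000 markers enter the joint fit), and a
reduced 2D-MCP grid (4 warm-start model sizes × γ ∈ {30, 3, 1.5} × 8
reorderings) — sizes chosen so the whole suite runs on one CPU in
minutes while preserving the qualitative contrast between the
penalized pipeline and single-marker analysis. The full-size defaults
(100 reorderings, 5 shapes, pre-screen 0.01) are what the package
recommends for real data. The null-calibration check runs at 100,000
markers: the genomic-control median needs many independent LD blocks
to be stable, and the deflation induced by conditioning on the
selected null markers (whose block mates drop out of the residual
scan) must be a negligible fraction of the panel, as it is at
real-data density.

## Known limitations

* Post-hoc scores are rank heuristics; they are deliberately not
  corrected for selection and should be read comparatively.
* The NEG penalty value relies on quadrature of a special-function
  ratio and saturates its derivative above the overflow guard; very
  large coefficients under NEG are effectively unpenalized.
* AIC-with-bound can and does select null markers on null data (the
  score threshold is the guard); the selected-k value alone is not an
  inference.
* Mixed models, score tests, group/elastic-net penalties and exact
  logistic regression are out of scope.
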