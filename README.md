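# pmrgwas

Penalized multiple-regression (PMR) association analysis for genome-wide
association studies (GWAS).

Standard GWAS practice tests one marker at a time, which leaves real but
weak susceptibility loci below the significance threshold. `pmrgwas`
instead fits **all** markers jointly in a sparse penalized generalized
linear model, so that each marker's association is assessed conditional
on every other relevant locus — smaller residual variance and often a
sharper conditional signal. It is aimed at statistical geneticists who
want to re-mine case/control or quantitative-trait GWAS datasets for
associations that single-marker tests miss, while keeping a conservative
false-discovery rate.

## The model

For phenotype vector *y* (binary 0/1 with a logistic link, or continuous
with an identity link), genotype dosage matrix *X* (minor-allele counts
in {0,1,2}) and unpenalized covariates *C* (intercept, sex, principal
components, ...), the package computes the penalized maximum-likelihood
estimate

  β̂ = argmax_β  ℓ(y; Cα + Xβ) − Σ_j P(|β_j|; λ)

where ℓ is the GLM log-likelihood and P is a sparsity penalty that
forces most marker coefficients to exactly zero. Five penalty families
are implemented:

| family | P(b) | tuning |
|---|---|---|
| lasso | λ·b | λ |
| adaptive lasso | λ·w_j·b, w_j = \|β̂_j,init\|^(−1/2) | λ |
| MCP | λb − b²/(2γ) for b ≤ γλ, else γλ²/2 | λ, γ > 1 |
| LOG | λ·log(1 + b/η) / log(1 + 1/η) | λ, η > 0 |
| NEG | −log normal-exponential-gamma marginal density | λ, scale s |

λ is the slope of every penalty near the origin (the signal level below
which a coefficient is zeroed); the second parameter of the non-convex
families (MCP, LOG, NEG) controls how fast the penalty derivative tails
off to zero, i.e. how little large coefficients are shrunk.

Fitting is by **minorize-maximization (MM) coordinate ascent**: each
coordinate maximizes a quadratic lower bound of the likelihood whose
curvature (Σx²/4 for logistic, Σx² for linear) dominates the true
negative second derivative, so the penalized objective provably never
decreases and no per-update likelihood evaluations are needed. The
non-convex objectives are multimodal; distinct modes are explored by
permuting the coordinate update order (default 100 reorderings).

Around the solver the package provides the full workflow: PLINK
TPED/TFAM text I/O with mean imputation, single-marker and conditional
scans, marginal p-value pre-screening, a regularization-path /
two-dimensional tuning-grid search warm-started from lasso solutions,
min-AIC model selection bounded by k ≤ ⌈√(n/log n)⌉, post-hoc
refit + correlation-pruning p-value scores, residual-QQ overfitting
diagnostics, a liability-threshold case/control simulator with LD
structure, and power-at-FDR evaluation with LD-aware true/false
positive counting.

## Worked example

```python
import numpy as np
from pmrgwas import (SimulationConfig, simulate_dataset,
                     RunConfig, run_pipeline)
from pmrgwas.evaluate import evaluate_report

g, y, truth = simulate_dataset(SimulationConfig(
    n_cases=1000, n_controls=1000, n_markers=20_000,
    n_causal=10, h2=0.5, seed=11))

res = run_pipeline(g, y, cfg=RunConfig(
    penalty="mcp", mode="2D", prescreen_cutoff=0.1,
    n_orders=8, n_warm=4, shapes=(30.0, 3.0, 1.5), seed=11))
print(res.selected.summary())

hits = res.report.table[res.report.table["retained"]]
out = evaluate_report(hits.rename(columns={"score": "p"})[["id", "p"]],
                      truth, g)
print(f"power at 5% FDR: {out.power:.2f}  "
      f"(TP loci {out.tp_count}/{truth.m}, FP clusters {out.fp_clusters})")
```

which prints (the grid search examined 105 models, 10 of them
distinct; note the AIC winner on this dataset is a fit from the lasso
anchor path of the grid — the lasso is the weak-non-convexity limit of
MCP and its path points compete in the same model selection):

```
Penalized GLM fit
  family:     logistic
  penalty:    lasso (rate=45.508)
  selected k: 14
  loglik:     -1079.3641
  AIC:        2188.7283
  converged:  True (348 sweeps)
  nonzero markers (dosage-scale coefficients):
    [1189] +0.00182
    [1194] +0.20525
    ...
    [3736] -0.05455
power at 5% FDR: 0.50  (TP loci 5/10, FP clusters 0)
```

Fourteen markers carry nonzero coefficients at the AIC-selected point
of the tuning search; after the unpenalized refit, correlation pruning
and min-p rescoring, the retained markers tag 5 of the 10 simulated
causal loci at a 5% false-discovery rate with no false-positive
cluster — versus 2 of 10 for the single-marker scan of the same
dataset at the same FDR.

The same workflow is available from the shell:

```sh
pmrgwas simulate --n 2000 --p 20000 --causal 10 --h2 0.5 --seed 11 --out sim
pmrgwas pmr --tped sim.tped --tfam sim.tfam --penalty mcp --out-dir run/
pmrgwas evaluate --hits run/report.tsv --truth sim.truth.tsv \
    --causal-dosages sim.causal_dosages.tsv --tped sim.tped --tfam sim.tfam
```

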