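"""Case/control GWAS simulation under an additive liability-threshold model.

Genotypes are built from a finite pool of haplotypes organized in LD
blocks: within a block, alleles come from thresholding a latent AR(1)
Gaussian process (allelic correlation decays geometrically with marker
distance), and blocks are mutually independent.  Individuals are formed
by drawing two haplotypes from the pool with replacement, mimicking
resampling haplotypes from a reference panel; dosage is the haplotype
sum.  The within-block latent correlation is drawn high enough that a
typical marker has a near-duplicate neighbor, emulating the dense tag
coverage of genotyping arrays (a causal variant removed from the panel
can still be tagged at high r^2).

Phenotypes follow the additive liability-threshold model: liability =
genetic value + Gaussian environmental noise scaled so the genetic
share of liability variance equals the target heritability h^2; an
individual is a case when liability exceeds the (1 - K) population
quantile, K the prevalence.  Causal markers are drawn uniformly among
markers above a minor-allele-frequency floor with i.i.d. standard
normal effect sizes, independent of allele frequency, and the emitted
analysis dataset excludes the causal columns so associations must be
found through LD proxies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset, PhenotypeVector

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated GWAS."""

    n_cases: int = 1000
    n_controls: int = 1000
    n_markers: int = 20_000
    n_causal: int = 10
    h2: float = 0.5                       # liability heritability
    prevalence: float = 0.5               # population disease prevalence K
    causal_maf_floor: float = 0.05
    maf_range: tuple = (0.05, 0.45)       # per-block base minor allele freq
    maf_jitter: float = 0.001             # per-marker deviation from block base
    block_len_range: tuple = (5, 50)      # markers per LD block
    block_rho_range: tuple = (0.999, 0.9999)  # latent AR(1) correlation
    n_haplotypes: int = 1000              # pool size (2H)
    marker_spacing_bp: int = 2500
    n_reference: int = 100_000            # draws to calibrate the threshold
    draw_budget_factor: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal >= self.n_markers:
            raise ValueError("need n_causal < n_markers")


@dataclass
class SimulationTruth:
    """Ground truth for evaluating method output against a simulation."""

    causal_ids: list[str]
    betas: np.ndarray                     # N(0,1) draws (unscaled)
    maf: np.ndarray                       # causal pool allele frequencies
    marginal_h2: np.ndarray               # per-locus share of liability var
    var_genetic: float
    var_liability: float
    threshold: float
    causal_bp: np.ndarray
    causal_chrom: np.ndarray
    causal_block: np.ndarray
    causal_dosages: np.ndarray | None = field(default=None, repr=False)
    sigma_e: float = 0.0

    @property
    def m(self) -> int:
        return len(self.causal_ids)


class GwasSimulator:
    """Haplotype-pool simulator; one instance is one genotyping panel.

    All randomness flows from ``cfg.seed`` through a single generator,
    consumed in a fixed order (pool, causal set, effects, reference
    draw, ascertainment), so identical configs give identical datasets.
    """

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self._build_pool()

    def _build_pool(self):
        cfg = self.cfg
        p = cfg.n_markers
        nh = cfg.n_haplotypes
        lo, hi = cfg.block_len_range
        lengths = []
        total = 0
        while total < p:
            L = int(self.rng.integers(lo, hi + 1))
            lengths.append(min(L, p - total))
            total += lengths[-1]
        self.block_id = np.repeat(np.arange(len(lengths)), lengths)
        pool = np.empty((nh, p), dtype=np.int8)
        mafs = np.empty(p)
        start = 0
        for L in lengths:
            base = self.rng.uniform(*cfg.maf_range)
            maf = np.clip(base + self.rng.uniform(-cfg.maf_jitter,
                                                  cfg.maf_jitter, L),
                          cfg.maf_range[0], 0.5)
            rho = self.rng.uniform(*cfg.block_rho_range)
            z = np.empty((nh, L))
            z[:, 0] = self.rng.standard_normal(nh)
            innov = self.rng.standard_normal((nh, L))
            s = np.sqrt(1.0 - rho * rho)
            for j in range(1, L):
                z[:, j] = rho * z[:, j - 1] + s * innov[:, j]
            pool[:, start:start + L] = z < stats.norm.ppf(maf)
            mafs[start:start + L] = maf
            start += L
        self.pool = pool
        self.target_maf = mafs
        self.pool_freq = pool.mean(axis=0)
        bp = (1 + np.arange(p, dtype=np.int64)) * cfg.marker_spacing_bp
        self.markers = pd.DataFrame({
            "chrom": "1", "id": [f"snp{j + 1}" for j in range(p)],
            "cm": bp / 1.0e6, "bp": bp, "block": self.block_id})

    # -- genotype draws ------------------------------------------------------

    def draw_hap_pairs(self, n: int) -> np.ndarray:
        return self.rng.integers(0, self.cfg.n_haplotypes, size=(n, 2))

    def dosages_for(self, pairs: np.ndarray, cols=None) -> np.ndarray:
        pool = self.pool if cols is None else self.pool[:, cols]
        return (pool[pairs[:, 0]] + pool[pairs[:, 1]]).astype(np.float64)

    def dataset_for(self, pairs: np.ndarray, fid_prefix="sim") -> GenotypeDataset:
        n = len(pairs)
        samples = pd.DataFrame({
            "fid": [f"{fid_prefix}{i + 1}" for i in range(n)],
            "iid": ["1"] * n, "sex": [0] * n})
        return GenotypeDataset(self.dosages_for(pairs),
                               self.markers.drop(columns="block"), samples,
                               np.zeros((n, self.cfg.n_markers), dtype=bool))

    # -- effects and phenotypes ----------------------------------------------

    def assign_effects(self, distinct_blocks: bool = False) -> SimulationTruth:
        """Pick causal markers and effect sizes; derive variance components.

        Effects are standard normal, independent of allele frequency.
        The environmental variance is set from the empirical genetic
        variance (over a reference population draw) so that the genetic
        share of liability variance is exactly the configured h^2; the
        marginal heritability of locus c is 2 p_c (1 - p_c) beta_c^2
        over the total liability variance.
        """
        cfg = self.cfg
        eligible = np.flatnonzero(self.pool_freq >= cfg.causal_maf_floor)
        if eligible.size < cfg.n_causal:
            raise ValueError(
                f"only {eligible.size} markers have MAF >= {cfg.causal_maf_floor}")
        if distinct_blocks:
            order = self.rng.permutation(eligible)
            chosen, seen = [], set()
            for j in order:
                b = self.block_id[j]
                if b not in seen:
                    chosen.append(j)
                    seen.add(b)
                if len(chosen) == cfg.n_causal:
                    break
            causal = np.sort(np.array(chosen))
        else:
            causal = np.sort(self.rng.choice(eligible, cfg.n_causal,
                                             replace=False))
        betas = self.rng.standard_normal(cfg.n_causal)

        ref_pairs = self.draw_hap_pairs(cfg.n_reference)
        g_ref = self.dosages_for(ref_pairs, causal) @ betas
        var_g = float(np.var(g_ref))
        if cfg.h2 > 0 and var_g > 0:
            sigma_e = float(np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2))
            var_l = var_g + sigma_e ** 2
        else:
            sigma_e, var_l = 1.0, 1.0
        liab_ref = g_ref + sigma_e * self.rng.standard_normal(cfg.n_reference) \
            if cfg.h2 > 0 else self.rng.standard_normal(cfg.n_reference)
        threshold = float(np.quantile(liab_ref, 1.0 - cfg.prevalence))

        freq = self.pool_freq[causal]
        marg = 2.0 * freq * (1.0 - freq) * betas ** 2 / var_l if cfg.h2 > 0 \
            else np.zeros(cfg.n_causal)
        self._causal_cols = causal
        return SimulationTruth(
            causal_ids=[self.markers["id"].iat[j] for j in causal],
            betas=betas, maf=freq, marginal_h2=marg,
            var_genetic=var_g if cfg.h2 > 0 else 0.0,
            var_liability=var_l, threshold=threshold,
            causal_bp=self.markers["bp"].to_numpy()[causal],
            causal_chrom=self.markers["chrom"].to_numpy()[causal],
            causal_block=self.block_id[causal], sigma_e=sigma_e)

    def liabilities(self, pairs: np.ndarray, truth: SimulationTruth) -> np.ndarray:
        e = truth.sigma_e * self.rng.standard_normal(len(pairs))
        if self.cfg.h2 <= 0:
            return e
        g = self.dosages_for(pairs, self._causal_cols) @ truth.betas
        return g + e

    def simulate_case_control(self, truth: SimulationTruth
                              ) -> tuple[GenotypeDataset, PhenotypeVector]:
        """Draw individuals until the case and control quotas are filled.

        Returns the ascertained analysis dataset (causal columns
        removed; ``truth.causal_dosages`` keeps them for evaluation) and
        the 0/1 phenotype, cases first.
        """
        cfg = self.cfg
        want = {1: cfg.n_cases, 0: cfg.n_controls}
        got = {1: [], 0: []}
        budget = cfg.draw_budget_factor * (cfg.n_cases + cfg.n_controls)
        drawn = 0
        while (len(got[1]) < want[1] or len(got[0]) < want[0]):
            if drawn >= budget:
                raise RuntimeError(
                    f"case/control collection exceeded {budget} draws; "
                    "prevalence too extreme for the requested design")
            batch = min(max(2 * (want[1] + want[0]), 1000), budget - drawn)
            pairs = self.draw_hap_pairs(batch)
            liab = self.liabilities(pairs, truth)
            is_case = liab > truth.threshold
            drawn += batch
            for status in (1, 0):
                need = want[status] - len(got[status])
                if need > 0:
                    sel = pairs[is_case == bool(status)][:need]
                    got[status].extend(sel.tolist())
        pairs = np.array(got[1] + got[0])
        full = self.dataset_for(pairs)
        truth.causal_dosages = full.dosages[:, self._causal_cols].copy()
        keep = np.setdiff1d(np.arange(cfg.n_markers), self._causal_cols)
        analysis = full.subset_markers(keep)
        assert not set(truth.causal_ids) & set(analysis.markers["id"])
        y = PhenotypeVector(np.r_[np.ones(cfg.n_cases), np.zeros(cfg.n_controls)],
                            "logistic")
        return analysis, y


def correlated_marker_block(rng: np.random.Generator, n: int, k: int,
                            latent_rho: float, maf: float = 0.3) -> np.ndarray:
    """k dosage columns with exchangeable within-block correlation.

    Two haplotypes per individual, each thresholded from a shared-factor
    Gaussian with latent correlation ``latent_rho``; the realized dosage
    correlation is somewhat below the latent value (thresholding loss).
    Useful for constructing LD fixtures without a full haplotype pool.
    """
    out = np.zeros((n, k))
    t = stats.norm.ppf(maf)
    for _ in range(2):
        z = (np.sqrt(latent_rho) * rng.standard_normal((n, 1))
             + np.sqrt(1.0 - latent_rho) * rng.standard_normal((n, k)))
        out += z < t
    return out


# ---------------------------------------------------------------------------
# functional interface

def simulate_dataset(cfg: SimulationConfig, distinct_blocks: bool = False
                     ) -> tuple[GenotypeDataset, PhenotypeVector, SimulationTruth]:
    """One ascertained case/control GWAS with ground truth."""
    sim = GwasSimulator(cfg)
    truth = sim.assign_effects(distinct_blocks=distinct_blocks)
    g, y = sim.simulate_case_control(truth)
    return g, y, truth


def generate_genotypes(cfg: SimulationConfig, n: int | None = None
                       ) -> GenotypeDataset:
    """An unascertained population draw of genotypes (all markers)."""
    sim = GwasSimulator(cfg)
    return sim.dataset_for(sim.draw_hap_pairs(n or cfg.n_cases + cfg.n_controls))


def assign_effects(g: GenotypeDataset, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> SimulationTruth:
    """Causal set, effects and variance components for an existing dataset.

    Operates on the dataset's own empirical frequencies and genetic
    values; used when the haplotype-pool machinery is not in play.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    freq_all = g.dosages.mean(axis=0) / 2.0
    eligible = np.flatnonzero(freq_all >= cfg.causal_maf_floor)
    if eligible.size < cfg.n_causal:
        raise ValueError("not enough markers above the causal MAF floor")
    causal = np.sort(rng.choice(eligible, cfg.n_causal, replace=False))
    betas = rng.standard_normal(cfg.n_causal)
    gval = g.dosages[:, causal] @ betas
    var_g = float(np.var(gval))
    if cfg.h2 > 0 and var_g > 0:
        sigma_e = float(np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2))
        var_l = var_g + sigma_e ** 2
    else:
        sigma_e, var_l = 1.0, 1.0
    freq = freq_all[causal]
    marg = (2.0 * freq * (1.0 - freq) * betas ** 2 / var_l if cfg.h2 > 0
            else np.zeros(cfg.n_causal))
    # threshold from the analytic mixture: genetic value of a fresh draw
    ref = (gval[rng.integers(0, g.n, cfg.n_reference)]
           + sigma_e * rng.standard_normal(cfg.n_reference)) if cfg.h2 > 0 \
        else rng.standard_normal(cfg.n_reference)
    return SimulationTruth(
        causal_ids=[g.markers["id"].iat[j] for j in causal], betas=betas,
        maf=freq, marginal_h2=marg, var_genetic=var_g if cfg.h2 > 0 else 0.0,
        var_liability=var_l,
        threshold=float(np.quantile(ref, 1.0 - cfg.prevalence)),
        causal_bp=g.markers["bp"].to_numpy()[causal],
        causal_chrom=g.markers["chrom"].to_numpy()[causal],
        causal_block=np.zeros(cfg.n_causal, dtype=int),
        causal_dosages=g.dosages[:, causal].copy(), sigma_e=sigma_e)


def simulate_phenotypes(g: GenotypeDataset, truth: SimulationTruth,
                        cfg: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> PhenotypeVector:
    """Population (unascertained) case/control phenotypes for ``g``.

    Liability = genetic value + N(0, sigma_e^2); case iff liability
    exceeds the threshold stored in ``truth``.  The case fraction is
    therefore close to the configured prevalence.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if cfg.h2 > 0:
        gval = g.dosages[:, g.marker_index(truth.causal_ids)] @ truth.betas
        liab = gval + truth.sigma_e * rng.standard_normal(g.n)
    else:
        liab = rng.standard_normal(g.n)
    return PhenotypeVector((liab > truth.threshold).astype(float), "logistic")
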