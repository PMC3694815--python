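"""Linear/logistic GLM fits, single-marker and conditional scans.

The scan machinery underpins everything else: pre-screening before the
penalized fit, likelihood-ratio refits for post-hoc scoring, and the
genomic-control inflation factor used as a calibration diagnostic.

Linear-model scans use the exact F-test after residualizing phenotype
and marker against the covariates (Frisch-Waugh); logistic scans use a
per-marker Newton fit and a 1-df likelihood-ratio test against the
covariate-only null, compiled with numba so that genome-sized scans
stay fast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .io import CovariateMatrix, GenotypeDataset, PhenotypeVector

logger = logging.getLogger(__name__)

#: |coefficient| cap applied when a logistic fit separates perfectly
SEPARATION_CAP = 30.0
#: chi-square(1df) median, the genomic-control null calibration constant
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GlmFit:
    """An unpenalized maximum-likelihood fit."""

    params: np.ndarray
    loglik: float
    family: str
    converged: bool
    n_iter: int
    fitted: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


@dataclass
class ScanResult:
    """Per-marker association tests (columns: chrom, id, bp, effect, stat, p)."""

    table: pd.DataFrame
    test_type: str  # "F-test" | "LRT"

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _logistic_newton_nb(X, y, beta, max_iter, tol, cap):
    """Newton-Raphson logistic MLE with step-halving and a coefficient cap.

    Returns (loglik, converged, iterations); beta is updated in place.
    """
    n, q = X.shape
    ll_old = _loglik_nb(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = np.zeros(q)
        H = np.zeros((q, q))
        for i in range(n):
            eta = 0.0
            for k in range(q):
                eta += X[i, k] * beta[k]
            if eta > 35.0:
                mu = 1.0
            elif eta < -35.0:
                mu = 0.0
            else:
                mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu) + 1e-12
            r = y[i] - mu
            for k in range(q):
                g[k] += X[i, k] * r
                for l in range(k, q):
                    H[k, l] += w * X[i, k] * X[i, l]
        for k in range(q):
            for l in range(k):
                H[k, l] = H[l, k]
        step = np.linalg.solve(H + 1e-10 * np.eye(q), g)
        # step-halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            trial = beta + t * step
            for k in range(q):
                if trial[k] > cap:
                    trial[k] = cap
                elif trial[k] < -cap:
                    trial[k] = -cap
            ll_new = _loglik_nb(X, y, trial)
            if ll_new >= ll_old - 1e-12:
                break
            t *= 0.5
        beta[:] = trial
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    capped = False
    for k in range(q):
        if abs(beta[k]) >= cap:
            capped = True
    return ll_old, converged and not capped, it


@njit(cache=True)
def _loglik_nb(X, y, beta):
    n, q = X.shape
    ll = 0.0
    for i in range(n):
        eta = 0.0
        for k in range(q):
            eta += X[i, k] * beta[k]
        if eta > 0.0:
            ll += y[i] * eta - eta - np.log1p(np.exp(-eta))
        else:
            ll += y[i] * eta - np.log1p(np.exp(eta))
    return ll


@njit(cache=True)
def _logistic_scan_nb(G, C, y, beta_null, ll_null, max_iter, tol, cap):
    """Per-marker logistic LRT vs the covariate-only null.

    G is (n, p) dosages, C the (n, c) covariates.  Returns per-marker
    (effect, lrt statistic) arrays; monomorphic markers get stat 0.
    """
    n, p = G.shape
    c = C.shape[1]
    X = np.empty((n, c + 1))
    X[:, :c] = C
    effect = np.zeros(p)
    stat = np.zeros(p)
    mono = np.zeros(p, dtype=np.bool_)
    beta = np.empty(c + 1)
    for j in range(p):
        v0 = G[0, j]
        is_mono = True
        for i in range(1, n):
            if G[i, j] != v0:
                is_mono = False
                break
        if is_mono:
            mono[j] = True
            continue
        X[:, c] = G[:, j]
        beta[:c] = beta_null
        beta[c] = 0.0
        llf, _, _ = _logistic_newton_nb(X, y, beta, max_iter, tol, cap)
        effect[j] = beta[c]
        s = 2.0 * (llf - ll_null)
        stat[j] = s if s > 0.0 else 0.0
    return effect, stat, mono


# ---------------------------------------------------------------------------
# fits

def logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor eta (stable)."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def gaussian_profile_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood profiled over the error variance."""
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _check_rank(X: np.ndarray, labels=None):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column set via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        dep = [i for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        names = [labels[i] for i in dep] if labels else dep
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {names}")


def fit_glm(y: PhenotypeVector, X: np.ndarray | None,
            C: CovariateMatrix | np.ndarray, labels=None,
            max_iter: int = 100, tol: float = 1e-8) -> GlmFit:
    """Unpenalized MLE of ``y ~ C + X`` (X optional extra columns).

    Linear family: closed-form least squares with the Gaussian
    log-likelihood profiled over the error variance.  Logistic family:
    Newton-Raphson (equivalently IRLS) with step-halving; under perfect
    separation coefficients are capped at +-30 and the fit is flagged
    non-converged, but the (capped) log-likelihood is still usable in
    likelihood-ratio tests.
    """
    Cv = C.values if isinstance(C, CovariateMatrix) else np.asarray(C, float)
    design = Cv if X is None else np.column_stack([Cv, np.asarray(X, float)])
    if y.n <= design.shape[1]:
        raise ValueError("need n > number of design columns")
    _check_rank(design, labels)
    yv = y.values
    if y.family == "linear":
        params, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
        fitted = design @ params
        rss = float(np.sum((yv - fitted) ** 2))
        ll = gaussian_profile_loglik(max(rss, 1e-300), y.n)
        return GlmFit(params, ll, "linear", True, 0, fitted)
    beta = np.zeros(design.shape[1])
    Xc = np.ascontiguousarray(design)
    ll, converged, it = _logistic_newton_nb(Xc, yv, beta, max_iter, tol,
                                            SEPARATION_CAP)
    eta = design @ beta
    fitted = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return GlmFit(beta, float(ll), "logistic", bool(converged), int(it), fitted)


# ---------------------------------------------------------------------------
# scans

def single_marker_scan(g: GenotypeDataset, y: PhenotypeVector,
                       C: CovariateMatrix | None = None) -> ScanResult:
    """Marginal association test of every marker, adjusted for covariates.

    Fits ``y ~ C + g_j`` per marker.  Linear phenotypes use the exact
    1-df F-test; case/control phenotypes use a likelihood-ratio test
    against ``y ~ C``.  Monomorphic markers are reported with p = 1 and
    zero effect.
    """
    if g.has_missing:
        raise ValueError("impute missing genotypes before scanning")
    C = C or CovariateMatrix.intercept_only(g.n)
    G = np.ascontiguousarray(g.dosages)
    yv = y.values

    if y.family == "linear":
        # Frisch-Waugh: residualize y and markers on C, then univariate fits
        Q, _ = np.linalg.qr(C.values)
        yr = yv - Q @ (Q.T @ yv)
        Gr = G - Q @ (Q.T @ G)
        sxx = np.einsum("ij,ij->j", Gr, Gr)
        mono = sxx < 1e-12
        sxx_safe = np.where(mono, 1.0, sxx)
        sxy = Gr.T @ yr
        beta = np.where(mono, 0.0, sxy / sxx_safe)
        rss0 = float(yr @ yr)
        rss1 = np.maximum(rss0 - beta * sxy, 1e-300)
        df2 = g.n - C.c - 1
        fstat = np.where(mono, 0.0, (rss0 - rss1) / (rss1 / df2))
        pvals = np.where(mono, 1.0, stats.f.sf(fstat, 1, df2))
        stat, test = fstat, "F-test"
    else:
        null = fit_glm(y, None, C)
        effect, stat, mono = _logistic_scan_nb(
            G, np.ascontiguousarray(C.values), yv, null.params,
            null.loglik, 50, 1e-10, SEPARATION_CAP)
        pvals = np.where(mono, 1.0, stats.chi2.sf(stat, 1))
        beta = np.where(mono, 0.0, effect)
        test = "LRT"
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic markers reported with p=1",
                      stacklevel=2)
    table = g.markers[["chrom", "id", "bp"]].copy()
    table["effect"] = beta
    table["stat"] = stat
    table["p"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return ScanResult(table, test)


def prescreen(scan: ScanResult, cutoff: float = 0.01) -> np.ndarray:
    """Indices of markers with marginal p <= cutoff (order preserved).

    Pre-screening discards markers whose marginal association is so weak
    that they are extremely unlikely to receive a nonzero coefficient in
    the joint penalized fit; sure-screening theory shows the relevant
    markers are retained with probability tending to one.
    """
    keep = np.flatnonzero(scan.p_values <= cutoff)
    if keep.size == 0:
        raise ValueError(
            f"no markers pass the pre-screen at p <= {cutoff}; relax the cutoff")
    logger.info("prescreen retained %d/%d markers (%.3f) at p <= %g",
                keep.size, len(scan.table), keep.size / len(scan.table), cutoff)
    return keep


def _prune_hits_by_window(table: pd.DataFrame, hits: np.ndarray,
                          window: int) -> list[int]:
    """Keep the smallest-p hit per `window`-bp stretch, per chromosome."""
    kept: list[int] = []
    order = hits[np.argsort(table["p"].to_numpy()[hits], kind="stable")]
    for j in order:
        chrom, bp = table["chrom"].iat[j], table["bp"].iat[j]
        if all(table["chrom"].iat[k] != chrom or abs(table["bp"].iat[k] - bp) > window
               for k in kept):
            kept.append(int(j))
    return sorted(kept)


def conditional_scan(g: GenotypeDataset, y: PhenotypeVector,
                     C: CovariateMatrix | None = None,
                     stage1_cutoff: float = 1e-5,
                     window: int = 100_000) -> ScanResult:
    """Two-stage conditional regression scan.

    Stage-1 hits (p <= cutoff) are pruned to the single strongest marker
    per ``window`` bp and added to the covariates; remaining markers are
    re-tested conditional on them, and each marker is reported with the
    minimum of its two p-values (stage-1 covariate markers keep their
    stage-1 p).
    """
    C = C or CovariateMatrix.intercept_only(g.n)
    stage1 = single_marker_scan(g, y, C)
    hits = np.flatnonzero(stage1.p_values <= stage1_cutoff)
    if hits.size == 0:
        logger.info("no stage-1 hits at p <= %g; returning marginal scan",
                    stage1_cutoff)
        return stage1
    lead = _prune_hits_by_window(stage1.table, hits, window)
    C2 = CovariateMatrix(
        np.column_stack([C.values, g.dosages[:, lead]]),
        C.labels + [f"stage1:{g.markers['id'].iat[j]}" for j in lead])
    stage2 = single_marker_scan(g, y, C2)
    table = stage1.table.copy()
    better = stage2.table["p"].to_numpy() < table["p"].to_numpy()
    better[lead] = False  # conditioning markers keep their stage-1 test
    for colname in ("effect", "stat", "p"):
        vals = table[colname].to_numpy().copy()
        vals[better] = stage2.table[colname].to_numpy()[better]
        table[colname] = vals
    return ScanResult(table, stage1.test_type)


def genomic_inflation(p_values: np.ndarray | ScanResult) -> float:
    """Genomic-control inflation factor: median chi2(1) quantile / 0.4549."""
    if isinstance(p_values, ScanResult):
        p_values = p_values.p_values
    p = np.asarray(p_values, float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable median")
    chi = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)
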