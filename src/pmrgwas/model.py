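"""Penalized maximum-likelihood estimation for sparse GWAS regression.

The centerpiece is :class:`PenalizedGLM`, a statsmodels-style model
object: construct it from a phenotype, a marker matrix and unpenalized
covariates, then call :meth:`~PenalizedGLM.fit` (one penalized fit),
:meth:`~PenalizedGLM.fit_reorderings` (multimodal exploration for
non-convex penalties), :meth:`~PenalizedGLM.fit_path` (convex
regularization path) or :meth:`~PenalizedGLM.fit_grid` (the 1D/2D
tuning-parameter grid for the non-convex families).  Fits are returned
as :class:`PenalizedGLMResults`; path/grid searches return a
:class:`ModelPath` whose :meth:`~ModelPath.select` applies min-AIC model
selection under the sample-size-dependent sparsity bound
ceil(sqrt(n / log n)).

The solver is minorize-maximization coordinate ascent: each coordinate
maximizes a quadratic lower bound of the log-likelihood whose curvature
``d_j`` dominates the negative second derivative (sum(x_ij^2)/4 for the
logistic model, sum(x_ij^2) for the linear model), so every single
coordinate update is guaranteed not to decrease the penalized
objective.  Marker columns are mean-centered before fitting so the
penalty rate has a per-allele interpretation; reported coefficients
remain on the dosage scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .glm import fit_glm, gaussian_profile_loglik, logistic_loglik
from .io import CovariateMatrix, GenotypeDataset, PhenotypeVector
from .penalties import PenaltySpec, adaptive_weights, coordinate_update, penalty_value

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-5
DEFAULT_MAX_SWEEPS = 500

#: shape schedules per non-convex family, ordered from near-lasso
#: (weak non-convexity) to aggressive; the 1D mode pins the starred value.
SHAPE_SCHEDULES = {
    "mcp": (100.0, 30.0, 10.0, 3.0, 1.5),
    "log": (100.0, 10.0, 1.0, 0.1, 0.01),
    "neg": (100.0, 10.0, 3.0, 1.0, 0.3),
}
MCP_FIXED_SHAPE = 30.0  # the perm-MCP convention for gamma


def model_size_bound(n: int) -> int:
    """Largest detectable model size for sample size n: ceil(sqrt(n/log n))."""
    if n < 10:
        raise ValueError("need n >= 10")
    return int(np.ceil(np.sqrt(n / np.log(n))))


# ---------------------------------------------------------------------------
# numba sweep kernel (lasso / adaptive lasso / MCP)

@njit(cache=True)
def _mcp_update(z, d, lam, gamma):
    a = abs(z)
    s = 1.0 if z >= 0 else -1.0
    if gamma * d > 1.0:
        if a <= lam / d:
            return 0.0
        if a <= gamma * lam:
            return s * (a - lam / d) / (1.0 - 1.0 / (gamma * d))
        return z
    # convex-surrogate corner case: compare candidates {0, gamma*lam, a}
    plateau = gamma * lam * lam / 2.0
    best_b, best_h = 0.0, -(d / 2.0) * a * a
    b = gamma * lam
    h = -(d / 2.0) * (b - a) ** 2 - (lam * b - b * b / (2.0 * gamma))
    if h > best_h:
        best_b, best_h = b, h
    if a > gamma * lam:
        h = -plateau
        if h > best_h:
            best_b = a
    return s * best_b


@njit(cache=True)
def _sweeps_nb(XT, CT, y, dx, dc, beta, alpha, eta, family, pen,
               rate, gamma, weights, order, tol, max_sweeps):
    """Coordinate-ascent sweeps; family 0=linear 1=logistic, pen 0=soft 1=mcp.

    Full sweeps alternate with active-set refinement passes over the
    currently nonzero coefficients; converged when no full sweep moves
    any coefficient by more than tol.
    """
    p, n = XT.shape
    c = CT.shape[0]
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        md = _one_pass(XT, CT, y, dx, dc, beta, alpha, eta, family, pen,
                       rate, gamma, weights, order, False)
        sweeps += 1
        if md < tol:
            converged = True
            break
        while sweeps < max_sweeps:
            md2 = _one_pass(XT, CT, y, dx, dc, beta, alpha, eta, family, pen,
                            rate, gamma, weights, order, True)
            sweeps += 1
            if md2 < tol:
                break
    return sweeps, converged


@njit(cache=True)
def _one_pass(XT, CT, y, dx, dc, beta, alpha, eta, family, pen,
              rate, gamma, weights, order, active_only):
    p, n = XT.shape
    c = CT.shape[0]
    maxdelta = 0.0
    # unpenalized covariates first
    for k in range(c):
        grad = 0.0
        if family == 1:
            for i in range(n):
                e = eta[i]
                if e > 35.0:
                    mu = 1.0
                elif e < -35.0:
                    mu = 0.0
                else:
                    mu = 1.0 / (1.0 + np.exp(-e))
                grad += CT[k, i] * (y[i] - mu)
        else:
            for i in range(n):
                grad += CT[k, i] * (y[i] - eta[i])
        delta = grad / dc[k]
        if delta != 0.0:
            alpha[k] += delta
            for i in range(n):
                eta[i] += CT[k, i] * delta
            if abs(delta) > maxdelta:
                maxdelta = abs(delta)
    # penalized markers in the given order
    for t in range(p):
        j = order[t]
        if dx[j] < 1e-12:
            continue
        if active_only and beta[j] == 0.0:
            continue
        grad = 0.0
        if family == 1:
            for i in range(n):
                e = eta[i]
                if e > 35.0:
                    mu = 1.0
                elif e < -35.0:
                    mu = 0.0
                else:
                    mu = 1.0 / (1.0 + np.exp(-e))
                grad += XT[j, i] * (y[i] - mu)
        else:
            for i in range(n):
                grad += XT[j, i] * (y[i] - eta[i])
        z = beta[j] + grad / dx[j]
        lam = rate * weights[j]
        if pen == 0:
            a = abs(z)
            new = 0.0 if a <= lam / dx[j] else (a - lam / dx[j]) * (1.0 if z >= 0 else -1.0)
        else:
            new = _mcp_update(z, dx[j], lam, gamma)
        delta = new - beta[j]
        if delta != 0.0:
            beta[j] = new
            for i in range(n):
                eta[i] += XT[j, i] * delta
            if abs(delta) > maxdelta:
                maxdelta = abs(delta)
    return maxdelta


# ---------------------------------------------------------------------------
# results containers

@dataclass
class PenalizedGLMResults:
    """One penalized maximum-likelihood solution (a sparse fit)."""

    beta: np.ndarray                  # marker coefficients, dosage scale
    alpha: np.ndarray                 # unpenalized covariate coefficients
    loglik: float                     # unpenalized log-likelihood at the fit
    objective: float                  # penalized solver objective
    spec: PenaltySpec
    converged: bool
    n_sweeps: int
    order_seed: int | None = None
    model: "PenalizedGLM | None" = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        """Number of markers with nonzero coefficients."""
        return int(np.count_nonzero(self.beta))

    @property
    def support(self) -> frozenset:
        return frozenset(np.flatnonzero(self.beta).tolist())

    @property
    def aic(self) -> float:
        """AIC = -2 loglik + 2 (k + number of covariates)."""
        return -2.0 * self.loglik + 2.0 * (self.k + self.alpha.size)

    def summary(self) -> str:
        lines = [
            "Penalized GLM fit",
            f"  family:     {self.model.family if self.model else '?'}",
            f"  penalty:    {self.spec.family} (rate={self.spec.rate:.5g}"
            + (f", shape={self.spec.shape:.5g})" if self.spec.shape else ")"),
            f"  selected k: {self.k}",
            f"  loglik:     {self.loglik:.4f}",
            f"  AIC:        {self.aic:.4f}",
            f"  converged:  {self.converged} ({self.n_sweeps} sweeps)",
        ]
        if self.model is not None and self.k:
            lines.append("  nonzero markers (dosage-scale coefficients):")
            for j in np.flatnonzero(self.beta):
                lines.append(f"    [{j}] {self.beta[j]:+.5f}")
        return "\n".join(lines)


@dataclass
class ModelPath:
    """Fits collected over a tuning-parameter path or grid."""

    fits: list[PenalizedGLMResults]
    family: str                       # penalty family searched
    n: int                            # sample size (for the selection bound)

    @property
    def n_models(self) -> int:
        return len(self.fits)

    @property
    def n_unique_models(self) -> int:
        """Number of distinct selected-marker sets among all fits."""
        return len({f.support for f in self.fits})

    def extend(self, other: "ModelPath") -> None:
        self.fits.extend(other.fits)

    def select(self, n: int | None = None,
               k_max: int | None = None) -> PenalizedGLMResults:
        """Min-AIC fit among those within the model-size bound.

        Ties are broken toward smaller models, then first encountered.
        If every fit exceeds the bound the null (most penalized) model
        is returned with a warning.
        """
        n = n or self.n
        bound = k_max if k_max is not None else model_size_bound(n)
        admissible = [f for f in self.fits if f.k <= bound]
        if not admissible:
            warnings.warn("all fits exceed the model-size bound; "
                          "returning the null model", stacklevel=2)
            null = min(self.fits, key=lambda f: f.k)
            return null
        return min(enumerate(admissible),
                   key=lambda t: (t[1].aic, t[1].k, t[0]))[1]


# ---------------------------------------------------------------------------
# the model object

class PenalizedGLM:
    """Sparse penalized GLM of a phenotype on genotype dosages.

    Parameters
    ----------
    y : PhenotypeVector or ndarray
        Phenotype; 0/1 for the logistic family.
    markers : ndarray or GenotypeDataset
        n x p dosage matrix of the (pre-screened, imputed) markers that
        receive the sparsity penalty.
    covariates : CovariateMatrix or ndarray, optional
        Unpenalized design including the intercept; defaults to
        intercept only.
    family : str, optional
        'linear' or 'logistic'; inferred from ``y`` when omitted.
    """

    def __init__(self, y, markers, covariates=None, family=None):
        if isinstance(markers, GenotypeDataset):
            if markers.has_missing:
                raise ValueError("impute missing genotypes before fitting")
            self.marker_ids = markers.markers["id"].to_numpy()
            X = markers.dosages
        else:
            X = np.asarray(markers, dtype=np.float64)
            self.marker_ids = None
        if isinstance(y, PhenotypeVector):
            family = family or y.family
            y = y.values
        self.y = np.asarray(y, dtype=np.float64)
        self.family = family or "logistic"
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if covariates is None:
            covariates = CovariateMatrix.intercept_only(len(self.y))
        C = covariates.values if isinstance(covariates, CovariateMatrix) else \
            np.atleast_2d(np.asarray(covariates, float))
        self.n, self.p = X.shape
        if C.shape[0] != self.n or self.y.shape[0] != self.n:
            raise ValueError("y, markers and covariates disagree on n")
        self.C = np.ascontiguousarray(C)
        self.col_means = X.mean(axis=0)
        self.XT = np.ascontiguousarray((X - self.col_means).T)  # (p, n), centered
        sq_x = np.einsum("ji,ji->j", self.XT, self.XT)
        sq_c = np.einsum("ij,ij->j", self.C, self.C)
        if self.family == "logistic":
            self.dx = sq_x / 4.0
            self.dc = np.maximum(sq_c / 4.0, 1e-12)
        else:
            self.dx = sq_x
            self.dc = np.maximum(sq_c, 1e-12)
        self._null_alpha = fit_glm(
            PhenotypeVector(self.y, self.family), None, self.C).params

    # -- likelihood pieces ---------------------------------------------------

    def _eta(self, beta, alpha):
        return self.C @ alpha + self.XT.T @ beta

    def loglik(self, beta, alpha) -> float:
        """Reporting log-likelihood (Gaussian profile for the linear family)."""
        eta = self._eta(beta, alpha)
        if self.family == "logistic":
            return logistic_loglik(eta, self.y)
        rss = float(np.sum((self.y - eta) ** 2))
        return gaussian_profile_loglik(max(rss, 1e-300), self.n)

    def _solver_loglik(self, eta) -> float:
        if self.family == "logistic":
            return logistic_loglik(eta, self.y)
        return -0.5 * float(np.sum((self.y - eta) ** 2))

    def objective(self, beta, alpha, spec: PenaltySpec) -> float:
        """Penalized objective: solver log-likelihood minus total penalty."""
        pen = sum(float(penalty_value(abs(b), spec, j))
                  for j, b in enumerate(beta) if b != 0.0)
        return self._solver_loglik(self._eta(beta, alpha)) - pen

    def lambda_max(self, weights=None) -> float:
        """Smallest rate at which the fit is null (entry threshold).

        max_j |gradient_j| at the covariate-only fit, divided by the
        adaptive weight when one applies.
        """
        eta = self.C @ self._null_alpha
        resid = (self.y - 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
                 if self.family == "logistic" else self.y - eta)
        grad = self.XT @ resid
        if weights is not None:
            grad = grad / weights
        return float(np.max(np.abs(grad))) if grad.size else 0.0

    # -- fitting -------------------------------------------------------------

    def fit(self, spec: PenaltySpec, order: np.ndarray | None = None,
            warm_start: PenalizedGLMResults | None = None,
            tol: float = DEFAULT_TOL, max_sweeps: int = DEFAULT_MAX_SWEEPS,
            debug_monotone: bool = False,
            order_seed: int | None = None) -> PenalizedGLMResults:
        """One penalized MM coordinate-ascent fit.

        ``order`` is the marker update permutation (natural order by
        default); ``warm_start`` seeds the coefficients from a previous
        fit.  With ``debug_monotone`` the pure-python path is used and
        the penalized objective is asserted non-decreasing after every
        single coordinate update (the MM guarantee).
        """
        order = np.arange(self.p, dtype=np.int64) if order is None \
            else np.asarray(order, dtype=np.int64)
        if warm_start is not None:
            beta = warm_start.beta.copy()
            alpha = warm_start.alpha.copy()
        else:
            beta = np.zeros(self.p)
            alpha = self._null_alpha.copy()
        eta = self._eta(beta, alpha)
        weights = (np.asarray(spec.weights, float) if spec.weights is not None
                   else np.ones(self.p))

        fast = spec.family in ("lasso", "adaptive_lasso", "mcp") and not debug_monotone
        if fast:
            pen = 1 if spec.family == "mcp" else 0
            gamma = spec.shape if spec.family == "mcp" else 0.0
            sweeps, converged = _sweeps_nb(
                self.XT, self.C.T.copy(), self.y, self.dx, self.dc,
                beta, alpha, eta, 1 if self.family == "logistic" else 0,
                pen, spec.rate, gamma, weights, order, tol, max_sweeps)
        else:
            sweeps, converged = self._sweeps_py(
                beta, alpha, eta, spec, order, tol, max_sweeps, debug_monotone)
        if not converged:
            logger.warning("pMLE fit did not converge in %d sweeps", sweeps)
        return PenalizedGLMResults(
            beta=beta, alpha=alpha, loglik=self.loglik(beta, alpha),
            objective=self.objective(beta, alpha, spec), spec=spec,
            converged=bool(converged), n_sweeps=int(sweeps),
            order_seed=order_seed, model=self)

    def _sweeps_py(self, beta, alpha, eta, spec, order, tol, max_sweeps,
                   debug_monotone):
        """Generic python sweep path (all families; optional MM assertion)."""
        obj = self.objective(beta, alpha, spec) if debug_monotone else None
        logistic = self.family == "logistic"

        def mu_of(eta):
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

        def one_pass(active_only):
            nonlocal obj, eta
            maxdelta = 0.0
            for k in range(self.C.shape[1]):
                resid = self.y - (mu_of(eta) if logistic else eta)
                delta = float(self.C[:, k] @ resid) / self.dc[k]
                if delta:
                    alpha[k] += delta
                    eta += self.C[:, k] * delta
                    maxdelta = max(maxdelta, abs(delta))
            for j in order:
                if self.dx[j] < 1e-12 or (active_only and beta[j] == 0.0):
                    continue
                resid = self.y - (mu_of(eta) if logistic else eta)
                grad = float(self.XT[j] @ resid)
                z = beta[j] + grad / self.dx[j]
                new = coordinate_update(z, float(self.dx[j]), spec, j)
                delta = new - beta[j]
                if delta:
                    beta[j] = new
                    eta += self.XT[j] * delta
                    maxdelta = max(maxdelta, abs(delta))
                    if debug_monotone:
                        new_obj = self.objective(beta, alpha, spec)
                        assert new_obj >= obj - 1e-9, (
                            f"MM monotonicity violated: {obj} -> {new_obj}")
                        obj = new_obj
            return maxdelta

        sweeps, converged = 0, False
        while sweeps < max_sweeps:
            md = one_pass(False)
            sweeps += 1
            if md < tol:
                converged = True
                break
            while sweeps < max_sweeps:
                if one_pass(True) < tol:
                    sweeps += 1
                    break
                sweeps += 1
        return sweeps, converged

    def fit_reorderings(self, spec: PenaltySpec, n_orders: int = 100,
                        seed: int = 0,
                        warm_start: PenalizedGLMResults | None = None,
                        **kw) -> list[PenalizedGLMResults]:
        """Fits under random coordinate update orders (seeded).

        Non-convex penalties have multimodal objectives; permuting the
        update order explores distinct modes.  Convex families return
        the single natural-order fit.
        """
        if spec.is_convex:
            return [self.fit(spec, warm_start=warm_start, **kw)]
        rng = np.random.default_rng(seed)
        fits = []
        for r in range(n_orders):
            order = rng.permutation(self.p)
            fits.append(self.fit(spec, order=order, warm_start=warm_start,
                                 order_seed=seed + r if n_orders > 1 else seed,
                                 **kw))
        return fits

    def fit_path(self, family: str = "lasso", k_max: int | None = None,
                 rate_factor: float = 0.8, max_points: int = 100,
                 **kw) -> ModelPath:
        """Convex regularization path from the null model down to k_max.

        The rate starts at the entry threshold (null fit) and decreases
        on a multiplicative grid, warm-starting every fit from the
        previous one, until ``k_max`` markers are selected.  The
        adaptive lasso runs the two-step procedure: a lasso path, AIC
        selection for the initial estimates, then the weighted path.
        """
        if family not in ("lasso", "adaptive_lasso"):
            raise ValueError("fit_path is for the convex families")
        k_max = k_max or model_size_bound(self.n)
        if family == "adaptive_lasso":
            init_path = self.fit_path("lasso", k_max=k_max,
                                      rate_factor=rate_factor,
                                      max_points=max_points, **kw)
            init = init_path.select(self.n)
            if init.k == 0:
                nonnull = [f for f in init_path.fits if f.k > 0]
                if not nonnull:
                    raise ValueError("lasso initialization selected no markers; "
                                     "increase k_max or relax the penalty")
                init = nonnull[0]
            weights = adaptive_weights(init.beta)
        else:
            weights = None

        lam_max = self.lambda_max(weights)
        fits = []
        rate = lam_max
        prev = None
        for _ in range(max_points):
            spec = PenaltySpec(family, rate, weights=weights)
            prev = self.fit(spec, warm_start=prev, **kw)
            fits.append(prev)
            if prev.k >= k_max:
                break
            rate *= rate_factor
        return ModelPath(fits, family, self.n)

    def fit_grid(self, family: str, k_max: int | None = None,
                 n_orders: int = 100, mode: str = "2D", seed: int = 0,
                 shapes=None, n_warm: int = 5, rate_factor: float = 0.8,
                 **kw) -> ModelPath:
        """1D/2D tuning-parameter grid search for a non-convex family.

        The outer loop takes lasso path solutions at roughly equally
        spaced model sizes up to ``k_max`` as warm starts; the inner
        loop increases the non-convexity of the penalty (decreasing MCP
        gamma toward 1, and the analogous shape schedules for LOG and
        NEG), refitting with ``n_orders`` random update orders per grid
        cell.  ``mode='1D'`` pins the shape at the perm-MCP convention
        (gamma = 30 for MCP; the schedule midpoint otherwise) and
        searches the rate only.
        """
        if family not in ("mcp", "log", "neg"):
            raise ValueError("fit_grid is for the non-convex families")
        k_max = k_max or model_size_bound(self.n)
        if shapes is None:
            shapes = (SHAPE_SCHEDULES[family] if mode == "2D" else
                      ((MCP_FIXED_SHAPE,) if family == "mcp"
                       else (SHAPE_SCHEDULES[family][2],)))
        lasso_path = self.fit_path("lasso", k_max=k_max,
                                   rate_factor=rate_factor, **kw)
        targets = np.unique(np.maximum(
            np.round(np.linspace(k_max / n_warm, k_max, n_warm)), 1))
        ks = np.array([f.k for f in lasso_path.fits])
        warm_idx = sorted({int(np.argmin(np.abs(ks - t))) for t in targets})

        all_fits = list(lasso_path.fits)
        for b, wi in enumerate(warm_idx):
            warm = lasso_path.fits[wi]
            prev = warm
            for si, shape in enumerate(shapes):
                spec = PenaltySpec(family, warm.spec.rate, shape)
                fits = self.fit_reorderings(
                    spec, n_orders=n_orders,
                    seed=seed + 1000 * b + 10 * si,
                    warm_start=prev, **kw)
                all_fits.extend(fits)
                prev = max(fits, key=lambda f: f.objective)
        return ModelPath(all_fits, family, self.n)

    def perm_mcp_rate(self, shape: float = MCP_FIXED_SHAPE,
                      efpr: float = 1e-3, n_perms: int = 20, seed: int = 0,
                      rate_factor: float = 0.9, max_points: int = 80,
                      **kw) -> float:
        """Permutation-tuned MCP rate at fixed gamma.

        The phenotype is permuted ``n_perms`` times; on each permutation
        the MCP entry path is traced over a decreasing rate grid and the
        number of selected markers recorded.  The returned rate is the
        (log-linear interpolated) value at which the *average* selected
        count equals ``efpr`` times the number of screened markers.
        """
        target = efpr * self.p
        rng = np.random.default_rng(seed)
        lam0 = None
        counts = None
        for _ in range(n_perms):
            yp = rng.permutation(self.y)
            perm = PenalizedGLM(yp, self.XT.T + self.col_means, self.C,
                                family=self.family)
            if lam0 is None:
                lam0 = perm.lambda_max() * 1.05
                rates = lam0 * rate_factor ** np.arange(max_points)
                counts = np.zeros(max_points)
            prev = None
            for i, rate in enumerate(rates):
                prev = perm.fit(PenaltySpec("mcp", rate, shape),
                                warm_start=prev, **kw)
                counts[i] += prev.k
                if prev.k > max(5.0 * target, target + 5.0):
                    counts[i + 1:] += prev.k  # lower rates select at least as many
                    break
        counts /= n_perms
        idx = np.flatnonzero(counts >= target)
        if idx.size == 0:
            warnings.warn("permutation grid never reached the eFPR target; "
                          "returning the smallest grid rate", stacklevel=2)
            return float(rates[-1])
        i = int(idx[0])
        if i == 0 or counts[i] == counts[i - 1]:
            return float(rates[i])
        # interpolate in log-rate between the bracketing grid points
        f = (target - counts[i - 1]) / (counts[i] - counts[i - 1])
        return float(np.exp(np.log(rates[i - 1])
                            + f * (np.log(rates[i]) - np.log(rates[i - 1]))))


# ---------------------------------------------------------------------------
# functional wrappers mirroring the operation-style interface

def fit_pmle(g, y, C, spec, order=None, warm_start=None, **kw):
    return PenalizedGLM(y, g, C).fit(spec, order=order, warm_start=warm_start, **kw)


def fit_with_reorderings(g, y, C, spec, n_orders=100, seed=0, **kw):
    return PenalizedGLM(y, g, C).fit_reorderings(spec, n_orders, seed, **kw)


def convex_path(g, y, C, family="lasso", k_max=None, **kw):
    return PenalizedGLM(y, g, C).fit_path(family, k_max=k_max, **kw)


def nonconvex_grid(g, y, C, family="mcp", k_max=None, n_orders=100,
                   mode="2D", seed=0, **kw):
    return PenalizedGLM(y, g, C).fit_grid(family, k_max=k_max,
                                          n_orders=n_orders, mode=mode,
                                          seed=seed, **kw)


def select_model(path: ModelPath, n: int | None = None,
                 k_max: int | None = None) -> PenalizedGLMResults:
    return path.select(n, k_max)


def perm_mcp_rate(g, y, C, shape=MCP_FIXED_SHAPE, efpr=1e-3, n_perms=20,
                  seed=0, **kw):
    return PenalizedGLM(y, g, C).perm_mcp_rate(shape, efpr, n_perms, seed, **kw)
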