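"""Sparsity penalties and their coordinate-wise thresholding operators.

Five penalty families on the magnitude of a regression coefficient are
supported: the convex lasso and adaptive lasso, and the non-convex MCP,
LOG and NEG penalties.  Each family is parameterized by a primary *rate*
parameter (the slope of the penalty near the origin, which sets the
signal level below which a coefficient is zeroed) and, for the
non-convex families, a *shape* parameter controlling how quickly the
penalty derivative tails off to zero for large coefficients:

========  =========================================================
lasso     P(b) = rate * b
adaptive  P_j(b) = rate * w_j * b   with per-marker weights w_j
mcp       P(b) = rate*b - b^2/(2*shape)  for b <= shape*rate,
          else shape*rate^2/2   (derivative hits 0 at b = shape*rate)
log       P(b) = rate * log(1 + b/shape) / log(1 + 1/shape)
neg       normal-exponential-gamma negative log marginal density,
          defined through its derivative (a ratio of parabolic
          cylinder functions) normalized so P'(0) = rate;
          shape is the NEG scale parameter
========  =========================================================

All penalties are normalized so P(0) = 0, are non-decreasing and
continuous in b, and the non-convex ones are concave in b.

The solver never evaluates the penalty directly during ascent; it calls
:func:`coordinate_update`, the exact maximizer of the minorizing
quadratic surrogate -(d/2)(beta - z)^2 - P(|beta|), which for lasso is
the soft-threshold rule and for MCP the firm-threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

FAMILIES = ("lasso", "adaptive_lasso", "log", "neg", "mcp")

#: fixed NEG mixing-shape hyperparameter (exponential-gamma shape a); the
#: two tuning parameters exposed are the origin slope and the scale.
_NEG_A = 1.0
#: argument beyond which the parabolic-cylinder ratio D_{-2a-2}/D_{-2a-1}
#: is replaced by its 1/x asymptote (the exact ratio 0/0-underflows).
_NEG_XMAX = 20.0


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its tuning parameters.

    Parameters
    ----------
    family : str
        One of ``lasso``, ``adaptive_lasso``, ``log``, ``neg``, ``mcp``.
    rate : float
        Primary tuning parameter, the slope of the penalty near the
        origin (log-likelihood units per unit coefficient).
    shape : float, optional
        Second tuning parameter for the non-convex families: MCP
        ``gamma > 1`` (coefficient value relative to ``rate`` at which
        the derivative reaches zero), LOG ``eta > 0``, NEG scale
        ``s > 0``.
    weights : ndarray, optional
        Strictly positive per-marker multipliers (adaptive lasso only).
    """

    family: str
    rate: float
    shape: float | None = None
    weights: np.ndarray | None = field(default=None, compare=False)

    _DEFAULT_SHAPE = {"mcp": 30.0, "log": 0.1, "neg": 1.0}

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.shape is None and self.family in self._DEFAULT_SHAPE:
            object.__setattr__(self, "shape", self._DEFAULT_SHAPE[self.family])
        if self.family == "mcp" and not self.shape > 1:
            raise ValueError("mcp shape (gamma) must be > 1")
        if self.family in ("log", "neg") and not self.shape > 0:
            raise ValueError(f"{self.family} shape must be > 0")
        if self.weights is not None:
            if self.family != "adaptive_lasso":
                raise ValueError("weights only apply to adaptive_lasso")
            if np.any(np.asarray(self.weights) <= 0):
                raise ValueError("adaptive weights must be strictly positive")

    @property
    def is_convex(self) -> bool:
        return self.family in ("lasso", "adaptive_lasso")

    def with_rate(self, rate: float) -> "PenaltySpec":
        return replace(self, rate=rate)

    def weight(self, j: int | None) -> float:
        """Per-coordinate multiplier on ``rate`` (1 except adaptive lasso)."""
        if self.weights is None or j is None:
            return 1.0
        return float(self.weights[j])


# ---------------------------------------------------------------------------
# NEG shrinkage derivative

def _pbdv_ratio(x: np.ndarray) -> np.ndarray:
    """D_{-2a-2}(x) / D_{-2a-1}(x) for a = _NEG_A, with 1/x asymptote."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _NEG_XMAX
    if np.any(small):
        xs = x[small]
        num = special.pbdv(-2.0 * _NEG_A - 2.0, xs)[0]
        den = special.pbdv(-2.0 * _NEG_A - 1.0, xs)[0]
        out[small] = num / den
    if np.any(~small):
        out[~small] = 1.0 / x[~small]
    return out


_NEG_R0 = float(_pbdv_ratio(np.array(0.0)))
_GAUSS64 = np.polynomial.legendre.leggauss(64)


def penalty_deriv(b, spec: PenaltySpec, j: int | None = None):
    """dP/db at magnitude ``b`` >= 0 (one-sided derivative at 0)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("penalty derivative defined for b >= 0")
    lam = spec.rate * spec.weight(j)
    if spec.family in ("lasso", "adaptive_lasso"):
        return np.broadcast_to(lam, b.shape).copy() if b.ndim else lam
    if spec.family == "mcp":
        return np.maximum(lam - b / spec.shape, 0.0)
    if spec.family == "log":
        c = lam / np.log1p(1.0 / spec.shape)
        return c / (spec.shape + b)
    # neg: normalized parabolic-cylinder ratio; saturates to ~ s/b decay
    return lam * _pbdv_ratio(b / spec.shape) / _NEG_R0


def penalty_value(b, spec: PenaltySpec, j: int | None = None):
    """Penalty P(b) at coefficient magnitude ``b`` (>= 0), with P(0) = 0."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("penalty defined on magnitudes b >= 0")
    lam = spec.rate * spec.weight(j)
    if spec.family in ("lasso", "adaptive_lasso"):
        return lam * b
    if spec.family == "mcp":
        g = spec.shape
        return np.where(b <= g * lam, lam * b - b * b / (2.0 * g),
                        g * lam * lam / 2.0)
    if spec.family == "log":
        return lam * np.log1p(b / spec.shape) / np.log1p(1.0 / spec.shape)
    # neg: no elementary antiderivative; Gauss-Legendre quadrature of the
    # (smooth, monotone) derivative is exact to machine precision here
    scalar = b.ndim == 0
    nodes, wts = _GAUSS64
    vals = np.empty(np.atleast_1d(b).shape)
    for i, bi in enumerate(np.atleast_1d(b).ravel()):
        t = 0.5 * bi * (nodes + 1.0)
        vals.flat[i] = 0.5 * bi * float(wts @ penalty_deriv(t, spec, j))
    return float(vals[0]) if scalar else vals


# ---------------------------------------------------------------------------
# coordinate update (thresholding operators)

def _surrogate(beta: float, z: float, d: float, spec, j) -> float:
    return -(d / 2.0) * (beta - z) ** 2 - float(penalty_value(abs(beta), spec, j))


def coordinate_update(z: float, d: float, spec: PenaltySpec,
                      j: int | None = None) -> float:
    """Maximize the quadratic surrogate -(d/2)(beta - z)^2 - P(|beta|).

    ``z`` is the unpenalized univariate optimum (current coefficient plus
    gradient over curvature) and ``d`` the MM curvature bound for the
    coordinate.  Returns exactly 0 whenever the surrogate at 0 is
    maximal, which makes every family a thresholding rule.
    """
    if d <= 0:
        raise ValueError("curvature bound d must be > 0")
    lam = spec.rate * spec.weight(j)
    a, s = abs(z), np.sign(z)
    if spec.family in ("lasso", "adaptive_lasso"):
        return s * max(a - lam / d, 0.0)
    if spec.family == "mcp":
        g = spec.shape
        if g * d > 1.0:  # firm threshold, closed form
            if a <= lam / d:
                return 0.0
            if a <= g * lam:
                return s * (a - lam / d) / (1.0 - 1.0 / (g * d))
            return z
        # surrogate convex on the MCP arc: compare the corner candidates
        cands = [0.0, g * lam] + ([a] if a > g * lam else [])
        best = max(cands, key=lambda b: _surrogate(b, a, d, spec, j))
        return s * best
    if spec.family == "log":
        # stationary roots of d(a - b) = c/(eta + b): a quadratic in b
        eta = spec.shape
        c = lam / np.log1p(1.0 / eta)
        disc = (a + eta) ** 2 - 4.0 * c / d
        cands = [0.0]
        if disc >= 0.0:
            root = ((a - eta) + np.sqrt(disc)) / 2.0
            if root > 0.0:
                cands.append(root)
        best = max(cands, key=lambda b: _surrogate(b, a, d, spec, j))
        return s * best
    # neg: safeguarded search over sign changes of the surrogate gradient
    return s * _neg_update_mag(a, d, spec, j)


def _neg_update_mag(a: float, d: float, spec: PenaltySpec, j) -> float:
    """Maximize the surrogate over b in [0, a] for the NEG penalty."""
    if a == 0.0:
        return 0.0

    def h_grad(b):
        return d * (a - b) - float(penalty_deriv(b, spec, j))

    # bracket sign changes (+ -> -) of the surrogate gradient on (0, a]
    grid = np.linspace(0.0, a, 65)
    gv = np.array([h_grad(b) for b in grid])
    cands = [0.0]
    for i in range(len(grid) - 1):
        if gv[i] > 0.0 >= gv[i + 1]:
            cands.append(float(optimize.brentq(h_grad, grid[i], grid[i + 1],
                                               xtol=1e-12)))
    if gv[-1] > 0.0:  # gradient still positive at b = a (cannot happen: = -P'(a) < 0
        cands.append(a)  # unless P'(a) underflows to 0); keep the endpoint
    best = max(cands, key=lambda b: _surrogate(b, a, d, spec, j))
    return best


def threshold_level(d: float, spec: PenaltySpec, j: int | None = None) -> float:
    """|z| below which coordinate_update returns exactly 0.

    Returns P'(0)/d = rate*w/d, the lasso-like entry condition
    |gradient| > P'(0).  This is the exact global threshold for the
    convex families and for MCP with gamma*d > 1; for strongly
    non-convex settings it is the level below which 0 is a *local*
    maximum (a distant mode may still win).  Rate paths are anchored at
    the lasso limit, where the value is exact.
    """
    return spec.rate * spec.weight(j) / d


def adaptive_weights(beta_init: np.ndarray) -> np.ndarray:
    """Adaptive-lasso weights w_j = 1/sqrt(|beta_j_init|).

    Markers with a zero first-stage estimate stay penalizable: they get
    the weight of the smallest non-zero initial estimate (the strongest
    weight assigned to any estimated marker).
    """
    beta_init = np.asarray(beta_init, dtype=float)
    mag = np.abs(beta_init)
    nz = mag[mag > 0]
    if nz.size == 0:
        raise ValueError(
            "all initial estimates are zero; relax the first-stage penalty")
    w = np.empty_like(mag)
    w[mag > 0] = 1.0 / np.sqrt(mag[mag > 0])
    w[mag == 0] = 1.0 / np.sqrt(nz.min())
    return w
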