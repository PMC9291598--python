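"""Monotone B-spline sieve for the baseline transforms phi_j.

The sieve space is the set of order-``m`` B-spline functions
``phi(t; gamma) = sum_s gamma_s B_{s,m}(t)`` with strictly increasing
coefficients ``gamma_1 < ... < gamma_{N_n + m}``; increasing coefficients
make the spline nondecreasing.  The number of interior knots grows like
``N_n ~ n^nu`` and knots sit at empirical percentiles of the pooled
observation times.  Boundary knots at ``a = 0`` and ``b`` (the largest
finite observation time) carry multiplicity ``m`` (clamped spline), so
``phi(a) = gamma_1`` and ``phi(b) = gamma_{N_n+m}``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SieveSpec",
    "SplineCoefficients",
    "select_knots",
    "basis_eval",
    "basis_matrix",
    "phi_eval",
    "monotone_reparam",
    "monotone_reparam_inverse",
    "monotone_reparam_jacobian",
    "DEFAULT_MIN_GAP",
]

#: minimum gap between consecutive gamma, making "strictly increasing"
#: numerically meaningful
DEFAULT_MIN_GAP = 1e-6


@dataclass(frozen=True)
class SieveSpec:
    """B-spline sieve specification: order, knot count and knot vector."""

    order_m: int
    n_interior: int
    knots: np.ndarray
    nu: float = 0.2
    smoothness_p: int = 2

    def __post_init__(self) -> None:
        if self.order_m < 2:
            raise ValueError("B-spline order m must be >= 2")
        if self.n_interior < 0:
            raise ValueError("number of interior knots must be >= 0")
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if len(knots) != self.n_interior + 2 * self.order_m:
            raise ValueError(
                f"knot vector length {len(knots)} != N_n + 2m = "
                f"{self.n_interior + 2 * self.order_m}"
            )
        if np.any(np.diff(knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if not knots[0] < knots[-1]:
            raise ValueError("degenerate time window: a must be < b")
        interior = knots[self.order_m : self.order_m + self.n_interior]
        if interior.size and (interior.min() <= knots[0] or interior.max() >= knots[-1]):
            raise ValueError("interior knots must lie strictly inside (a, b)")

    @property
    def a(self) -> float:
        return float(self.knots[0])

    @property
    def b(self) -> float:
        return float(self.knots[-1])

    @property
    def dim(self) -> int:
        """Dimension of the spline basis, ``N_n + m``."""
        return self.n_interior + self.order_m


@dataclass(frozen=True)
class SplineCoefficients:
    """Strictly increasing spline coefficient vector gamma."""

    gamma: np.ndarray
    min_gap: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        if np.any(np.diff(gamma) <= 0):
            raise ValueError("gamma must be strictly increasing")


def select_knots(
    observation_times: np.ndarray,
    n: int,
    order_m: int = 4,
    nu: float = 0.2,
    n_interior: int | None = None,
    smoothness_p: int = 2,
) -> SieveSpec:
    """Place sieve knots from the pooled observation times {V_i, U_i}.

    Interior knots go at the ``j/(N_n+1)`` empirical percentiles of the
    finite, positive observation times with ``N_n = ceil(n^nu)`` unless
    overridden; boundary knots are ``a = 0`` and ``b = max`` finite time,
    each with multiplicity ``m``.  If there are too few distinct times,
    ``N_n`` is reduced with a logged warning.
    """
    times = np.asarray(observation_times, dtype=float)
    times = times[np.isfinite(times) & (times > 0)]
    if times.size == 0:
        raise ValueError("no finite positive observation times to place knots")
    if n_interior is None:
        n_interior = math.ceil(n**nu)
    b = float(times.max())
    n_distinct = len(np.unique(times))
    if n_distinct < n_interior:
        logger.warning(
            "reducing interior knots from %d to %d (only %d distinct times)",
            n_interior, n_distinct, n_distinct,
        )
        n_interior = n_distinct
    while True:
        if n_interior == 0:
            interior = np.empty(0)
            break
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(times, probs)
        interior = np.unique(interior[(interior > 0.0) & (interior < b)])
        if len(interior) == n_interior:
            break
        logger.warning(
            "tied/boundary percentiles: reducing interior knots %d -> %d",
            n_interior, len(interior),
        )
        n_interior = len(interior)
    knots = np.concatenate([np.zeros(order_m), interior, np.full(order_m, b)])
    return SieveSpec(
        order_m=order_m, n_interior=n_interior, knots=knots,
        nu=nu, smoothness_p=smoothness_p,
    )


def basis_matrix(t: np.ndarray, spec: SieveSpec) -> np.ndarray:
    """Dense B-spline design matrix, rows = times, columns = N_n + m basis
    functions.  Rows are nonnegative and sum to one (partition of unity)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < spec.a) or np.any(t > spec.b):
        raise ValueError(f"evaluation times must lie in [{spec.a}, {spec.b}]")
    return BSpline.design_matrix(t, spec.knots, spec.order_m - 1).toarray()


def basis_eval(t: float, spec: SieveSpec) -> np.ndarray:
    """All basis functions B_{s,m}(t) at one time point."""
    return basis_matrix(np.atleast_1d(t), spec)[0]


def phi_eval(t, gamma: SplineCoefficients | np.ndarray, spec: SieveSpec):
    """Evaluate ``phi(t; gamma) = sum_s gamma_s B_{s,m}(t)``."""
    g = gamma.gamma if isinstance(gamma, SplineCoefficients) else np.asarray(gamma, float)
    if len(g) != spec.dim:
        raise ValueError(f"gamma has length {len(g)}, expected {spec.dim}")
    out = basis_matrix(t, spec) @ g
    return out if np.ndim(t) else float(out[0])


def monotone_reparam(raw: np.ndarray, min_gap: float = DEFAULT_MIN_GAP) -> SplineCoefficients:
    """Map an unconstrained vector to strictly increasing coefficients.

    ``gamma_1 = raw_1`` and ``gamma_{s+1} = gamma_s + exp(raw_{s+1}) + delta``
    with minimum gap ``delta``; any raw vector yields an admissible gamma,
    so the optimizer can run unconstrained in ``raw``.
    """
    raw = np.asarray(raw, dtype=float)
    gamma = np.empty_like(raw)
    gamma[0] = raw[0]
    gamma[1:] = raw[0] + np.cumsum(np.exp(raw[1:]) + min_gap)
    return SplineCoefficients(gamma=gamma, min_gap=min_gap)


def monotone_reparam_inverse(
    gamma: SplineCoefficients | np.ndarray, min_gap: float = DEFAULT_MIN_GAP
) -> np.ndarray:
    """Inverse of :func:`monotone_reparam` for gaps exceeding ``min_gap``."""
    g = gamma.gamma if isinstance(gamma, SplineCoefficients) else np.asarray(gamma, float)
    gaps = np.diff(g) - min_gap
    if np.any(gaps <= 0):
        raise ValueError("gamma gaps must exceed the minimum gap delta")
    return np.concatenate([[g[0]], np.log(gaps)])


def monotone_reparam_jacobian(raw: np.ndarray) -> np.ndarray:
    """Jacobian d gamma_s / d raw_t of :func:`monotone_reparam`.

    Lower-triangular: column 1 is all ones; column ``t >= 2`` equals
    ``exp(raw_t)`` for rows ``s >= t``.
    """
    raw = np.asarray(raw, dtype=float)
    q = len(raw)
    J = np.zeros((q, q))
    J[:, 0] = 1.0
    e = np.exp(raw[1:])
    for t in range(1, q):
        J[t:, t] = e[t - 1]
    return J
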