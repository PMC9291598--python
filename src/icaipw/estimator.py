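"""AIPW sieve maximum likelihood for CIF regression with missing event
types.

The observed-data log-likelihood for interval-censored competing risks
(all event types observed) is, per subject,

    sum_j D1_j log{F_j(U) - F_j(V)} + sum_j D2_j log F_j(U)
        + (1 - D) log{1 - sum_j F_j(V)},

with D1_j / D2_j the cause-specific interval/left-censoring indicators.
With missing event types the indicators are replaced by augmented
inverse-probability weights

    D~_j^(l) = D^(l) [ (R/rho) I(eps = j) - ((R - rho)/rho) pi_j(O) ],

built from the stage-1 response model ``rho`` and event-type model
``pi``.  The weighted objective is maximized over the monotone B-spline
sieve for the baseline transforms phi_j and the regression coefficients
beta_j, subject to the constraint that the CIFs sum to below one at the
end of the observation window for every observed covariate pattern.
The estimator is doubly robust: consistent when either ``rho`` or
``pi`` is correctly specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import ICDataset, ICRecord, validate
from .links import CauseLinkSpec, g_inverse, g_inverse_deriv, g_link
from .nuisance import (
    NuisanceDesign,
    NuisanceFit,
    fit_nuisance,
)
from .sieve import (
    DEFAULT_MIN_GAP,
    SieveSpec,
    SplineCoefficients,
    basis_matrix,
    monotone_reparam,
    monotone_reparam_inverse,
    select_knots,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "ThetaParams",
    "FitResult",
    "NonconvergenceError",
    "complete_loglik",
    "tilde_weights",
    "aipw_objective",
    "feasibility_constraint",
    "fit_aipw",
    "fit_complete",
    "bootstrap_variance",
    "predict_cif",
]


class NonconvergenceError(Exception):
    """Optimization failed after all restarts; carries the best iterate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for the two-stage sieve fit.

    ``alpha`` holds the per-cause odds-rate exponents (1 = proportional
    odds, the default; 0 = Fine--Gray).  The sieve defaults are cubic
    splines (m = 4) with ``N_n = ceil(n^nu)`` interior knots and
    ``nu = 1/(1 + 2p)`` for smoothness ``p = 2``.
    """

    alpha: tuple = None                 # per cause; None -> all 1.0
    order_m: int = 4
    nu: float = 0.2
    n_interior: int | None = None
    smoothness_p: int = 2
    rho_design: NuisanceDesign | None = None
    pi_design: NuisanceDesign | None = None
    min_gap: float = DEFAULT_MIN_GAP
    ftol: float = 1e-8
    maxiter: int = 300
    n_restarts: int = 3
    seed: int | None = None
    analytic_gradients: bool = True
    feas_margin: float = 1e-6           # enforced slack in sum_j F_j(b;z) < 1
    log_eps: float = 1e-10              # linearized-log threshold

    def alphas(self, k: int) -> tuple:
        if self.alpha is None:
            return tuple(1.0 for _ in range(k))
        if len(self.alpha) != k:
            raise ValueError(f"alpha must have one entry per cause ({k})")
        return tuple(float(a) for a in self.alpha)


@dataclass
class ThetaParams:
    """Sieve parameters: per-cause spline coefficients, regression
    coefficients and link exponents, sharing one knot specification."""

    spec: SieveSpec
    gammas: list            # k SplineCoefficients
    betas: list             # k arrays of length d
    links: list             # k CauseLinkSpec

    @property
    def k(self) -> int:
        return len(self.gammas)

    def cif(self, t, z, cause: int):
        """F_j(t; z) for cause ``j = cause`` (1-based)."""
        j = cause - 1
        eta = basis_matrix(np.atleast_1d(t), self.spec) @ self.gammas[j].gamma
        eta = eta + float(np.dot(self.betas[j], np.atleast_1d(z)))
        out = g_inverse(eta, self.links[j].alpha)
        return out if np.ndim(t) else float(out[0])

    def beta_flat(self) -> np.ndarray:
        return np.concatenate(self.betas)


@dataclass
class FitResult:
    """Outcome of a sieve fit, with optional bootstrap uncertainty."""

    theta_hat: ThetaParams
    nuisance: NuisanceFit | None
    objective_value: float
    converged: bool
    message: str = ""
    n_iter: int = 0
    se_beta: np.ndarray | None = None
    ci_beta: np.ndarray | None = None   # (k*d, 2)
    n_bootstrap_used: int = 0

    @property
    def beta_hat(self) -> np.ndarray:
        return self.theta_hat.beta_flat()


# --------------------------------------------------------------------------
# linearized logarithm: keeps the objective finite and C^1 when a line
# search momentarily drives a probability difference to ~0
def _slog(x: np.ndarray, eps: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= eps, np.log(np.maximum(x, eps)), np.log(eps) + (x - eps) / eps)


def _dslog(x: np.ndarray, eps: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= eps, 1.0 / np.maximum(x, eps), 1.0 / eps)


class _Workspace:
    """Precomputed design pieces for one dataset: basis matrices per
    censoring class, covariate blocks, and the (possibly augmented)
    cause-by-class weight matrices."""

    def __init__(self, ds: ICDataset, spec: SieveSpec, alphas: Sequence[float],
                 W1: np.ndarray, W2: np.ndarray, log_eps: float = 1e-10):
        self.spec = spec
        self.alphas = tuple(alphas)
        self.k = len(self.alphas)
        self.d = ds.d
        self.n = ds.n
        self.log_eps = log_eps
        d1 = ds.delta1 == 1
        d2 = ds.delta2 == 1
        d0 = ds.delta == 0
        b = spec.b
        clip = lambda t: np.clip(t, spec.a, b)
        self.B_int_U = basis_matrix(clip(ds.u[d1]), spec) if d1.any() else np.zeros((0, spec.dim))
        self.B_int_V = basis_matrix(clip(ds.v[d1]), spec) if d1.any() else np.zeros((0, spec.dim))
        self.Z_int = ds.z[d1]
        self.B_left_U = basis_matrix(clip(ds.u[d2]), spec) if d2.any() else np.zeros((0, spec.dim))
        self.Z_left = ds.z[d2]
        self.B_right_V = basis_matrix(clip(ds.v[d0]), spec) if d0.any() else np.zeros((0, spec.dim))
        self.Z_right = ds.z[d0]
        self.W1 = W1
        self.W2 = W2
        self.Zcon = np.unique(ds.z, axis=0)   # constraint rows: observed patterns
        self.q = spec.dim

    # ---- parameter packing: per cause [raw_gamma (q), beta (d)] ----------
    def unpack(self, x: np.ndarray, min_gap: float):
        q, d, k = self.q, self.d, self.k
        gammas = np.empty((k, q))
        betas = np.empty((k, d))
        raws = np.empty((k, q))
        for j in range(k):
            off = j * (q + d)
            raws[j] = x[off : off + q]
            gammas[j] = monotone_reparam(raws[j], min_gap).gamma
            betas[j] = x[off + q : off + q + d]
        return raws, gammas, betas

    def eval_objective(self, gammas: np.ndarray, betas: np.ndarray,
                       want_grad: bool = False, raws: np.ndarray | None = None):
        """Mean weighted log-likelihood (and gradient in packed raw/beta
        coordinates when requested)."""
        k, q, d, n, eps = self.k, self.q, self.d, self.n, self.log_eps
        total = 0.0
        grad = np.zeros(k * (q + d)) if want_grad else None

        # per-cause linear predictors for each class/time
        for j in range(k):
            a = self.alphas[j]
            g, bta = gammas[j], betas[j]
            gg = np.zeros(q)
            gb = np.zeros(d)

            if self.B_int_U.shape[0]:
                eta_u = self.B_int_U @ g + self.Z_int @ bta
                eta_v = self.B_int_V @ g + self.Z_int @ bta
                Fu, Fv = g_inverse(eta_u, a), g_inverse(eta_v, a)
                diff = Fu - Fv
                w = self.W1[:, j]
                total += float(w @ _slog(diff, eps))
                if want_grad:
                    s = w * _dslog(diff, eps)
                    cu = s * g_inverse_deriv(eta_u, a)
                    cv = -s * g_inverse_deriv(eta_v, a)
                    gg += self.B_int_U.T @ cu + self.B_int_V.T @ cv
                    gb += self.Z_int.T @ (cu + cv)

            if self.B_left_U.shape[0]:
                eta_u = self.B_left_U @ g + self.Z_left @ bta
                Fu = g_inverse(eta_u, a)
                w = self.W2[:, j]
                total += float(w @ _slog(Fu, eps))
                if want_grad:
                    c = w * _dslog(Fu, eps) * g_inverse_deriv(eta_u, a)
                    gg += self.B_left_U.T @ c
                    gb += self.Z_left.T @ c

            if want_grad:
                off = j * (q + d)
                grad[off : off + q] = gg       # temporary: d/d gamma
                grad[off + q : off + q + d] = gb

        # right-censored survival term couples the causes
        if self.B_right_V.shape[0]:
            Fsum = np.zeros(self.B_right_V.shape[0])
            etas = []
            for j in range(k):
                eta_v = self.B_right_V @ gammas[j] + self.Z_right @ betas[j]
                etas.append(eta_v)
                Fsum += g_inverse(eta_v, self.alphas[j])
            surv = 1.0 - Fsum
            total += float(np.sum(_slog(surv, eps)))
            if want_grad:
                s = _dslog(surv, eps)
                for j in range(k):
                    c = -s * g_inverse_deriv(etas[j], self.alphas[j])
                    off = j * (q + d)
                    grad[off : off + self.q] += self.B_right_V.T @ c
                    grad[off + self.q : off + self.q + d] += self.Z_right.T @ c

        total /= n
        if not want_grad:
            return total, None
        grad /= n
        # chain rule through the monotone reparameterization
        if raws is not None:
            for j in range(k):
                off = j * (q + d)
                gg = grad[off : off + q]
                e = np.exp(raws[j][1:])
                out = np.empty(q)
                out[0] = gg.sum()
                # d gamma_s / d raw_t = exp(raw_t) for s >= t >= 2
                out[1:] = e * np.cumsum(gg[::-1])[::-1][1:]
                grad[off : off + q] = out
        return total, grad

    # ---- feasibility: 1 - sum_j F_j(b; z) over observed patterns ---------
    def constraint_values(self, gammas: np.ndarray, betas: np.ndarray) -> np.ndarray:
        Fsum = np.zeros(self.Zcon.shape[0])
        for j in range(self.k):
            eta = gammas[j][-1] + self.Zcon @ betas[j]   # phi_j(b) = gamma_last
            Fsum += g_inverse(eta, self.alphas[j])
        return 1.0 - Fsum

    def constraint_jac(self, raws: np.ndarray, gammas: np.ndarray,
                       betas: np.ndarray) -> np.ndarray:
        ncon = self.Zcon.shape[0]
        q, d = self.q, self.d
        J = np.zeros((ncon, self.k * (q + d)))
        for j in range(self.k):
            eta = gammas[j][-1] + self.Zcon @ betas[j]
            dF = g_inverse_deriv(eta, self.alphas[j])
            off = j * (q + d)
            # d gamma_last / d raw = [1, exp(raw_2), ..., exp(raw_q)]
            dlast = np.concatenate([[1.0], np.exp(raws[j][1:])])
            J[:, off : off + q] = -np.outer(dF, dlast)
            J[:, off + q : off + q + d] = -dF[:, None] * self.Zcon
        return J


# --------------------------------------------------------------------------
# weight construction


def _complete_weights(ds: ICDataset) -> tuple[np.ndarray, np.ndarray]:
    """Cause-indicator weights; requires every event type observed."""
    if np.any((ds.delta == 1) & (ds.r == 0)):
        raise ValueError("complete-data likelihood requires all event types observed")
    d1, d2 = ds.delta1 == 1, ds.delta2 == 1
    W1 = np.zeros((int(d1.sum()), ds.k))
    W2 = np.zeros((int(d2.sum()), ds.k))
    for j in range(ds.k):
        W1[:, j] = (ds.cause[d1] == j + 1).astype(float)
        W2[:, j] = (ds.cause[d2] == j + 1).astype(float)
    return W1, W2


def tilde_weights(record: ICRecord, rho_hat: float, pi_hat: np.ndarray) -> np.ndarray:
    """AIPW weight matrix (k rows, columns l = 1: interval, l = 2: left).

    The augmentation applies to the record's observed censoring class
    only; summed over causes and classes the weights equal one, like the
    indicators they replace.
    """
    if record.delta != 1:
        raise ValueError("tilde weights are defined for event records (Delta = 1) only")
    pi_hat = np.asarray(pi_hat, dtype=float)
    k = len(pi_hat)
    if not 0.0 < rho_hat < 1.0:
        raise ValueError("rho_hat must lie in (0, 1)")
    out = np.zeros((k, 2))
    l = 0 if record.delta1 == 1 else 1
    aug = -((record.r - rho_hat) / rho_hat) * pi_hat
    out[:, l] = aug
    if record.r == 1:
        out[record.cause - 1, l] += record.r / rho_hat
    return out


def _aipw_weights(ds: ICDataset, nuisance: NuisanceFit) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tilde weights split into the interval/left matrices."""
    ev = ds.delta == 1
    if nuisance.no_missingness or nuisance.rho is None:
        return _complete_weights(ds)
    rho = nuisance.rho.predict(ds, ev)
    pi = nuisance.pi.predict(ds, ev)
    r = ds.r[ev].astype(float)
    cause = ds.cause[ev]
    k = ds.k
    W = -((r - rho) / rho)[:, None] * pi
    rows = np.arange(len(r))
    obs = r == 1
    W[rows[obs], cause[obs] - 1] += (r / rho)[obs]
    d1_ev = (ds.delta1[ev] == 1)
    return W[d1_ev], W[~d1_ev]


# --------------------------------------------------------------------------
# spec-level operations


def _theta_workspace(theta: ThetaParams, ds: ICDataset, W1, W2,
                     log_eps: float = 1e-10) -> tuple[_Workspace, np.ndarray, np.ndarray]:
    alphas = [lnk.alpha for lnk in theta.links]
    ws = _Workspace(ds, theta.spec, alphas, W1, W2, log_eps)
    gammas = np.vstack([g.gamma for g in theta.gammas])
    betas = np.vstack(theta.betas)
    return ws, gammas, betas


def complete_loglik(theta: ThetaParams, ds: ICDataset) -> float:
    """Mean observed-cause log-likelihood; -inf when a log argument is
    nonpositive (the objective rejects the point)."""
    W1, W2 = _complete_weights(ds)
    ws, gammas, betas = _theta_workspace(theta, ds, W1, W2, log_eps=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val, _ = ws.eval_objective(gammas, betas)
    return val if np.isfinite(val) else -np.inf


def aipw_objective(theta: ThetaParams, ds: ICDataset, nuisance: NuisanceFit) -> float:
    """Mean AIPW-weighted log-likelihood at ``theta``."""
    W1, W2 = _aipw_weights(ds, nuisance)
    ws, gammas, betas = _theta_workspace(theta, ds, W1, W2, log_eps=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val, _ = ws.eval_objective(gammas, betas)
    return val if np.isfinite(val) else -np.inf


def feasibility_constraint(theta: ThetaParams, ds: ICDataset) -> float:
    """``1 - max_z sum_j F_j(b; z)`` over the observed covariate rows;
    positive iff the fitted CIFs are jointly feasible."""
    W1, W2 = _complete_weights_shape(ds)
    ws, gammas, betas = _theta_workspace(theta, ds, W1, W2)
    return float(ws.constraint_values(gammas, betas).min())


def _complete_weights_shape(ds: ICDataset) -> tuple[np.ndarray, np.ndarray]:
    """Zero weight matrices with the right shapes (constraint evaluation
    does not need weights)."""
    return (np.zeros((int((ds.delta1 == 1).sum()), ds.k)),
            np.zeros((int((ds.delta2 == 1).sum()), ds.k)))


# --------------------------------------------------------------------------
# maximization


def _initial_point(ws: _Workspace, config: FitConfig) -> np.ndarray:
    """Feasible start: beta = 0 and baseline CIFs rising from ~0.01 at a
    to 0.3/k at b."""
    q, d, k = ws.q, ws.d, ws.k
    x0 = np.empty(k * (q + d))
    for j in range(k):
        a = ws.alphas[j]
        lo = g_link(0.01, a)
        hi = g_link(0.3 / k, a)
        gamma = np.linspace(lo, hi, q)
        off = j * (q + d)
        x0[off : off + q] = monotone_reparam_inverse(gamma, config.min_gap)
        x0[off + q : off + q + d] = 0.0
    return x0


#: loose parameter box; never active at a reasonable optimum, it only
#: stops runaway line searches from overflowing exp() in the
#: reparameterization
_RAW0_BOUNDS = (-25.0, 10.0)
_RAWINC_BOUNDS = (-25.0, 6.0)
_BETA_BOUNDS = (-15.0, 15.0)


def _maximize(ws: _Workspace, config: FitConfig,
              x0: np.ndarray | None = None) -> tuple[np.ndarray, float, bool, str, int]:
    rng = np.random.default_rng(config.seed)
    start = _initial_point(ws, config) if x0 is None else np.asarray(x0, float)
    q, d, k = ws.q, ws.d, ws.k
    bounds = ([_RAW0_BOUNDS] + [_RAWINC_BOUNDS] * (q - 1) + [_BETA_BOUNDS] * d) * k
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    start = np.clip(start, lo, hi)

    cache = {}

    def _eval(x, want_grad):
        key = x.tobytes()
        if cache.get("key") != key or (want_grad and cache.get("grad") is None):
            raws, gammas, betas = ws.unpack(x, config.min_gap)
            val, grad = ws.eval_objective(gammas, betas, want_grad=want_grad, raws=raws)
            if not np.isfinite(val):
                val = -1e10
                grad = np.zeros_like(x) if want_grad else None
            cache.update(key=key, val=val, grad=grad,
                         raws=raws, gammas=gammas, betas=betas)
        return cache

    def fun(x):
        return -_eval(x, config.analytic_gradients)["val"]

    def jac(x):
        return -_eval(x, True)["grad"]

    def con_fun(x):
        c = _eval(x, False)
        return ws.constraint_values(c["gammas"], c["betas"]) - config.feas_margin

    def con_jac(x):
        c = _eval(x, True)
        return ws.constraint_jac(c["raws"], c["gammas"], c["betas"])

    constraints = [{"type": "ineq", "fun": con_fun, "jac": con_jac}]
    best = None
    message = ""
    for attempt in range(1 + config.n_restarts):
        xa = start if attempt == 0 else np.clip(
            start + rng.normal(0.0, 0.2, size=len(start)), lo, hi
        )
        res = minimize(
            fun, xa,
            jac=jac if config.analytic_gradients else None,
            method="SLSQP", bounds=bounds, constraints=constraints,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        feasible = bool(np.all(con_fun(res.x) >= -0.9 * config.feas_margin))
        cand = (res.x, -res.fun, res.nit)
        if feasible and np.isfinite(cand[1]) and (best is None or cand[1] > best[1]):
            best = cand
        message = res.message
        if res.success and feasible and np.isfinite(res.fun):
            return res.x, -res.fun, True, res.message, res.nit
    # salvage: a failed exit at a feasible near-stationary point
    if best is not None:
        x, val, nit = best
        g = jac(x)
        interior = (x > lo + 1e-8) & (x < hi - 1e-8)
        if np.linalg.norm(g[interior], ord=np.inf) < 1e-3:
            return x, val, True, f"accepted near-stationary point ({message})", nit
    raise NonconvergenceError(
        f"sieve optimization failed after {config.n_restarts} restarts: {message}",
        best=best,
    )


def _build_theta(ws: _Workspace, x: np.ndarray, config: FitConfig) -> ThetaParams:
    raws, gammas, betas = ws.unpack(x, config.min_gap)
    return ThetaParams(
        spec=ws.spec,
        gammas=[SplineCoefficients(gamma=g, min_gap=config.min_gap) for g in gammas],
        betas=[b.copy() for b in betas],
        links=[CauseLinkSpec(alpha=a) for a in ws.alphas],
    )


def _prepare(ds: ICDataset, config: FitConfig) -> SieveSpec:
    report = validate(ds)
    if report["total"]:
        bad = {k: v for k, v in report.items() if v and k != "total"}
        raise ValueError(f"dataset fails validation: {bad}")
    return select_knots(
        ds.observation_times(), n=ds.n, order_m=config.order_m,
        nu=config.nu, n_interior=config.n_interior,
        smoothness_p=config.smoothness_p,
    )


def fit_complete(ds: ICDataset, config: FitConfig | None = None,
                 x0: np.ndarray | None = None) -> FitResult:
    """Complete-data sieve MLE (every event type observed)."""
    config = config or FitConfig()
    spec = _prepare(ds, config)
    W1, W2 = _complete_weights(ds)
    ws = _Workspace(ds, spec, config.alphas(ds.k), W1, W2, config.log_eps)
    x, val, ok, msg, nit = _maximize(ws, config, x0=x0)
    return FitResult(
        theta_hat=_build_theta(ws, x, config), nuisance=None,
        objective_value=val, converged=ok, message=msg, n_iter=nit,
    )


def fit_aipw(ds: ICDataset, config: FitConfig | None = None,
             x0: np.ndarray | None = None,
             nuisance: NuisanceFit | None = None) -> FitResult:
    """Two-stage doubly robust fit.

    Stage 1 estimates the response and event-type models by parametric
    maximum likelihood; stage 2 maximizes the AIPW-weighted sieve
    objective under the joint-CIF feasibility constraint.  With no
    missing event types the fit short-circuits to the complete-data
    sieve MLE.
    """
    config = config or FitConfig()
    spec = _prepare(ds, config)
    if nuisance is None:
        nuisance = fit_nuisance(ds, config.rho_design, config.pi_design)
    W1, W2 = _aipw_weights(ds, nuisance)
    ws = _Workspace(ds, spec, config.alphas(ds.k), W1, W2, config.log_eps)
    x, val, ok, msg, nit = _maximize(ws, config, x0=x0)
    return FitResult(
        theta_hat=_build_theta(ws, x, config), nuisance=nuisance,
        objective_value=val, converged=ok, message=msg, n_iter=nit,
    )


def _warm_start(fit: FitResult, config: FitConfig) -> np.ndarray:
    parts = []
    for g, b in zip(fit.theta_hat.gammas, fit.theta_hat.betas):
        parts.append(monotone_reparam_inverse(g, config.min_gap))
        parts.append(np.asarray(b, float))
    return np.concatenate(parts)


def bootstrap_variance(
    ds: ICDataset,
    config: FitConfig | None = None,
    B: int = 100,
    stratified: bool = False,
    fit: FitResult | None = None,
    seed: int | None = None,
    fitter: Callable[[ICDataset, FitConfig, np.ndarray], FitResult] | None = None,
) -> FitResult:
    """Nonparametric bootstrap standard errors and Wald 95% intervals.

    ``stratified=True`` resamples separately within the observed-type
    (R = 1) and missing-type (R = 0) events and the right-censored pool,
    preserving the stratum sizes fixed by a double-sampling design.
    Each replicate reruns the full two-stage fit (warm-started at the
    original estimate); nonconvergent replicates are dropped and counted
    in ``n_bootstrap_used``.
    """
    config = config or FitConfig()
    if fitter is None:
        fitter = fit_aipw
    if fit is None:
        fit = fitter(ds, config)
    if B <= 0:
        return fit
    x0 = _warm_start(fit, config)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    if stratified:
        strata = [
            np.flatnonzero((ds.delta == 1) & (ds.r == 1)),
            np.flatnonzero((ds.delta == 1) & (ds.r == 0)),
            np.flatnonzero(ds.delta == 0),
        ]
        strata = [s for s in strata if len(s)]
    betas = []
    failures = 0
    for _ in range(B):
        if stratified:
            idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        else:
            idx = rng.integers(0, ds.n, size=ds.n)
        try:
            bfit = fitter(ds.subset(idx), config, x0=x0)
            betas.append(bfit.beta_hat)
        except Exception:
            failures += 1
    if failures > 0.5 * B:
        raise NonconvergenceError(
            f"bootstrap: {failures}/{B} replicates failed to converge"
        )
    if failures > 0.2 * B:
        logger.warning("bootstrap: %d/%d replicates failed to converge", failures, B)
    betas = np.asarray(betas)
    se = betas.std(axis=0, ddof=1)
    bh = fit.beta_hat
    ci = np.column_stack([bh - 1.96 * se, bh + 1.96 * se])
    return replace(fit, se_beta=se, ci_beta=ci, n_bootstrap_used=B - failures)


def predict_cif(fit: FitResult, z, times) -> np.ndarray:
    """Fitted CIF curves: (k, len(times)) array, each nondecreasing.
    Baseline curves are obtained with ``z = 0``."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    theta = fit.theta_hat
    if np.any(times < theta.spec.a) or np.any(times > theta.spec.b):
        raise ValueError(
            f"prediction times must lie in [{theta.spec.a}, {theta.spec.b}]"
        )
    return np.vstack([theta.cif(times, z, j + 1) for j in range(theta.k)])
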