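"""Stage-1 parametric nuisance models for the AIPW estimator.

Two models are fitted by ordinary maximum likelihood before the sieve
stage:

* the *response* (nonmissingness) model
  ``rho(O; xi) = Pr(R = 1 | Delta = 1, O)`` -- a binary logistic model
  fitted on the subjects with an observed event (``Delta = 1``);
* the *event-type* model
  ``pi_j(O; psi) = Pr(eps = j | Delta = 1, O)`` -- binary logistic for
  two causes, multinomial for more -- fitted on the complete events
  (``R = 1`` and ``Delta = 1``).

Here ``O = (U, Z, A)``: the event-detection time, the covariates of
interest, and any auxiliary covariates.  Either model may be deliberately
misspecified; the AIPW estimator stays consistent as long as one of the
two is correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data import ICDataset, ICRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NoMissingnessError",
    "NuisanceConvergenceError",
    "NuisanceDesign",
    "RhoFit",
    "PiFit",
    "NuisanceFit",
    "fit_rho",
    "fit_pi",
    "fit_nuisance",
    "predict_rho",
    "predict_pi",
    "EPS_CLIP",
]

#: clip for predicted probabilities used as inverse weights; unclipped
#: near-zero response probabilities explode the AIPW objective
EPS_CLIP = 1e-3


class NoMissingnessError(Exception):
    """All event types are observed; the caller should fall back to the
    complete-data sieve maximum likelihood estimator."""


class NuisanceConvergenceError(Exception):
    """Logistic maximum likelihood failed (separation, rank deficiency)."""


@dataclass(frozen=True)
class NuisanceDesign:
    """Covariate specification over O = (U, Z, A).

    ``terms`` name columns of the per-subject feature set: ``"1"``
    (intercept), ``"u"``, ``"v"``, covariate names (``z1``, ...) and
    auxiliary names (``a1``, ...).  ``None`` means the default linear
    design: intercept + U + all Z + all A.  ``saturated=True`` instead
    fits one free probability per observed combination of ``terms``
    (which must then be discrete), the nonparametric/saturated logistic
    model.
    """

    terms: tuple | None = None
    saturated: bool = False

    def resolved_terms(self, ds: ICDataset) -> tuple:
        if self.terms is not None:
            return tuple(self.terms)
        if self.saturated:
            return tuple(["u"] + list(ds.z_names))
        return tuple(["1", "u"] + list(ds.z_names) + list(ds.a_names))

    def matrix(self, ds: ICDataset, idx: np.ndarray) -> np.ndarray:
        cols = []
        for term in self.resolved_terms(ds):
            if term == "1":
                cols.append(np.ones(int(np.sum(idx)) if idx.dtype == bool else len(idx)))
            elif term == "u":
                cols.append(ds.u[idx])
            elif term == "v":
                cols.append(ds.v[idx])
            elif term in ds.z_names:
                cols.append(ds.z[idx, list(ds.z_names).index(term)])
            elif term in ds.a_names:
                cols.append(ds.a[idx, list(ds.a_names).index(term)])
            else:
                raise ValueError(f"unknown design term '{term}'")
        return np.column_stack(cols)


def _logit_mle(y: np.ndarray, X: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary-logistic MLE with score-equation and rank checks."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NuisanceConvergenceError(
            f"{what}: rank-deficient design (a column is constant or collinear "
            "on the fitting subset)"
        )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparation and friends
        raise NuisanceConvergenceError(f"{what}: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise NuisanceConvergenceError(
            f"{what}: maximum likelihood did not converge "
            "(quasi-complete separation is the usual cause)"
        )
    score = res.model.score(res.params) / len(y)  # per-observation score
    if np.linalg.norm(score, ord=np.inf) > 1e-6:
        raise NuisanceConvergenceError(
            f"{what}: score not zero at optimum (|score|={np.abs(score).max():.2e}); "
            "possible quasi-complete separation"
        )
    return np.asarray(res.params), np.asarray(res.cov_params())


@dataclass
class RhoFit:
    """Fitted response model rho(O; xi)."""

    xi: np.ndarray
    cov: np.ndarray
    design: NuisanceDesign
    converged: bool = True
    eps_clip: float = EPS_CLIP

    def predict(self, ds: ICDataset, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            idx = np.arange(ds.n)
        X = self.design.matrix(ds, idx)
        p = _expit(X @ self.xi)
        return _clip_probs(p, self.eps_clip, "rho")


@dataclass
class PiFit:
    """Fitted event-type model pi_j(O; psi), j = 1..k."""

    k: int
    design: NuisanceDesign
    psi: np.ndarray | None = None            # (p,) for k=2; (k-1, p) for k>2
    cov: np.ndarray | None = None
    cells: dict | None = None                # saturated: key -> prob vector
    cell_fallback: np.ndarray | None = None
    converged: bool = True
    eps_clip: float = EPS_CLIP

    def predict(self, ds: ICDataset, idx: np.ndarray | None = None,
                psi: np.ndarray | None = None) -> np.ndarray:
        """(n_idx, k) matrix of event-type probabilities, rows sum to 1."""
        if idx is None:
            idx = np.arange(ds.n)
        X = self.design.matrix(ds, idx)
        if self.design.saturated:
            probs = np.empty((X.shape[0], self.k))
            for i, row in enumerate(map(tuple, np.round(X, 12))):
                probs[i] = self.cells.get(row, self.cell_fallback)
        elif self.k == 2:
            p1 = _expit(X @ (self.psi if psi is None else psi))
            probs = np.column_stack([p1, 1.0 - p1])
        else:
            coef = (self.psi if psi is None else psi).reshape(self.k - 1, -1)
            eta = X @ coef.T                       # reference category = cause 1
            eta = np.column_stack([np.zeros(len(eta)), eta])
            eta -= eta.max(axis=1, keepdims=True)
            probs = np.exp(eta)
            probs /= probs.sum(axis=1, keepdims=True)
        probs = _clip_probs(probs, self.eps_clip, "pi")
        return probs / probs.sum(axis=1, keepdims=True)


@dataclass
class NuisanceFit:
    """Container for both stage-1 fits.  With no missing event types both
    models are unnecessary and are left unfitted."""

    rho: RhoFit | None
    pi: PiFit | None
    no_missingness: bool = False

    @property
    def converged(self) -> bool:
        return ((self.rho is None or self.rho.converged)
                and (self.pi is None or self.pi.converged))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def _clip_probs(p: np.ndarray, eps: float, what: str) -> np.ndarray:
    if np.any(p < eps) or np.any(p > 1 - eps):
        logger.info("clipping %s predictions to [%g, %g]", what, eps, 1 - eps)
    return np.clip(p, eps, 1 - eps)


def fit_rho(ds: ICDataset, design: NuisanceDesign | None = None) -> RhoFit:
    """Fit the response model on the Delta = 1 subset.

    Raises :class:`NoMissingnessError` when every event type is observed
    (the AIPW machinery is then unnecessary) and
    :class:`NuisanceConvergenceError` on separation.
    """
    design = design or NuisanceDesign()
    ev = ds.delta == 1
    if not np.any(ev):
        raise ValueError("no events (Delta = 1) in the dataset")
    y = ds.r[ev].astype(float)
    if np.all(y == 1):
        raise NoMissingnessError("all event types observed among events")
    if np.all(y == 0):
        raise NuisanceConvergenceError("rho: no observed event types at all")
    X = design.matrix(ds, ev)
    xi, cov = _logit_mle(y, X, "rho model")
    return RhoFit(xi=xi, cov=cov, design=design)


def fit_pi(ds: ICDataset, design: NuisanceDesign | None = None) -> PiFit:
    """Fit the event-type model on the complete events (R = 1, Delta = 1)."""
    design = design or NuisanceDesign()
    sub = (ds.delta == 1) & (ds.r == 1)
    causes = ds.cause[sub]
    observed = np.unique(causes)
    if len(observed) < 2:
        raise NuisanceConvergenceError(
            "pi: a single observed event type among complete events; "
            "the event-type model is degenerate"
        )
    X = design.matrix(ds, sub)
    if design.saturated:
        keys = list(map(tuple, np.round(X, 12)))
        cells: dict = {}
        for key in set(keys):
            rows = [i for i, kk in enumerate(keys) if kk == key]
            counts = np.array([np.sum(causes[rows] == j + 1) for j in range(ds.k)], float)
            cells[key] = _cell_probs(counts)
        fallback = _cell_probs(
            np.array([np.sum(causes == j + 1) for j in range(ds.k)], float)
        )
        return PiFit(k=ds.k, design=design, cells=cells, cell_fallback=fallback)
    if ds.k == 2:
        y = (causes == 1).astype(float)
        psi, cov = _logit_mle(y, X, "pi model")
        return PiFit(k=2, design=design, psi=psi, cov=cov)
    # multinomial logistic, reference category = cause 1
    try:
        res = sm.MNLogit(causes - 1, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise NuisanceConvergenceError(f"pi model (multinomial): {exc}") from exc
    return PiFit(k=ds.k, design=design, psi=np.asarray(res.params).T,
                 cov=np.asarray(res.cov_params()))


def _cell_probs(counts: np.ndarray) -> np.ndarray:
    """Saturated-model cell probabilities with clipping for pure cells."""
    total = counts.sum()
    p = counts / total if total > 0 else np.full(len(counts), 1.0 / len(counts))
    p = np.clip(p, EPS_CLIP, 1 - EPS_CLIP)
    return p / p.sum()


def fit_nuisance(
    ds: ICDataset,
    rho_design: NuisanceDesign | None = None,
    pi_design: NuisanceDesign | None = None,
) -> NuisanceFit:
    """Run both stage-1 fits; flags (rather than raises) no-missingness,
    in which case neither model is needed nor fitted."""
    try:
        rho = fit_rho(ds, rho_design)
    except NoMissingnessError:
        logger.info("no missing event types: AIPW reduces to complete-data MLE")
        return NuisanceFit(rho=None, pi=None, no_missingness=True)
    return NuisanceFit(rho=rho, pi=fit_pi(ds, pi_design))


def _as_singleton_ds(record: ICRecord, ds_like: ICDataset | None = None) -> ICDataset:
    return ICDataset(
        ids=np.array([record.id]), v=np.array([record.v]), u=np.array([record.u]),
        cause=np.array([record.cause]), r=np.array([record.r]),
        z=record.z.reshape(1, -1), a=record.a.reshape(1, -1),
        k=ds_like.k if ds_like is not None else 2,
        z_names=ds_like.z_names if ds_like is not None else None,
        a_names=ds_like.a_names if ds_like is not None else None,
    )


def predict_rho(fit: RhoFit, record_or_ds, idx=None):
    """Response probability for one record (scalar) or a dataset subset."""
    if isinstance(record_or_ds, ICRecord):
        return float(fit.predict(_as_singleton_ds(record_or_ds))[0])
    return fit.predict(record_or_ds, idx)


def predict_pi(fit: PiFit, record_or_ds, idx=None):
    """Event-type probability vector(s); rows sum to one."""
    if isinstance(record_or_ds, ICRecord):
        return fit.predict(_as_singleton_ds(record_or_ds))[0]
    return fit.predict(record_or_ds, idx)
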