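"""Benchmark strategies for missing event types: complete-case analysis
and multiple imputation with Rubin's rules.

The complete-case (CC) analysis simply drops the events whose type is
missing and runs the complete-data sieve MLE.  Because missingness can
only occur among events (right-censored subjects are always fully
observed), CC selectively removes events and is biased whenever the
response probability is not constant.

Multiple imputation (MI) draws each missing type from the fitted
event-type model -- properly, with the model parameters themselves
redrawn from their asymptotic normal per imputation -- fits the
complete-data sieve MLE on each completed dataset, and pools with
Rubin's rules.  MI is biased when the imputation model is misspecified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import ICDataset, MISSING_CAUSE
from .estimator import FitConfig, FitResult, bootstrap_variance, fit_complete
from .nuisance import PiFit, fit_pi

logger = logging.getLogger(__name__)

__all__ = ["MIPooled", "MIResult", "run_cc", "mi_impute", "rubin_pool", "run_mi"]


@dataclass
class MIPooled:
    """Rubin's-rules summary over M imputations."""

    m_imputations: int
    beta_bar: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray

    @property
    def total_var(self) -> np.ndarray:
        return self.within_var + (1.0 + 1.0 / self.m_imputations) * self.between_var

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total_var)


@dataclass
class MIResult:
    """Pooled MI fit exposing the same summary surface as a FitResult."""

    pooled: MIPooled
    fits: list
    converged: bool = True
    se_beta: np.ndarray | None = None
    ci_beta: np.ndarray | None = None

    @property
    def beta_hat(self) -> np.ndarray:
        return self.pooled.beta_bar


def run_cc(ds: ICDataset, config: FitConfig | None = None,
           x0: np.ndarray | None = None) -> FitResult:
    """Complete-case analysis: drop missing-type events (only those --
    right-censored subjects have nothing to drop), then run the
    complete-data sieve MLE."""
    keep = ds.r == 1
    return fit_complete(ds.subset(keep), config, x0=x0)


def mi_impute(ds: ICDataset, pi_fit: PiFit, seed=None,
              proper: bool = True) -> ICDataset:
    """One imputed dataset: every missing event type drawn from the
    event-type model.

    Proper MI first perturbs the model coefficients with a draw from
    their asymptotic normal distribution; improper MI (``proper=False``)
    keeps them fixed at the MLE.
    """
    rng = np.random.default_rng(seed)
    miss = np.flatnonzero(ds.r == 0)
    if miss.size == 0:
        return ds
    psi = None
    if proper and pi_fit.psi is not None and pi_fit.cov is not None:
        flat = np.asarray(pi_fit.psi, dtype=float).ravel()
        psi = rng.multivariate_normal(flat, pi_fit.cov)  # svd: tolerates PSD
        if np.asarray(pi_fit.psi).ndim > 1:
            psi = psi.reshape(np.asarray(pi_fit.psi).shape)
    probs = pi_fit.predict(ds, miss, psi=psi)
    draws = np.array(
        [rng.choice(ds.k, p=probs[i]) + 1 for i in range(len(miss))], dtype=int
    )
    cause = ds.cause.copy()
    r = ds.r.copy()
    cause[miss] = draws
    r[miss] = 1
    out = ICDataset(ids=ds.ids, v=ds.v, u=ds.u, cause=cause, r=r,
                    z=ds.z, a=ds.a, k=ds.k,
                    z_names=ds.z_names, a_names=ds.a_names)
    return out


def rubin_pool(estimates, variances) -> MIPooled:
    """Rubin's rules: pooled mean, within-variance W, between-variance B
    and total variance ``T = W + (1 + 1/M) B``."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    M = est.shape[0]
    if M < 2:
        raise ValueError("Rubin's rules require at least two imputations")
    beta_bar = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1)
    return MIPooled(m_imputations=M, beta_bar=beta_bar,
                    within_var=within, between_var=between)


def run_mi(ds: ICDataset, config: FitConfig | None = None, M: int = 5,
           B_within: int = 0, seed=None, proper: bool = True) -> MIResult:
    """Multiple imputation: M completed datasets, M complete-data sieve
    fits, Rubin's-rules pooling.

    ``B_within`` bootstrap replicates per imputation feed the
    within-imputation variance; with ``B_within = 0`` only pooled point
    estimates are produced.  Without any missing types this reduces to a
    single complete-data fit.
    """
    config = config or FitConfig()
    if not np.any(ds.r == 0):
        fit = fit_complete(ds, config)
        pooled = MIPooled(m_imputations=1, beta_bar=fit.beta_hat,
                          within_var=np.zeros_like(fit.beta_hat),
                          between_var=np.zeros_like(fit.beta_hat))
        return MIResult(pooled=pooled, fits=[fit], converged=fit.converged,
                        se_beta=fit.se_beta, ci_beta=fit.ci_beta)
    pi_fit = fit_pi(ds, config.pi_design)
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    children = ss.spawn(M)
    fits, estimates, variances = [], [], []
    x0 = None
    for child in children:
        imputed = mi_impute(ds, pi_fit, seed=child, proper=proper)
        fit = fit_complete(imputed, config, x0=x0)
        if B_within > 0:
            fit = bootstrap_variance(
                imputed, config, B=B_within, fit=fit,
                seed=int(child.generate_state(1)[0] % 2**31),
                fitter=fit_complete,
            )
            variances.append(fit.se_beta**2)
        fits.append(fit)
        estimates.append(fit.beta_hat)
    if B_within == 0:
        variances = [np.zeros_like(e) for e in estimates]
    pooled = rubin_pool(estimates, variances)
    result = MIResult(pooled=pooled, fits=fits,
                      converged=all(f.converged for f in fits))
    if B_within > 0:
        result.se_beta = pooled.se
        result.ci_beta = np.column_stack([
            pooled.beta_bar - 1.96 * pooled.se,
            pooled.beta_bar + 1.96 * pooled.se,
        ])
    return result
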