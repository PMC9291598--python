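"""Monte Carlo study orchestration: replicate the generative design,
fit the competing strategies, and summarize percent bias, Monte Carlo
standard deviation (MCSD), average standard error (ASE) and empirical
coverage probability (ECP) per coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .comparators import run_cc, run_mi
from .estimator import FitConfig, bootstrap_variance, fit_aipw, predict_cif
from .simulate import SimScenario, gompertz_phi, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["SimSummary", "percent_bias", "ecp", "run_scenario"]


def percent_bias(estimates, truth: float) -> float:
    """``100 (mean(estimates) - truth) / truth``; undefined at truth 0
    (use absolute bias there)."""
    if truth == 0:
        raise ValueError("percent bias is undefined for a zero truth; "
                         "use absolute bias")
    return float(100.0 * (np.mean(estimates) - truth) / truth)


def ecp(cis, truth: float) -> float:
    """Fraction of intervals (lo, hi) containing the truth."""
    cis = list(cis)
    if not cis:
        raise ValueError("empty interval list")
    hits = sum(1 for lo, hi in cis if lo <= truth <= hi)
    return hits / len(cis)


@dataclass
class SimSummary:
    """Table-1-shaped summary of one scenario.

    ``results[method]`` maps to a dict of per-coefficient arrays
    (percent_bias, mcsd, and -- when bootstrapping was on -- ase, ecp);
    ``cif_overlay`` optionally carries the mean fitted baseline CIF
    curves against the generative truth.
    """

    scenario: SimScenario
    truth: np.ndarray
    results: dict = field(default_factory=dict)
    reps_completed: dict = field(default_factory=dict)
    reps_failed: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)
    cif_overlay: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        coef_names = [
            f"beta{j+1}{c+1}"
            for j in range(self.scenario.k) for c in range(self.scenario.d)
        ]
        for method, stats in self.results.items():
            for stat_name, values in stats.items():
                row = {"method": method, "stat": stat_name}
                row.update({cn: values[i] for i, cn in enumerate(coef_names)})
                rows.append(row)
        return pd.DataFrame(rows)


def _one_replicate(scenario: SimScenario, rep_seed: int, methods, config: FitConfig,
                   bootstrap_B: int, mi_m: int, stratified: bool,
                   cif_times: np.ndarray | None):
    """Simulate one dataset and fit every requested method on it."""
    ds = simulate_dataset(replace(scenario, seed=rep_seed))
    out = {}
    for method in methods:
        try:
            if method == "aipw":
                fit = fit_aipw(ds, config)
                if bootstrap_B > 0:
                    fit = bootstrap_variance(ds, config, B=bootstrap_B,
                                             stratified=stratified, fit=fit,
                                             seed=rep_seed + 1)
            elif method == "cc":
                fit = run_cc(ds, config)
                if bootstrap_B > 0:
                    fit = bootstrap_variance(
                        ds.subset(ds.r == 1), config, B=bootstrap_B, fit=fit,
                        seed=rep_seed + 1,
                        fitter=lambda d, c, x0=None: run_cc(d, c, x0=x0),
                    )
            elif method == "mi":
                fit = run_mi(ds, config, M=mi_m, B_within=bootstrap_B,
                             seed=rep_seed + 2)
            else:
                raise ValueError(f"unknown method '{method}'")
            entry = {"beta": np.asarray(fit.beta_hat, float),
                     "se": None if fit.se_beta is None else np.asarray(fit.se_beta),
                     "ci": None if fit.ci_beta is None else np.asarray(fit.ci_beta)}
            if method == "aipw" and cif_times is not None:
                entry["cif"] = predict_cif(
                    fit, np.zeros(ds.d),
                    np.clip(cif_times, fit.theta_hat.spec.a, fit.theta_hat.spec.b),
                )
            out[method] = entry
        except Exception as exc:
            logger.debug("replicate seed=%d method=%s failed: %s", rep_seed, method, exc)
            out[method] = None
    return out


def run_scenario(
    scenario: SimScenario,
    methods=("aipw",),
    reps: int = 200,
    bootstrap_B: int = 0,
    seed: int = 0,
    workers: int = 1,
    config: FitConfig | None = None,
    mi_m: int = 5,
    stratified: bool = False,
    cif_times: np.ndarray | None = None,
) -> SimSummary:
    """Replicate the scenario and summarize each method.

    Per-replicate seeds are derived from the master ``seed`` by a
    counter-based scheme, so results are identical for any worker count.
    ASE and ECP are produced only when ``bootstrap_B > 0``.  Replicates
    where a method fails to converge are dropped for that method and
    counted in ``reps_failed``.
    """
    config = config or FitConfig()
    truth = scenario.beta_flat()
    rep_seeds = [
        int(s) for s in
        np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint32) % (2**31 - 3)
    ]
    work = (delayed(_one_replicate)(scenario, rs, methods, config, bootstrap_B,
                                    mi_m, stratified, cif_times)
            for rs in rep_seeds)
    results = Parallel(n_jobs=workers)(work) if workers != 1 else [
        _one_replicate(scenario, rs, methods, config, bootstrap_B, mi_m,
                       stratified, cif_times)
        for rs in rep_seeds
    ]

    summary = SimSummary(scenario=scenario, truth=truth)
    for method in methods:
        good = [r[method] for r in results if r[method] is not None]
        n_fail = reps - len(good)
        if n_fail > 0.05 * reps:
            logger.warning("method %s: %d/%d replicates failed", method, n_fail, reps)
        betas = np.vstack([g["beta"] for g in good])
        stats = {
            "percent_bias": np.array([
                percent_bias(betas[:, i], truth[i]) for i in range(len(truth))
            ]),
            "mcsd": betas.std(axis=0, ddof=1),
        }
        if bootstrap_B > 0 and all(g["se"] is not None for g in good):
            ses = np.vstack([g["se"] for g in good])
            stats["ase"] = ses.mean(axis=0)
            stats["ecp"] = np.array([
                ecp([(g["ci"][i, 0], g["ci"][i, 1]) for g in good], truth[i])
                for i in range(len(truth))
            ])
        summary.results[method] = stats
        summary.reps_completed[method] = len(good)
        summary.reps_failed[method] = n_fail
        summary.estimates[method] = betas
        if method == "aipw" and cif_times is not None:
            curves = [g["cif"] for g in good if "cif" in g]
            if curves:
                mean_cif = np.mean(curves, axis=0)
                frames = {"time": cif_times}
                for j in range(scenario.k):
                    frames[f"cif{j+1}_mean_fit"] = mean_cif[j]
                    phi = gompertz_phi(cif_times, scenario.tau[j], scenario.rho_g[j])
                    frames[f"cif{j+1}_true"] = np.exp(phi) / (1.0 + np.exp(phi))
                summary.cif_overlay = pd.DataFrame(frames)
    return summary
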