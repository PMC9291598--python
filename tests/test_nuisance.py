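"""Stage-1 logistic nuisance models: closed-form anchors, an independent
IRLS oracle, score equations, and the clipping contract."""

import numpy as np
import pytest
from scipy.special import expit, logit

from icaipw import (
    ICDataset,
    MISSING_CAUSE,
    NoMissingnessError,
    NuisanceConvergenceError,
    NuisanceDesign,
    SimScenario,
    fit_pi,
    fit_rho,
    predict_pi,
    predict_rho,
    simulate_dataset,
)
from icaipw.nuisance import EPS_CLIP, RhoFit


def _events_dataset(r, cause, u=None, z=None):
    n = len(r)
    return ICDataset(
        ids=np.arange(n), v=np.full(n, 0.2),
        u=np.full(n, 0.8) if u is None else np.asarray(u, float),
        cause=np.asarray(cause), r=np.asarray(r),
        z=np.zeros((n, 1)) if z is None else np.asarray(z, float),
        a=np.zeros((n, 0)),
    )


def _irls_logit(y, X, iters=60):
    """Textbook iteratively reweighted least squares, as an independent
    oracle for the logistic MLE."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = expit(X @ beta)
        W = p * (1 - p)
        beta = beta + np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - p))
    return beta


class TestFitRho:
    def test_intercept_only_closed_form(self):
        # 7 of 10 events observed -> xi0 = logit(0.7)
        ds = _events_dataset(
            r=[1] * 7 + [0] * 3,
            cause=[1, 2, 1, 2, 1, 2, 1] + [MISSING_CAUSE] * 3,
        )
        fit = fit_rho(ds, NuisanceDesign(terms=("1",)))
        assert fit.xi[0] == pytest.approx(logit(0.7), abs=1e-6)

    def test_no_missingness_signal(self):
        ds = _events_dataset(r=[1] * 10, cause=[1, 2] * 5)
        with pytest.raises(NoMissingnessError):
            fit_rho(ds)

    def test_separation_detected(self):
        # R perfectly determined by z -> quasi-complete separation
        z = np.array([[0.0]] * 5 + [[1.0]] * 5)
        ds = _events_dataset(r=[1] * 5 + [0] * 5,
                             cause=[1, 2, 1, 2, 1] + [MISSING_CAUSE] * 5, z=z)
        with pytest.raises(NuisanceConvergenceError):
            fit_rho(ds, NuisanceDesign(terms=("1", "z1")))

    def test_parameter_recovery_generative_truth(self):
        # logit(rho) = 0.60 + 0.5 U - 0.5 Z1 + 0.6 Z2 + 0*A
        ds = simulate_dataset(SimScenario(n=5000, seed=77))
        fit = fit_rho(ds)
        truth = np.array([0.60, 0.5, -0.5, 0.6, 0.0])
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(fit.xi - truth) < 3 * se)

    def test_matches_irls_oracle_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = 60
            u = rng.uniform(0.1, 2, n)
            z = rng.normal(0, 1, (n, 1))
            eta = 0.3 + 0.4 * u - 0.6 * z[:, 0]
            r = (rng.random(n) < expit(eta)).astype(int)
            if r.min() == 1 or r.max() == 0:
                continue
            cause = np.where(r == 1, rng.integers(1, 3, n), MISSING_CAUSE)
            if len(np.unique(cause[r == 1])) < 2:
                continue
            ds = _events_dataset(r=r, cause=cause, u=u, z=z)
            try:
                fit = fit_rho(ds, NuisanceDesign(terms=("1", "u", "z1")))
            except NuisanceConvergenceError:
                continue
            X = np.column_stack([np.ones(n), u, z[:, 0]])
            np.testing.assert_allclose(fit.xi, _irls_logit(r.astype(float), X), atol=1e-6)
            # score equations at the optimum
            resid = r - expit(X @ fit.xi)
            assert np.max(np.abs(X.T @ resid)) < 1e-5


class TestFitPi:
    def test_intercept_only_closed_form(self):
        # 6 of 10 complete events are cause 1 -> psi0 = logit(0.6)
        ds = _events_dataset(r=[1] * 10, cause=[1] * 6 + [2] * 4)
        fit = fit_pi(ds, NuisanceDesign(terms=("1",)))
        assert fit.psi[0] == pytest.approx(logit(0.6), abs=1e-6)

    def test_probabilities_sum_to_one(self):
        ds = simulate_dataset(SimScenario(n=400, seed=3))
        fit = fit_pi(ds)
        probs = predict_pi(fit, ds, np.flatnonzero(ds.delta == 1))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_single_observed_cause_degenerate(self):
        ds = _events_dataset(r=[1] * 8, cause=[1] * 8)
        with pytest.raises(NuisanceConvergenceError):
            fit_pi(ds)

    def test_constant_covariate_rank_deficiency(self):
        ds = _events_dataset(r=[1] * 10, cause=[1, 2] * 5)  # z1 all zero
        with pytest.raises(NuisanceConvergenceError, match="rank"):
            fit_pi(ds, NuisanceDesign(terms=("1", "z1")))

    def test_saturated_model_is_cell_proportions(self):
        z = np.array([[0.0]] * 6 + [[1.0]] * 6)
        cause = [1, 1, 2, 1, 1, 2] + [2, 2, 2, 1, 2, 2]
        ds = _events_dataset(r=[1] * 12, cause=cause, z=z)
        fit = fit_pi(ds, NuisanceDesign(terms=("z1",), saturated=True))
        probs = predict_pi(fit, ds)
        np.testing.assert_allclose(probs[0], [4 / 6, 2 / 6], atol=1e-12)
        np.testing.assert_allclose(probs[-1], [1 / 6, 5 / 6], atol=1e-12)


class TestPredict:
    def test_zero_coefficients_give_half(self):
        ds = _events_dataset(r=[1, 0], cause=[1, MISSING_CAUSE])
        fit = RhoFit(xi=np.zeros(2), cov=np.eye(2),
                     design=NuisanceDesign(terms=("1", "u")))
        np.testing.assert_allclose(predict_rho(fit, ds), 0.5, atol=1e-12)

    def test_hand_computed_linear_predictor(self):
        ds = _events_dataset(r=[1], cause=[1], u=[1.0])
        fit = RhoFit(xi=np.array([0.0, 1.0]), cov=np.eye(2),
                     design=NuisanceDesign(terms=("1", "u")))
        assert predict_rho(fit, ds)[0] == pytest.approx(expit(1.0), abs=1e-12)

    def test_extreme_predictions_clipped(self):
        ds = _events_dataset(r=[1], cause=[1])
        fit = RhoFit(xi=np.array([50.0]), cov=np.eye(1),
                     design=NuisanceDesign(terms=("1",)))
        assert predict_rho(fit, ds)[0] == pytest.approx(1 - EPS_CLIP)
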