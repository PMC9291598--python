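"""Core estimator: likelihood anchors, AIPW weights, feasibility,
gradients, the no-missingness reduction, and bootstrap mechanics."""

import numpy as np
import pytest
from scipy.special import expit, logit

from icaipw import (
    CauseLinkSpec,
    FitConfig,
    ICDataset,
    ICRecord,
    MISSING_CAUSE,
    SieveSpec,
    SimScenario,
    SplineCoefficients,
    ThetaParams,
    aipw_objective,
    bootstrap_variance,
    complete_loglik,
    feasibility_constraint,
    fit_aipw,
    fit_complete,
    predict_cif,
    simulate_dataset,
    tilde_weights,
)
from icaipw.estimator import _Workspace, _aipw_weights, _initial_point
from icaipw.nuisance import NuisanceDesign, NuisanceFit, PiFit, RhoFit, fit_nuisance
from icaipw.sieve import select_knots


def _linear_theta(F_at_0, F_at_1, betas=None, b=1.0):
    """Two-cause model with linear phi on [0, b]: F_j interpolates (on the
    logit scale, alpha = 1) between the given endpoint values at z = 0."""
    spec = SieveSpec(order_m=2, n_interior=0, knots=np.array([0.0, 0.0, b, b]))
    k = len(F_at_0)
    betas = [np.zeros(1)] * k if betas is None else [np.atleast_1d(b_) for b_ in betas]
    return ThetaParams(
        spec=spec,
        gammas=[SplineCoefficients(np.array([logit(F_at_0[j]), logit(F_at_1[j])]))
                for j in range(k)],
        betas=betas,
        links=[CauseLinkSpec(1.0)] * k,
    )


def _dataset(rows, d=1):
    """rows: list of dicts with v, u, cause, r (z defaults to 0)."""
    n = len(rows)
    return ICDataset(
        ids=np.arange(n),
        v=np.array([r["v"] for r in rows], float),
        u=np.array([r["u"] for r in rows], float),
        cause=np.array([r.get("cause", 0) for r in rows]),
        r=np.array([r.get("r", 1) for r in rows]),
        z=np.array([[r.get("z", 0.0)] for r in rows]),
        a=np.zeros((n, 0)),
    )


class TestCompleteLoglik:
    def test_right_censored_record(self):
        # F1(V)=0.2, F2(V)=0.3 -> log 0.5
        theta = _linear_theta([0.2, 0.3], [0.5, 0.4])
        ds = _dataset([dict(v=0.0, u=np.inf, cause=0)])
        assert complete_loglik(theta, ds) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_interval_censored_record(self):
        # F1(U)=0.5, F1(V)=0.2 -> log 0.3 (V at a=0, U at b=1)
        theta = _linear_theta([0.2, 0.3], [0.5, 0.4])
        ds = _dataset([dict(v=1e-12, u=1.0, cause=1)])  # v>0: interval-censored
        assert complete_loglik(theta, ds) == pytest.approx(np.log(0.3), abs=1e-9)

    def test_left_censored_record(self):
        # F2(U)=0.25 at U=b -> log 0.25
        theta = _linear_theta([0.05, 0.1], [0.5, 0.25])
        ds = _dataset([dict(v=0.0, u=1.0, cause=2)])
        assert complete_loglik(theta, ds) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_missing_cause_rejected(self):
        theta = _linear_theta([0.2, 0.3], [0.5, 0.4])
        ds = _dataset([dict(v=0.2, u=1.0, cause=MISSING_CAUSE, r=0)])
        with pytest.raises(ValueError, match="observed"):
            complete_loglik(theta, ds)

    def test_infeasible_point_returns_minus_inf(self):
        # sum of CIFs above one at V -> nonpositive survival argument
        theta = _linear_theta([0.6, 0.55], [0.7, 0.6])
        ds = _dataset([dict(v=0.0, u=np.inf, cause=0)])
        assert complete_loglik(theta, ds) == -np.inf


def _record(v, u, cause, r):
    return ICRecord(id=0, v=v, u=u, delta=1, delta1=int(v > 0), delta2=int(v == 0),
                    cause=cause, r=r, z=np.zeros(1), a=np.zeros(0))


class TestTildeWeights:
    def test_no_missingness_reduction(self):
        rec = _record(v=0.3, u=0.8, cause=2, r=1)
        w = tilde_weights(rec, rho_hat=1.0 - 1e-12, pi_hat=np.array([0.3, 0.7]))
        np.testing.assert_allclose(w, [[0.0, 0.0], [1.0, 0.0]], atol=1e-9)

    def test_missing_type_gets_pi_weights_on_its_class(self):
        rec = _record(v=0.3, u=0.8, cause=MISSING_CAUSE, r=0)
        w = tilde_weights(rec, rho_hat=0.6, pi_hat=np.array([0.3, 0.7]))
        np.testing.assert_allclose(w[:, 0], [0.3, 0.7], atol=1e-12)
        np.testing.assert_allclose(w[:, 1], [0.0, 0.0], atol=1e-12)

    def test_observed_type_plug_in_arithmetic(self):
        # R=1, rho=0.5, interval-censored cause 1, pi1=0.3:
        # weight_1 = 1/0.5 - (0.5/0.5)*0.3 = 1.7, weight_2 = -0.7
        rec = _record(v=0.3, u=0.8, cause=1, r=1)
        w = tilde_weights(rec, rho_hat=0.5, pi_hat=np.array([0.3, 0.7]))
        np.testing.assert_allclose(w[:, 0], [1.7, -0.7], atol=1e-12)
        assert w[:, 0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_conservation_sums_to_one(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            v = rng.choice([0.0, 0.4])
            rec = _record(v=v, u=0.9, cause=int(rng.integers(1, 3)),
                          r=int(rng.integers(0, 2)))
            if rec.r == 0:
                rec = _record(v=v, u=0.9, cause=MISSING_CAUSE, r=0)
            p1 = rng.uniform(0.05, 0.95)
            w = tilde_weights(rec, rng.uniform(0.1, 0.95), np.array([p1, 1 - p1]))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_right_censored_record_rejected(self):
        rec = ICRecord(id=0, v=1.0, u=np.inf, delta=0, delta1=0, delta2=0,
                       cause=0, r=1, z=np.zeros(1), a=np.zeros(0))
        with pytest.raises(ValueError):
            tilde_weights(rec, 0.5, np.array([0.5, 0.5]))


class TestAipwObjective:
    def test_reduction_without_missingness(self):
        theta = _linear_theta([0.1, 0.15], [0.4, 0.3])
        ds = _dataset([
            dict(v=0.2, u=0.8, cause=1), dict(v=0.0, u=0.5, cause=2),
            dict(v=0.9, u=np.inf, cause=0),
        ])
        nui = fit_nuisance(ds)  # flags no_missingness
        assert nui.no_missingness
        assert aipw_objective(theta, ds, nui) == pytest.approx(
            complete_loglik(theta, ds), abs=1e-12)

    def test_missing_record_pattern(self):
        # single R=0 interval record: 0.3 log{F1(U)-F1(V)} + 0.7 log{F2(U)-F2(V)}
        theta = _linear_theta([0.1, 0.15], [0.4, 0.3])
        ds = _dataset([dict(v=1e-9, u=1.0, cause=MISSING_CAUSE, r=0)])
        nui = NuisanceFit(
            rho=RhoFit(xi=np.array([logit(0.6)]), cov=np.eye(1),
                       design=NuisanceDesign(terms=("1",))),
            pi=PiFit(k=2, psi=np.array([logit(0.3)]), cov=np.eye(1),
                     design=NuisanceDesign(terms=("1",))),
        )
        expected = 0.3 * np.log(0.4 - 0.1) + 0.7 * np.log(0.3 - 0.15)
        assert aipw_objective(theta, ds, nui) == pytest.approx(expected, abs=1e-6)

    def test_three_record_hand_sum(self):
        # one record per censoring class, fixed rho=0.6, pi=(0.3, 0.7)
        theta = _linear_theta([0.1, 0.15], [0.4, 0.3])
        ds = _dataset([
            dict(v=0.5, u=1.0, cause=1, r=1),              # interval, observed
            dict(v=0.0, u=1.0, cause=MISSING_CAUSE, r=0),  # left, missing
            dict(v=0.0, u=np.inf, cause=0),                # right-censored
        ])
        nui = NuisanceFit(
            rho=RhoFit(xi=np.array([logit(0.6)]), cov=np.eye(1),
                       design=NuisanceDesign(terms=("1",))),
            pi=PiFit(k=2, psi=np.array([logit(0.3)]), cov=np.eye(1),
                     design=NuisanceDesign(terms=("1",))),
        )
        # spreadsheet-style oracle, alpha = 1 so F = expit(linear phi)
        F = lambda j, t: expit(np.interp(t, [0, 1], [logit([0.1, 0.15][j]),
                                               logit([0.4, 0.3][j])]))
        w1 = np.array([1 / 0.6 - (0.4 / 0.6) * 0.3, -(0.4 / 0.6) * 0.7])
        rec1 = w1[0] * np.log(F(0, 1.0) - F(0, 0.5)) + w1[1] * np.log(F(1, 1.0) - F(1, 0.5))
        rec2 = 0.3 * np.log(F(0, 1.0)) + 0.7 * np.log(F(1, 1.0))
        rec3 = np.log(1 - F(0, 0.0) - F(1, 0.0))
        expected = (rec1 + rec2 + rec3) / 3
        assert aipw_objective(theta, ds, nui) == pytest.approx(expected, abs=1e-12)


class TestFeasibility:
    def test_feasible_margin(self):
        theta = _linear_theta([0.1, 0.15], [0.5, 0.47])
        ds = _dataset([dict(v=0.2, u=0.8, cause=1)])
        assert feasibility_constraint(theta, ds) == pytest.approx(0.03, abs=1e-9)

    def test_infeasible_row_negative(self):
        theta = _linear_theta([0.1, 0.15], [0.5, 0.47], betas=[[0.5], [0.5]])
        ds = _dataset([dict(v=0.2, u=0.8, cause=1, z=1.0),
                       dict(v=0.2, u=0.8, cause=1, z=0.0)])
        # at z=1 both CIFs shift up; the max over observed rows decides
        val = feasibility_constraint(theta, ds)
        F1 = expit(logit(0.5) + 0.5)
        F2 = expit(logit(0.47) + 0.5)
        assert val == pytest.approx(1 - F1 - F2, abs=1e-9)
        assert val < 0


class TestGradient:
    def test_matches_finite_differences_at_random_feasible_points(self):
        ds = simulate_dataset(SimScenario(n=120, seed=3))
        config = FitConfig()
        spec = select_knots(ds.observation_times(), n=ds.n)
        nui = fit_nuisance(ds)
        W1, W2 = _aipw_weights(ds, nui)
        ws = _Workspace(ds, spec, config.alphas(ds.k), W1, W2, config.log_eps)
        rng = np.random.default_rng(0)
        x0 = _initial_point(ws, config)
        h = 1e-6
        for _ in range(10):
            x = x0 + rng.normal(0, 0.3, len(x0))
            raws, gammas, betas = ws.unpack(x, config.min_gap)
            _, grad = ws.eval_objective(gammas, betas, want_grad=True, raws=raws)
            num = np.empty_like(grad)
            for i in range(len(x)):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                vp, _ = ws.eval_objective(*ws.unpack(xp, config.min_gap)[1:])
                vm, _ = ws.eval_objective(*ws.unpack(xm, config.min_gap)[1:])
                num[i] = (vp - vm) / (2 * h)
            assert np.max(np.abs(grad - num)) <= 1e-4


class TestFitting:
    @pytest.fixture(scope="class")
    def complete_ds(self):
        # response intercept at +50: every event type observed
        return simulate_dataset(SimScenario(n=150, seed=42, xi=(50.0, 0.5, -0.5, 0.6, 0.0)))

    def test_no_missingness_reduction_of_fit(self, complete_ds):
        config = FitConfig(seed=1)
        fit_a = fit_aipw(complete_ds, config)
        fit_c = fit_complete(complete_ds, config)
        assert fit_a.nuisance.no_missingness
        np.testing.assert_allclose(fit_a.beta_hat, fit_c.beta_hat, atol=1e-6)

    def test_fitted_theta_monotone_and_feasible(self, complete_ds):
        fit = fit_complete(complete_ds, FitConfig(seed=1))
        assert fit.converged
        for g in fit.theta_hat.gammas:
            assert np.all(np.diff(g.gamma) > 0)
        assert feasibility_constraint(fit.theta_hat, complete_ds) > 0

    def test_single_observed_cause_degenerate(self):
        ds = simulate_dataset(SimScenario(n=100, seed=9))
        cause = ds.cause.copy()
        cause[cause == 2] = 1  # collapse to one observed type
        bad = ICDataset(ids=ds.ids, v=ds.v, u=ds.u, cause=cause, r=ds.r,
                        z=ds.z, a=ds.a, k=2, z_names=ds.z_names, a_names=ds.a_names)
        from icaipw import NuisanceConvergenceError
        with pytest.raises(NuisanceConvergenceError):
            fit_aipw(bad)

    def test_predict_cif_monotone_and_bounded(self, complete_ds):
        fit = fit_complete(complete_ds, FitConfig(seed=1))
        spec = fit.theta_hat.spec
        times = np.linspace(spec.a, spec.b, 60)
        curves = predict_cif(fit, np.array([1.0, 0.5]), times)
        assert curves.shape == (2, 60)
        assert np.all(np.diff(curves, axis=1) >= -1e-10)
        assert curves[:, -1].sum() < 1
        with pytest.raises(ValueError):
            predict_cif(fit, np.zeros(2), [spec.b + 1.0])


class TestBootstrap:
    def test_zero_replicates_passthrough(self):
        ds = simulate_dataset(SimScenario(n=100, seed=12))
        fit = fit_aipw(ds, FitConfig(seed=0))
        out = bootstrap_variance(ds, FitConfig(seed=0), B=0, fit=fit)
        assert out is fit
        assert out.se_beta is None

    def test_stratified_resampling_preserves_stratum_sizes(self):
        ds = simulate_dataset(SimScenario(n=120, seed=13))
        sizes = {
            "obs": int(np.sum((ds.delta == 1) & (ds.r == 1))),
            "mis": int(np.sum((ds.delta == 1) & (ds.r == 0))),
            "cens": int(np.sum(ds.delta == 0)),
        }
        seen = []

        def spy_fitter(d, config, x0=None):
            seen.append({
                "obs": int(np.sum((d.delta == 1) & (d.r == 1))),
                "mis": int(np.sum((d.delta == 1) & (d.r == 0))),
                "cens": int(np.sum(d.delta == 0)),
            })
            return fit_aipw(d, config, x0=x0)

        fit = fit_aipw(ds, FitConfig(seed=0))
        bootstrap_variance(ds, FitConfig(seed=0), B=3, stratified=True,
                           fit=fit, seed=5, fitter=spy_fitter)
        assert all(s == sizes for s in seen)

    def test_se_and_ci_produced(self):
        ds = simulate_dataset(SimScenario(n=150, seed=14))
        fit = fit_aipw(ds, FitConfig(seed=0))
        out = bootstrap_variance(ds, FitConfig(seed=0), B=12, fit=fit, seed=3)
        assert out.se_beta.shape == (4,)
        assert np.all(out.se_beta > 0)
        np.testing.assert_allclose(
            out.ci_beta[:, 1] - out.ci_beta[:, 0], 2 * 1.96 * out.se_beta, atol=1e-12)
        assert out.n_bootstrap_used == 12
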