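import math

import numpy as np
import pandas as pd
import pytest

import deaequity as dq
from deaequity.exceptions import DegenerateFrontierError
from deaequity.sfa import MIXED_CHISQ_CRIT, fit_frontier, loglik_frontier

from conftest import make_period_frames


def simulate_frontier(rng, n, beta=(5.0, 2.0), sigma_v=1.0, sigma_u=2.0):
    z = rng.uniform(0.0, 10.0, n)
    Z = pd.DataFrame({"const": np.ones(n), "z": z})
    y = beta[0] + beta[1] * z + rng.normal(0, sigma_v, n) + np.abs(rng.normal(0, sigma_u, n))
    return pd.Series(y), Z


class TestSlackRegressions:
    def test_slack_is_radial_plus_nonradial(self, default_panel):
        panel, _ = default_panel
        period = panel.periods[-1]
        X, Y = panel.period_data(period)
        vrs = dq.solve_period(X, Y, rts="vrs")
        reg = dq.build_slack_regressions(vrs, panel, period)
        for dmu in panel.dmus:
            expected = (1.0 - vrs[dmu].theta) * X.loc[dmu] + vrs[dmu].input_slacks
            np.testing.assert_allclose(reg.slacks.loc[dmu], expected, atol=1e-9)
            if vrs[dmu].is_efficient:
                assert (reg.slacks.loc[dmu] <= 1e-6).all()
        assert list(reg.design.columns[:1]) == ["const"]

    def test_theta_half_arithmetic(self):
        r = dq.DEAResult("d", 0.5, pd.Series({"d": 1.0}),
                         pd.Series({"x": 0.0}), pd.Series(dtype=float), "vrs")
        # S = (1 - 0.5) * 4 + 0 = 2
        assert (1.0 - r.theta) * 4.0 + r.input_slacks["x"] == 2.0


class TestFitFrontier:
    def test_no_inefficiency_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        y, Z = simulate_frontier(rng, 400, sigma_u=0.0)
        fit = fit_frontier(y, Z)
        beta_ols, *_ = np.linalg.lstsq(Z.to_numpy(), y.to_numpy(), rcond=None)
        assert fit.gamma <= 0.3
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=0.25)

    def test_parameter_recovery(self):
        """50 replicates at n=500: mean gamma within 0.1 of 0.8, betas within 0.15."""
        rng = np.random.default_rng(11)
        gammas, b0, b1 = [], [], []
        for _ in range(50):
            y, Z = simulate_frontier(rng, 500)
            fit = fit_frontier(y, Z)
            gammas.append(fit.gamma)
            b0.append(fit.beta["const"])
            b1.append(fit.beta["z"])
        assert np.mean(gammas) == pytest.approx(0.8, abs=0.1)
        assert np.mean(b0) == pytest.approx(5.0, abs=0.15)
        assert np.mean(b1) == pytest.approx(2.0, abs=0.15)

    def test_lr_stays_below_boundary_critical_value_under_null(self):
        """One-sided LR on sigma_u=0 data rarely exceeds the 5% mixed-chi2 cutoff."""
        rng = np.random.default_rng(5)
        below = sum(
            fit_frontier(*simulate_frontier(rng, 200, sigma_u=0.0)).lr_one_sided
            < MIXED_CHISQ_CRIT[0.05]
            for _ in range(30)
        )
        assert below >= 27  # >= 90% of replicates

    def test_positive_effect_recovered_with_positive_sign(self):
        """A covariate inflating slack by 2 sigma_v per unit gets beta_hat > 0."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(30):
            n = 100
            z = rng.uniform(0, 4, n)
            Z = pd.DataFrame({"const": np.ones(n), "z": z})
            y = 1.0 + 2.0 * z + rng.normal(0, 1.0, n) + np.abs(rng.normal(0, 1.5, n))
            hits += fit_frontier(y, Z).beta["z"] > 0
        assert hits >= 27

    def test_zero_variance_dependent_is_degenerate(self):
        Z = pd.DataFrame({"const": np.ones(10), "z": np.arange(10.0)})
        with pytest.raises(DegenerateFrontierError, match="degenerate frontier"):
            fit_frontier(pd.Series(np.zeros(10)), Z)

    def test_too_few_observations_rejected(self):
        Z = pd.DataFrame({"const": np.ones(3), "z": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="observations"):
            fit_frontier(pd.Series([1.0, 2.0, 3.0]), Z)

    def test_loglik_matches_independent_grid_evaluation(self):
        """The optimizer's loglik agrees with a direct likelihood formula and is
        at least the likelihood at the true parameters."""
        rng = np.random.default_rng(3)
        y, Z = simulate_frontier(rng, 300)
        fit = fit_frontier(y, Z)
        # independent evaluation: plain sums of the half-normal density
        from scipy.stats import norm

        def direct_ll(beta, sigma2, gamma):
            sigma = math.sqrt(sigma2)
            lam = math.sqrt(gamma / (1 - gamma))
            eps = y.to_numpy() - Z.to_numpy() @ np.asarray(beta)
            return float(np.sum(np.log(2.0 / sigma * norm.pdf(eps / sigma)
                                       * norm.cdf(eps * lam / sigma))))

        assert fit.loglik == pytest.approx(
            direct_ll(fit.beta.to_numpy(), fit.sigma2, min(fit.gamma, 1 - 1e-6)), abs=1e-6)
        true_ll = loglik_frontier(y.to_numpy(), Z.to_numpy(),
                                  np.array([5.0, 2.0]), 5.0, 0.8)
        assert fit.loglik >= true_ll - 1e-9


class TestDecomposeResiduals:
    def test_jlms_closed_form_at_zero_residual(self):
        """eps=0, sigma_u=sigma_v=1: u_hat = phi(0)/Phi(0)/sqrt(2) ~ 0.5642."""
        fit = dq.SFAFit(beta=pd.Series({"const": 0.0}), sigma2=2.0, gamma=0.5,
                        loglik=0.0, lr_one_sided=0.0, converged=True)
        dec = dq.decompose_residuals(fit, pd.Series([0.0]), pd.DataFrame({"const": [1.0]}))
        assert dec.u_hat.iloc[0] == pytest.approx(0.5641895835, abs=1e-9)
        assert dec.v_hat.iloc[0] == pytest.approx(-0.5641895835, abs=1e-9)

    def test_gamma_zero_limit_gives_no_inefficiency(self):
        fit = dq.SFAFit(beta=pd.Series({"const": 1.0}), sigma2=1.0, gamma=0.0,
                        loglik=0.0, lr_one_sided=0.0, converged=True)
        dec = dq.decompose_residuals(fit, pd.Series([0.0, 2.0, -1.0]),
                                     pd.DataFrame({"const": np.ones(3)}))
        assert (dec.u_hat == 0).all()
        np.testing.assert_allclose(dec.v_hat, dec.residuals)

    def test_mean_u_hat_matches_halfnormal_mean(self):
        """E[u] = sigma_u sqrt(2/pi); the JLMS means should average to it."""
        rng = np.random.default_rng(9)
        sigma_u = 2.0
        y, Z = simulate_frontier(rng, 4000, sigma_u=sigma_u)
        fit = fit_frontier(y, Z)
        dec = dq.decompose_residuals(fit, y, Z)
        assert dec.u_hat.mean() == pytest.approx(sigma_u * math.sqrt(2 / math.pi), rel=0.10)

    def test_u_hat_nonnegative_and_finite_in_tails(self):
        fit = dq.SFAFit(beta=pd.Series({"const": 0.0}), sigma2=2.0, gamma=0.5,
                        loglik=0.0, lr_one_sided=0.0, converged=True)
        eps = pd.Series([-60.0, -10.0, 0.0, 10.0, 60.0])
        dec = dq.decompose_residuals(fit, eps, pd.DataFrame({"const": np.ones(5)}))
        assert (dec.u_hat >= 0).all()
        assert np.isfinite(dec.v_hat).all()


class TestAdjustInputs:
    def _fixture(self):
        rng = np.random.default_rng(2)
        X, _ = make_period_frames(rng.uniform(10, 100, (8, 2)), np.ones((8, 1)))
        Z = pd.DataFrame({"const": np.ones(8), "z": rng.uniform(0, 5, 8)}, index=X.index)
        fits, decs = {}, {}
        for name in X.columns:
            fit = dq.SFAFit(beta=pd.Series({"const": 1.0, "z": 2.0}), sigma2=1.0,
                            gamma=0.5, loglik=0.0, lr_one_sided=0.0, converged=True)
            fits[name] = fit
            y = pd.Series(rng.uniform(0, 10, 8), index=X.index)
            decs[name] = dq.decompose_residuals(fit, y, Z)
        return X, Z, fits, decs

    def test_adjustment_never_lowers_inputs(self):
        X, Z, fits, decs = self._fixture()
        XA = dq.adjust_inputs(X, fits, decs, Z)
        assert (XA.to_numpy() >= X.to_numpy() - 1e-12).all()

    def test_max_environment_dmu_and_max_luck_dmu_unadjusted(self):
        X, Z, fits, decs = self._fixture()
        XA = dq.adjust_inputs(X, fits, decs, Z)
        for name in X.columns:
            f = Z.to_numpy() @ fits[name].beta.to_numpy()
            env_adj = f.max() - f
            v = decs[name].v_hat.to_numpy()
            luck_adj = v.max() - v
            assert env_adj.min() == pytest.approx(0.0, abs=1e-12)
            assert luck_adj.min() == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(XA[name], X[name] + env_adj + luck_adj)

    def test_homogeneous_dmus_unchanged(self):
        X, _ = make_period_frames(np.full((4, 1), 10.0), np.ones((4, 1)))
        Z = pd.DataFrame({"const": np.ones(4), "z": np.full(4, 2.0)}, index=X.index)
        fit = dq.SFAFit(beta=pd.Series({"const": 1.0, "z": 1.0}), sigma2=1.0,
                        gamma=0.5, loglik=0.0, lr_one_sided=0.0, converged=True)
        dec = dq.decompose_residuals(fit, pd.Series(np.full(4, 3.0), index=X.index), Z)
        XA = dq.adjust_inputs(X, {"x0": fit}, {"x0": dec}, Z)
        pd.testing.assert_frame_equal(XA, X)
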