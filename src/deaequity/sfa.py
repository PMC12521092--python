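"""Stage 2: stochastic-frontier regression of input slacks on environment covariates.

Each input indicator's total stage-1 slack, S_i = (1 - theta_i) x_i + s-_i
(radial excess plus residual slack), is regressed on the environment covariates
with a composed error:

    S_i = Z_i beta + v_i + u_i,   v ~ N(0, sigma_v^2),   u ~ |N(0, sigma_u^2)|,

the cost-frontier orientation: inefficiency u >= 0 inflates slack.  Estimation is
maximum likelihood in the (sigma^2, gamma) parameterisation, sigma^2 = sigma_u^2
+ sigma_v^2 and gamma = sigma_u^2 / sigma^2, with a multi-start over a gamma grid
and modified-OLS initial values.  Observation-level inefficiency is recovered by
the Jondrow-Lovell-Materov-Schmidt conditional mean E[u | v + u], and the Fried
adjustment then raises every DMU's input to the level of the least favourable
environment and the worst luck, so stage 3 compares DMUs on management alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .dea import DEAResult
from .exceptions import DegenerateFrontierError
from .panel import PanelDataset

#: 50:50 mixed chi2(0)/chi2(1) critical values for the one-sided LR test of gamma=0
MIXED_CHISQ_CRIT = {0.10: 1.642, 0.05: 2.706, 0.01: 5.412}

_GAMMA_GRID = np.arange(0.05, 0.96, 0.10)
_GAMMA_EPS = 1e-6
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class SlackRegressionData:
    """Per-input dependent slack vectors and the shared covariate design matrix."""

    slacks: pd.DataFrame   # dmus x inputs, S_ni >= 0
    design: pd.DataFrame   # dmus x (const + environment covariates)


@dataclass
class SFAFit:
    """ML estimates of one input's frontier regression."""

    beta: pd.Series
    sigma2: float
    gamma: float
    loglik: float
    lr_one_sided: float
    converged: bool
    beta_se: pd.Series | None = None
    sigma2_se: float | None = None
    gamma_se: float | None = None

    @property
    def sigma_u2(self) -> float:
        return self.gamma * self.sigma2

    @property
    def sigma_v2(self) -> float:
        return (1.0 - self.gamma) * self.sigma2


@dataclass
class NoiseDecomposition:
    """Residuals split into inefficiency (u_hat >= 0) and noise (v_hat)."""

    residuals: pd.Series
    u_hat: pd.Series
    v_hat: pd.Series


def build_slack_regressions(stage1: dict[str, DEAResult], panel: PanelDataset,
                            period) -> SlackRegressionData:
    """Assemble S_ni = (1 - theta_i) X_ni + s-_ni and the covariate design.

    ``stage1`` holds the BCC (VRS) envelopment results of the chosen period, one
    per DMU; the dependent slack is actual input minus the frontier target
    theta*x - s-, i.e. radial plus non-radial excess.
    """
    X = panel.slice(period, "input")
    rows = {}
    for dmu in X.index:
        r = stage1[dmu]
        rows[dmu] = (1.0 - r.theta) * X.loc[dmu] + r.input_slacks
    slacks = pd.DataFrame.from_dict(rows, orient="index").loc[X.index].clip(lower=0.0)
    Z = panel.slice(period, "environment")
    design = Z.copy()
    design.insert(0, "const", 1.0)
    return SlackRegressionData(slacks=slacks, design=design)


def _neg_loglik(params: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    """Negative log-likelihood of the normal/half-normal cost frontier."""
    k = Z.shape[1]
    beta = params[:k]
    sigma2 = math.exp(params[k])
    gamma = min(max(params[k + 1], _GAMMA_EPS), 1.0 - _GAMMA_EPS)
    sigma = math.sqrt(sigma2)
    lam = math.sqrt(gamma / (1.0 - gamma))
    eps = y - Z @ beta
    z = eps * (lam / sigma)
    ll = (len(y) * (math.log(2.0) - _HALF_LOG_2PI - math.log(sigma))
          - 0.5 * float(eps @ eps) / sigma2 + float(np.sum(log_ndtr(z))))
    return -ll


def loglik_frontier(y: np.ndarray, Z: np.ndarray, beta: np.ndarray,
                    sigma2: float, gamma: float) -> float:
    """Log-likelihood at an arbitrary parameter point (exposed for cross-checks)."""
    params = np.concatenate([beta, [math.log(sigma2), gamma]])
    return -_neg_loglik(params, y, Z)


def _ols(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS beta, ML variance and normal log-likelihood (the gamma = 0 null)."""
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return beta, sigma2, ll


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_frontier(y: pd.Series | np.ndarray, Z: pd.DataFrame | np.ndarray,
                 compute_se: bool = False) -> SFAFit:
    """Fit the half-normal frontier S = Z beta + v + u by maximum likelihood.

    Multi-starts L-BFGS-B from every point of a gamma grid {0.05, ..., 0.95} with
    modified-OLS beta (the OLS intercept is shifted down by the implied mean
    inefficiency sigma_u sqrt(2/pi)) and the moment-matched sigma^2.  Falls back
    to the OLS (gamma = 0) fit with ``converged=False`` when no start converges.
    """
    names = list(Z.columns) if isinstance(Z, pd.DataFrame) else None
    Zm = np.asarray(Z, float)
    ym = np.asarray(y, float)
    n, k = Zm.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} regressors, got {n}")
    if np.allclose(ym, ym[0]):
        raise DegenerateFrontierError("degenerate frontier: dependent slack has zero variance")
    beta_ols, sigma2_ols, ll_ols = _ols(ym, Zm)
    if names is None:
        names = [f"b{i}" for i in range(k)]

    best = None
    bounds = [(None, None)] * k + [(-40.0, 40.0), (_GAMMA_EPS, 1.0 - _GAMMA_EPS)]
    for g in _GAMMA_GRID:
        # moment-matched start: Var(eps) = sigma2 (1 - 2 gamma / pi)
        sigma2_0 = sigma2_ols / max(1.0 - 2.0 * g / math.pi, 0.2)
        beta0 = beta_ols.copy()
        beta0[0] -= math.sqrt(2.0 * g * sigma2_0 / math.pi)  # E[u] off the intercept
        x0 = np.concatenate([beta0, [math.log(sigma2_0), g]])
        res = minimize(_neg_loglik, x0, args=(ym, Zm), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ll = -best.fun
    converged = bool(best.success) and np.isfinite(ll)
    if not converged or ll < ll_ols - 1e-6:
        # non-convergence (or a fit worse than the least-squares null): OLS fallback
        return SFAFit(beta=pd.Series(beta_ols, index=names), sigma2=sigma2_ols,
                      gamma=0.0, loglik=ll_ols, lr_one_sided=0.0, converged=False)
    beta = best.x[:k]
    sigma2 = math.exp(best.x[k])
    gamma = float(best.x[k + 1])
    # report boundary solutions unclamped
    if gamma <= 2 * _GAMMA_EPS:
        gamma = 0.0
    elif gamma >= 1.0 - 2 * _GAMMA_EPS:
        gamma = 1.0
    fit = SFAFit(beta=pd.Series(beta, index=names), sigma2=sigma2, gamma=gamma,
                 loglik=ll, lr_one_sided=max(0.0, 2.0 * (ll - ll_ols)), converged=True)
    if compute_se:
        try:
            H = _num_hessian(lambda p: _neg_loglik(p, ym, Zm), best.x)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            fit.beta_se = pd.Series(se[:k], index=names)
            fit.sigma2_se = float(se[k] * sigma2)  # delta method off log sigma2
            fit.gamma_se = float(se[k + 1])
        except np.linalg.LinAlgError:
            pass
    return fit


def _mills_ratio(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z), stable in the deep lower tail via log_ndtr."""
    log_phi = -0.5 * z * z - _HALF_LOG_2PI
    return np.exp(log_phi - log_ndtr(z))


def decompose_residuals(fit: SFAFit, y: pd.Series | np.ndarray,
                        Z: pd.DataFrame | np.ndarray) -> NoiseDecomposition:
    """JLMS split of residuals into u_hat = E[u | eps] >= 0 and v_hat = eps - u_hat.

    For the normal/half-normal cost frontier with lambda = sigma_u/sigma_v and
    sigma_* = sigma_u sigma_v / sigma:

        u_hat_i = sigma_* [ phi(z_i)/Phi(z_i) + z_i ],   z_i = eps_i lambda / sigma.

    In the gamma -> 0 limit u_hat -> 0 (no inefficiency component).
    """
    index = y.index if isinstance(y, pd.Series) else pd.RangeIndex(len(y))
    ym = np.asarray(y, float)
    Zm = np.asarray(Z, float)
    eps = ym - Zm @ fit.beta.to_numpy()
    if fit.gamma <= _GAMMA_EPS:
        u = np.zeros_like(eps)
    else:
        g = min(fit.gamma, 1.0 - _GAMMA_EPS)
        sigma = math.sqrt(fit.sigma2)
        sigma_star = math.sqrt(g * (1.0 - g)) * sigma
        lam = math.sqrt(g / (1.0 - g))
        z = eps * lam / sigma
        u = sigma_star * (_mills_ratio(z) + z)
        u = np.clip(u, 0.0, None)
    return NoiseDecomposition(
        residuals=pd.Series(eps, index=index),
        u_hat=pd.Series(u, index=index),
        v_hat=pd.Series(eps - u, index=index),
    )


def adjust_inputs(inputs: pd.DataFrame, fits: dict[str, SFAFit],
                  decomps: dict[str, NoiseDecomposition],
                  design: pd.DataFrame) -> pd.DataFrame:
    """Fried adjustment: X_A = X + [max f - f] + [max v_hat - v_hat], per input.

    DMUs in the least favourable environment (max fitted slack f = Z beta_hat) and
    with the worst luck (max v_hat) keep their inputs; everyone else's inputs are
    raised, levelling environment and noise across DMUs.  Inputs without a fit
    (all-zero slack columns) pass through unchanged.
    """
    adjusted = inputs.copy()
    Zm = design.to_numpy(float)
    for name in inputs.columns:
        if name not in fits:
            continue
        f = Zm @ fits[name].beta.to_numpy()
        env_adj = f.max() - f
        v = decomps[name].v_hat.to_numpy()
        luck_adj = v.max() - v
        adjusted[name] = inputs[name].to_numpy() + env_adj + luck_adj
    return adjusted


def sfa_table(fits: dict[str, SFAFit], alpha_stars=((0.01, "***"), (0.05, "**"), (0.10, "*"))) -> pd.DataFrame:
    """Published-layout summary: rows = coefficients, sigma^2, gamma, one-sided LR.

    Coefficient and variance stars are two-sided Wald tests (when standard errors
    are available); LR stars use the 50:50 mixed chi-square critical values.
    """
    from scipy.stats import norm

    def star_from_p(p: float) -> str:
        for a, s in alpha_stars:
            if p <= a:
                return s
        return ""

    first = next(iter(fits.values()))
    rows = list(first.beta.index) + ["sigma2", "gamma", "LR one-sided"]
    table = pd.DataFrame(index=rows, columns=list(fits), dtype=object)
    for name, fit in fits.items():
        for coef in fit.beta.index:
            val = fit.beta[coef]
            s = ""
            if fit.beta_se is not None and fit.beta_se[coef] > 0:
                s = star_from_p(2 * norm.sf(abs(val) / fit.beta_se[coef]))
            table.loc[coef, name] = f"{val:.6g}{s}"
        s2 = star_from_p(2 * norm.sf(fit.sigma2 / fit.sigma2_se)) if fit.sigma2_se else ""
        sg = (star_from_p(2 * norm.sf(fit.gamma / fit.gamma_se))
              if fit.gamma_se and fit.gamma_se > 0 else "")
        lr_star = ""
        for a in (0.01, 0.05, 0.10):
            if fit.lr_one_sided >= MIXED_CHISQ_CRIT[a]:
                lr_star = dict(alpha_stars)[a] if a in dict(alpha_stars) else ""
                break
        table.loc["sigma2", name] = f"{fit.sigma2:.6g}{s2}"
        table.loc["gamma", name] = f"{fit.gamma:.6g}{sg}"
        table.loc["LR one-sided", name] = f"{fit.lr_one_sided:.6g}{lr_star}"
    return table
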