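"""Gaussian-copula marginal beta regression with ARMA(p,q) errors.

The model for a bounded (0,1) time series y_t with covariate rows X_t:

    y_t | X ~ Beta(mu_t, kappa)        (mean-precision shapes mu*kappa,
    logit(mu_t) = X_t' beta             (1-mu)*kappa; constant precision)

Serial dependence is induced by a Gaussian copula: the latent scores
z_t = Phi^{-1}(F(y_t; mu_t, kappa)) are jointly multivariate normal with
unit variances and the autocorrelation structure of a stationary,
invertible ARMA(p,q) process

    eps_t = sum_i psi_i eps_{t-i} + sum_j lambda_j eta_{t-j} + eta_t.

Because the margin is continuous, the likelihood is available in closed
form (no importance sampling):

    loglik = sum_t log f(y_t) + log phi_n(z; 0, R) - sum_t log phi(z_t)

where R is the ARMA correlation matrix restricted to the observed time
points at their original lags (gap-aware). The copula separates the
linear predictor from the correlation structure, so beta is read exactly
as in a GLM. Parameters are estimated by maximum likelihood; standard
errors come from the inverse observed information (numerical Hessian,
delta method back to the natural scale).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, logit, ndtri
from scipy.stats import beta as beta_dist
from scipy.stats import norm
from statsmodels.tsa.arima_process import arma_acf
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import pacf as sm_pacf

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMarginParams",
    "ArmaParams",
    "CopulaBetaFit",
    "EffectEstimate",
    "beta_mp_pdf",
    "beta_mp_cdf",
    "beta_mp_quantile",
    "arma_correlation",
    "loglik",
    "fit",
    "effect_on_response_scale",
    "residuals",
    "acf_diagnostics",
]

CLAMP_EPS_DEFAULT = 1e-6


# ---------------------------------------------------------------- margins

def _shapes(mu, kappa):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie in (0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return mu * kappa, (1.0 - mu) * kappa


def _check_open_unit(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly in (0, 1); clamp boundary values first")
    return y


def beta_mp_pdf(y, mu, kappa):
    """Beta density in the mean-precision parameterization."""
    a, b = _shapes(mu, kappa)
    return beta_dist.pdf(_check_open_unit(y), a, b)


def beta_mp_cdf(y, mu, kappa):
    a, b = _shapes(mu, kappa)
    return beta_dist.cdf(_check_open_unit(y), a, b)


def beta_mp_quantile(p, mu, kappa):
    a, b = _shapes(mu, kappa)
    return beta_dist.ppf(p, a, b)


# ------------------------------------------------------------ ARMA errors

@dataclass(frozen=True)
class BetaMarginParams:
    """Regression coefficients (logit scale, intercept included) and
    log-precision of the constant-dispersion beta margin."""

    beta: np.ndarray
    log_kappa: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))

    @property
    def kappa(self) -> float:
        return float(np.exp(self.log_kappa))

    def mu(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.beta)


@dataclass(frozen=True)
class ArmaParams:
    """AR (psi) and MA (lambda) coefficients of the latent error process."""

    psi: np.ndarray = field(default_factory=lambda: np.empty(0))
    lam: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi", np.atleast_1d(np.asarray(self.psi, float)))
        object.__setattr__(self, "lam", np.atleast_1d(np.asarray(self.lam, float)))

    @property
    def p(self) -> int:
        return len(self.psi)

    @property
    def q(self) -> int:
        return len(self.lam)

    def validate(self) -> None:
        # poly in B, highest order first; stationarity/invertibility require
        # all roots strictly outside the unit circle
        if self.p and np.any(np.abs(np.roots(np.r_[-self.psi[::-1], 1.0])) <= 1):
            raise ValueError(f"AR coefficients {self.psi} are not stationary")
        if self.q and np.any(np.abs(np.roots(np.r_[self.lam[::-1], 1.0])) <= 1):
            raise ValueError(f"MA coefficients {self.lam} are not invertible")


def arma_correlation(arma: ArmaParams, lags) -> np.ndarray:
    """Correlation matrix of a stationary ARMA process at integer time points.

    ``lags`` is either the series length n (time points 0..n-1) or an array
    of integer time positions; the latter yields the gap-aware submatrix
    R[i, j] = rho(|t_i - t_j|) used when some windows are missing.
    """
    arma.validate()
    t = np.arange(lags) if np.isscalar(lags) else np.asarray(lags, dtype=int)
    if t.size < 1:
        raise ValueError("need at least one time point")
    maxlag = int(np.abs(t[:, None] - t[None, :]).max())
    if arma.p == 0 and arma.q == 0:
        rho = np.zeros(maxlag + 1)
        rho[0] = 1.0
    else:
        rho = arma_acf(np.r_[1.0, -arma.psi], np.r_[1.0, arma.lam], lags=maxlag + 1)
    return rho[np.abs(t[:, None] - t[None, :])]


def arma11_lag1_corr(psi: float, lam: float) -> float:
    """Closed-form lag-1 autocorrelation of an ARMA(1,1) process."""
    return (1 + psi * lam) * (psi + lam) / (1 + 2 * psi * lam + lam**2)


# ------------------------------------------------------------- likelihood

def _latent_scores(y, mu, kappa) -> np.ndarray:
    z = ndtri(beta_mp_cdf(y, mu, kappa))
    if not np.all(np.isfinite(z)):
        raise ValueError(
            "non-finite latent score: response too close to 0 or 1 — clamp "
            f"y into [{CLAMP_EPS_DEFAULT}, 1-{CLAMP_EPS_DEFAULT}] before fitting"
        )
    return z


def loglik(
    margin: BetaMarginParams,
    arma: ArmaParams,
    y,
    X,
    missing_mask=None,
) -> float:
    """Exact continuous-margin copula log-likelihood.

    ``missing_mask`` marks unobserved windows (True = missing); observed
    rows keep their original time index so the ARMA correlation is
    evaluated at the true lags across gaps. With p=q=0 the copula term
    cancels and the result is the independent beta log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X row dimension must match y")
    obs = (
        np.ones(len(y), dtype=bool)
        if missing_mask is None
        else ~np.asarray(missing_mask, dtype=bool)
    )
    yo = _check_open_unit(y[obs])
    mu = margin.mu(X[obs])
    kappa = margin.kappa
    a, b = _shapes(mu, kappa)
    logf = beta_dist.logpdf(yo, a, b)
    if not np.all(np.isfinite(logf)):
        raise ValueError("non-finite beta log-density")
    if arma.p == 0 and arma.q == 0:
        return float(logf.sum())
    z = _latent_scores(yo, mu, kappa)
    R = arma_correlation(arma, np.flatnonzero(obs))
    L = linalg.cholesky(R, lower=True)
    w = linalg.solve_triangular(L, z, lower=True)
    return float(
        logf.sum()
        - 0.5 * (w @ w - z @ z)
        - np.log(np.diag(L)).sum()
    )


# ------------------------------------------------------ parameter packing

def _pacf_to_coef(r: np.ndarray) -> np.ndarray:
    """Durbin-Levinson map from partial autocorrelations in (-1,1) to a
    stationary AR coefficient vector (Monahan's transform)."""
    a = np.empty(0)
    for rk in r:
        a = np.append(a - rk * a[::-1], rk)
    return a


def _unpack(theta: np.ndarray, k: int, p: int, q: int):
    beta = theta[:k]
    margin = BetaMarginParams(beta=beta, log_kappa=float(theta[k]))
    psi = _pacf_to_coef(np.tanh(theta[k + 1 : k + 1 + p]))
    lam = -_pacf_to_coef(np.tanh(theta[k + 1 + p : k + 1 + p + q]))
    return margin, ArmaParams(psi=psi, lam=lam)


def _natural_params(theta: np.ndarray, k: int, p: int, q: int) -> np.ndarray:
    margin, arma = _unpack(theta, k, p, q)
    return np.r_[margin.beta, margin.kappa, arma.psi, arma.lam]


# -------------------------------------------------------------------- fit

@dataclass
class CopulaBetaFit:
    """Maximum-likelihood fit of the copula beta regression."""

    margin: BetaMarginParams
    arma: ArmaParams
    loglik: float
    vcov: np.ndarray | None  # natural scale: (beta..., kappa, psi..., lam...)
    param_names: list[str]
    fitted_mu: np.ndarray
    residuals: np.ndarray  # decorrelated, normal scale, observed rows only
    converged: bool
    n_used: int
    clamp_count: int
    obs_index: np.ndarray
    y: np.ndarray
    X: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.r_[self.margin.beta, self.margin.kappa, self.arma.psi, self.arma.lam]

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(len(self.param_names), np.nan)
        return np.sqrt(np.diag(self.vcov))

    @property
    def aic(self) -> float:
        return 2.0 * len(self.param_names) - 2.0 * self.loglik

    def summary(self) -> dict:
        """Fit report as a plain dict (JSON-serializable)."""
        se = self.se
        z = self.params / se
        pvals = 2.0 * norm.sf(np.abs(z))  # Wald tests
        coef = {
            name: {
                "estimate": float(est),
                "se": float(s),
                "z": float(zz),
                "p": float(pv),
            }
            for name, est, s, zz, pv in zip(self.param_names, self.params, se, z, pvals)
        }
        return {
            "coefficients": coef,
            "kappa": self.margin.kappa,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_used": self.n_used,
            "clamp_count": self.clamp_count,
            "vcov_available": self.vcov is not None,
        }


def _clamp(y: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    clamped = np.clip(y, eps, 1.0 - eps)
    n = int(np.sum(clamped != y))
    if n:
        logger.warning("clamped %d response value(s) into [%g, 1-%g]", n, eps, eps)
    return clamped, n


def _numerical_hessian(f, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with step 1e-5 * (1 + |x|) per coordinate."""
    m = len(x)
    h = 1e-5 * (1.0 + np.abs(x))
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _numerical_jacobian(f, x: np.ndarray) -> np.ndarray:
    m = len(x)
    h = 1e-6 * (1.0 + np.abs(x))
    cols = []
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        cols.append((f(x + ei) - f(x - ei)) / (2.0 * h[i]))
    return np.column_stack(cols)


def fit(
    y,
    X,
    p: int = 0,
    q: int = 0,
    *,
    missing_mask=None,
    clamp_eps: float = CLAMP_EPS_DEFAULT,
    maxiter: int = 500,
    tol: float = 1e-8,
) -> CopulaBetaFit:
    """Maximize the copula beta likelihood over (beta, log kappa, ARMA).

    ARMA parameters are optimized on an unconstrained scale (tanh of
    partial autocorrelations mapped through the Durbin-Levinson recursion),
    which enforces stationarity and invertibility. Start values: beta from
    a least-squares fit of logit(y) on X, kappa by method of moments from
    the residual variance, ARMA at zero (the independence fit is a
    consistent starting point). Responses at 0 or 1 are clamped to
    [clamp_eps, 1-clamp_eps] with a logged count. Non-convergence is
    reported via the ``converged`` flag, not an exception; a singular
    Hessian leaves ``vcov`` as None.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    obs = (
        np.isfinite(y)
        if missing_mask is None
        else (~np.asarray(missing_mask, dtype=bool)) & np.isfinite(y)
    )
    obs_index = np.flatnonzero(obs)
    n_used = len(obs_index)
    k = X.shape[1]
    n_par = k + 1 + p + q
    if n_used <= n_par:
        raise ValueError(
            f"series has {n_used} observed value(s) but the model needs more "
            f"than its {n_par} parameter(s)"
        )
    yc, clamp_count = _clamp(y[obs], clamp_eps)
    Xo = X[obs]

    # start values: logit-scale least squares + method-of-moments precision
    eta = logit(yc)
    beta0, *_ = np.linalg.lstsq(Xo, eta, rcond=None)
    mu0 = np.clip(expit(Xo @ beta0), 1e-6, 1 - 1e-6)
    resid_var = max(np.var(yc - mu0, ddof=min(k, len(yc) - 1)), 1e-10)
    kappa0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 1.0)
    theta0 = np.r_[beta0, np.log(kappa0), np.zeros(p + q)]

    yfull = np.full_like(y, 0.5)
    yfull[obs] = yc

    def nll(theta: np.ndarray) -> float:
        try:
            margin, arma = _unpack(theta, k, p, q)
            return -loglik(margin, arma, yfull, X, missing_mask=~obs)
        except (ValueError, linalg.LinAlgError, FloatingPointError):
            return 1e12

    bounds = (
        [(None, None)] * k
        + [(-10.0, 20.0)]
        + [(-6.0, 6.0)] * (p + q)
    )
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
    )
    margin, arma = _unpack(res.x, k, p, q)

    # observed information -> vcov on the natural scale (delta method)
    vcov = None
    H = _numerical_hessian(nll, res.x)
    try:
        eig = np.linalg.eigvalsh((H + H.T) / 2)
        if eig.min() <= 0 or eig.max() / eig.min() > 1e10:
            raise linalg.LinAlgError("observed information singular or indefinite")
        vcov_theta = linalg.inv(H)
        J = _numerical_jacobian(lambda t: _natural_params(t, k, p, q), res.x)
        vcov = J @ vcov_theta @ J.T
        vcov = (vcov + vcov.T) / 2.0
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        logger.warning("singular observed information: vcov unavailable")
        vcov = None

    mu_all = margin.mu(X)
    z = _latent_scores(yc, margin.mu(Xo), margin.kappa)
    R = arma_correlation(arma, obs_index)
    L = linalg.cholesky(R, lower=True)
    resid = linalg.solve_triangular(L, z, lower=True)

    names = (
        [f"beta_{i}" for i in range(k)]
        + ["kappa"]
        + [f"psi_{i+1}" for i in range(p)]
        + [f"lambda_{j+1}" for j in range(q)]
    )
    return CopulaBetaFit(
        margin=margin,
        arma=arma,
        loglik=float(-res.fun),
        vcov=vcov,
        param_names=names,
        fitted_mu=mu_all,
        residuals=resid,
        converged=bool(res.success),
        n_used=n_used,
        clamp_count=clamp_count,
        obs_index=obs_index,
        y=y,
        X=X,
    )


# ------------------------------------------------------------ effect size

@dataclass(frozen=True)
class EffectEstimate:
    """Covariate effect on the response (overlap) scale, with a CI."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    method: str


def effect_on_response_scale(
    fit_result: CopulaBetaFit,
    x_from,
    x_to,
    *,
    ci_method: str = "delta",
    level: float = 0.95,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Change in mean response between two covariate settings.

    delta = logistic(x_to' beta) - logistic(x_from' beta), with a CI by the
    delta method (default) or a parametric bootstrap of beta.
    """
    beta = fit_result.margin.beta
    x_from = np.asarray(x_from, dtype=float)
    x_to = np.asarray(x_to, dtype=float)
    mu_to = float(expit(x_to @ beta))
    mu_from = float(expit(x_from @ beta))
    delta = mu_to - mu_from
    zq = norm.ppf(0.5 + level / 2.0)
    k = len(beta)
    if fit_result.vcov is None:
        return EffectEstimate(delta, np.nan, np.nan, np.nan, ci_method)
    vbeta = fit_result.vcov[:k, :k]
    if ci_method == "delta":
        grad = mu_to * (1 - mu_to) * x_to - mu_from * (1 - mu_from) * x_from
        se = float(np.sqrt(grad @ vbeta @ grad))
        return EffectEstimate(delta, se, delta - zq * se, delta + zq * se, "delta")
    if ci_method == "bootstrap":
        rng = rng or np.random.default_rng()
        draws = rng.multivariate_normal(beta, vbeta, size=n_boot)
        deltas = expit(draws @ x_to) - expit(draws @ x_from)
        lo, hi = np.quantile(deltas, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return EffectEstimate(delta, float(deltas.std(ddof=1)), float(lo), float(hi), "bootstrap")
    raise ValueError(f"unknown ci_method {ci_method!r}")


# ------------------------------------------------------------- diagnostics

def residuals(fit_result: CopulaBetaFit) -> np.ndarray:
    """Decorrelated normal-scale residuals L^{-1} z (innovations scale).

    Under a correctly specified model these are approximately i.i.d.
    standard normal and serially uncorrelated.
    """
    return fit_result.residuals


def acf_diagnostics(res: np.ndarray, max_lag: int = 20) -> pd.DataFrame:
    """ACF/PACF table for a residual series with 95% white-noise bands."""
    res = np.asarray(res, dtype=float)
    n = len(res)
    max_lag = min(max_lag, n - 2)
    acf_vals = sm_acf(res, nlags=max_lag, fft=True)
    pacf_vals = sm_pacf(res, nlags=max_lag)
    band = 1.96 / np.sqrt(n)
    return pd.DataFrame(
        {
            "lag": np.arange(max_lag + 1),
            "acf": acf_vals,
            "pacf": pacf_vals,
            "band_low": -band,
            "band_high": band,
        }
    )
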