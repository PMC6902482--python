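import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize
from scipy.special import expit, logit, ndtri
from scipy.stats import beta as beta_dist
from scipy.stats import multivariate_normal, norm

from overlapdyn import copula as cop
from tests.conftest import simulate_copula_series


class TestBetaMargin:
    def test_mean_half_precision_two_is_uniform(self):
        y = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(cop.beta_mp_pdf(y, 0.5, 2.0), 1.0)
        assert cop.beta_mp_cdf(0.3, 0.5, 2.0) == pytest.approx(0.3)

    def test_mean_parameter_is_the_distribution_mean(self):
        mu, kappa = 0.2, 10.0
        mean, _ = integrate.quad(lambda y: y * cop.beta_mp_pdf(y, mu, kappa), 0, 1)
        assert mean == pytest.approx(mu, abs=1e-8)

    @given(
        p=st.floats(min_value=1e-4, max_value=1 - 1e-4),
        mu=st.floats(min_value=0.15, max_value=0.85),
        kappa=st.floats(min_value=4.0, max_value=200.0),
    )
    def test_cdf_of_quantile_is_identity(self, p, mu, kappa):
        y = cop.beta_mp_quantile(p, mu, kappa)
        assert cop.beta_mp_cdf(y, mu, kappa) == pytest.approx(p, abs=1e-10)

    def test_boundary_response_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            cop.beta_mp_pdf(1.0, 0.5, 5.0)


class TestArmaCorrelation:
    def test_white_noise_is_identity(self):
        R = cop.arma_correlation(cop.ArmaParams(), 5)
        np.testing.assert_array_equal(R, np.eye(5))

    def test_ar1_geometric_decay(self):
        R = cop.arma_correlation(cop.ArmaParams(psi=[0.5]), 6)
        np.testing.assert_allclose(R[0], 0.5 ** np.arange(6), rtol=1e-10)

    def test_arma11_matches_closed_form_recursion(self):
        """ACF equals rho1=(1+psi*lam)(psi+lam)/(1+2 psi lam+lam^2),
        rho_k = psi*rho_{k-1} thereafter."""
        psi, lam = 0.5, 0.3
        R = cop.arma_correlation(cop.ArmaParams(psi=[psi], lam=[lam]), 6)
        rho1 = cop.arma11_lag1_corr(psi, lam)
        expected = np.r_[1.0, rho1 * psi ** np.arange(5)]
        np.testing.assert_allclose(R[0], expected, rtol=1e-10)

    def test_arma11_matches_long_simulation(self):
        """Lag-1 autocorrelation of a million-step simulated ARMA(1,1)."""
        psi, lam = 0.5, 0.3
        rng = np.random.default_rng(12)
        eta = rng.standard_normal(1_000_000)
        from scipy.signal import lfilter

        eps = lfilter([1.0, lam], [1.0, -psi], eta)
        emp = np.corrcoef(eps[:-1], eps[1:])[0, 1]
        assert cop.arma11_lag1_corr(psi, lam) == pytest.approx(emp, abs=0.005)

    def test_gap_aware_lags(self):
        R = cop.arma_correlation(cop.ArmaParams(psi=[0.5]), np.array([0, 1, 4]))
        np.testing.assert_allclose(
            R, [[1, 0.5, 0.5**4], [0.5, 1, 0.5**3], [0.5**4, 0.5**3, 1]], rtol=1e-10
        )

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            cop.arma_correlation(cop.ArmaParams(psi=[1.01]), 5)
        with pytest.raises(ValueError, match="invertible"):
            cop.arma_correlation(cop.ArmaParams(lam=[-1.2]), 5)


class TestLoglik:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.y = rng.uniform(0.2, 0.8, 5)
        self.X = np.column_stack([np.ones(5), rng.normal(size=5)])
        self.margin = cop.BetaMarginParams(beta=[0.2, 0.5], log_kappa=np.log(10))

    def test_independence_reduces_to_beta_likelihood(self):
        mu = self.margin.mu(self.X)
        expected = beta_dist.logpdf(self.y, mu * 10, (1 - mu) * 10).sum()
        got = cop.loglik(self.margin, cop.ArmaParams(), self.y, self.X)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_observation_ignores_the_copula(self):
        arma = cop.ArmaParams(psi=[0.7], lam=[0.2])
        mu = self.margin.mu(self.X[:1]).item()
        expected = float(beta_dist.logpdf(self.y[0], mu * 10, (1 - mu) * 10))
        got = cop.loglik(self.margin, arma, self.y[:1], self.X[:1])
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("psi,lam", [(0.5, 0.3), (-0.4, 0.0), (0.0, 0.6), (0.8, -0.5)])
    def test_matches_dense_mvn_oracle_on_short_series(self, psi, lam):
        arma = cop.ArmaParams(psi=[psi], lam=[lam])
        mu = self.margin.mu(self.X)
        z = ndtri(beta_dist.cdf(self.y, mu * 10, (1 - mu) * 10))
        R = cop.arma_correlation(arma, 5)
        oracle = (
            beta_dist.logpdf(self.y, mu * 10, (1 - mu) * 10).sum()
            + multivariate_normal.logpdf(z, mean=np.zeros(5), cov=R)
            - norm.logpdf(z).sum()
        )
        got = cop.loglik(self.margin, arma, self.y, self.X)
        assert got == pytest.approx(oracle, rel=1e-10)

    def test_missing_mask_evaluates_true_lags(self):
        """Dropping a middle window must use the lag-2 correlation across
        the gap, i.e. match the dense oracle on the observed subset."""
        arma = cop.ArmaParams(psi=[0.6], lam=[0.0])
        mask = np.array([False, True, False, False, False])
        mu = self.margin.mu(self.X[~mask])
        yo = self.y[~mask]
        z = ndtri(beta_dist.cdf(yo, mu * 10, (1 - mu) * 10))
        R = cop.arma_correlation(arma, np.flatnonzero(~mask))
        oracle = (
            beta_dist.logpdf(yo, mu * 10, (1 - mu) * 10).sum()
            + multivariate_normal.logpdf(z, mean=np.zeros(4), cov=R)
            - norm.logpdf(z).sum()
        )
        got = cop.loglik(self.margin, arma, self.y, self.X, missing_mask=mask)
        assert got == pytest.approx(oracle, rel=1e-10)


class TestFit:
    def test_independence_limit_matches_direct_beta_mle(self):
        """With p=q=0 the fit must agree with a direct, separately coded
        maximization of the independent beta-regression likelihood."""
        rng = np.random.default_rng(21)
        y, X = simulate_copula_series(300, [-1.0, 1.5], 30.0, 0.0, 0.0, rng)
        ours = cop.fit(y, X, p=0, q=0)

        def neg(params):
            b, lk = params[:2], params[2]
            mu = expit(X @ b)
            return -beta_dist.logpdf(y, mu * np.exp(lk), (1 - mu) * np.exp(lk)).sum()

        direct = optimize.minimize(
            neg, np.r_[0.0, 0.0, np.log(10.0)], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(ours.margin.beta, direct.x[:2], atol=1e-4)
        assert ours.margin.kappa == pytest.approx(np.exp(direct.x[2]), abs=1e-3)

    def test_constant_series_recovers_the_constant(self):
        y = np.full(40, 0.37)
        X = np.ones((40, 1))
        result = cop.fit(y, X)
        assert float(result.fitted_mu[0]) == pytest.approx(0.37, abs=1e-6)

    def test_boundary_values_clamped_and_counted(self, caplog):
        rng = np.random.default_rng(5)
        y = rng.uniform(0.2, 0.8, 60)
        y[:2] = [0.0, 1.0]
        with caplog.at_level("WARNING"):
            result = cop.fit(y, np.ones((60, 1)))
        assert result.clamp_count == 2

    def test_arma11_recovery_within_wald_bands(self):
        """Single ARMA(1,1) fit at n=400: every parameter inside +-3 SE."""
        truth = np.array([-1.386, 2.773, 40.0, 0.5, 0.3])
        rng = np.random.default_rng(99)
        y, X = simulate_copula_series(400, truth[:2], truth[2], truth[3], truth[4], rng)
        result = cop.fit(y, X, p=1, q=1)
        assert result.converged and result.vcov is not None
        np.testing.assert_array_less(np.abs(result.params - truth), 3 * result.se)

    def test_duplicated_column_reports_unavailable_vcov(self):
        rng = np.random.default_rng(8)
        y, _ = simulate_copula_series(80, [-0.5, 0.0], 20.0, 0.0, 0.0, rng)
        X = np.ones((80, 2))  # intercept duplicated: singular information
        result = cop.fit(y, X)
        assert result.vcov is None
        assert np.isnan(result.se).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            cop.fit(np.full(3, 0.5), np.ones((3, 2)), p=1, q=1)

    def test_fitted_means_respect_logit_monotonicity(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        X = np.column_stack([np.ones(10), x])
        lo = cop.BetaMarginParams(beta=[0.0, 0.5], log_kappa=0.0).mu(X)
        hi = cop.BetaMarginParams(beta=[0.0, 1.5], log_kappa=0.0).mu(X)
        np.testing.assert_allclose(hi[:5], lo[:5])
        assert (hi[5:] > lo[5:]).all()


class TestEffectAndResiduals:
    def _fit_with(self, beta, vcov_beta):
        k = len(beta)
        vcov = np.zeros((k + 1, k + 1))
        vcov[:k, :k] = vcov_beta
        return cop.CopulaBetaFit(
            margin=cop.BetaMarginParams(beta=beta, log_kappa=np.log(20)),
            arma=cop.ArmaParams(),
            loglik=0.0, vcov=vcov,
            param_names=[f"beta_{i}" for i in range(k)] + ["kappa"],
            fitted_mu=np.empty(0), residuals=np.empty(0), converged=True,
            n_used=0, clamp_count=0, obs_index=np.empty(0, int),
            y=np.empty(0), X=np.empty((0, k)),
        )

    def test_step_effect_is_difference_of_back_transformed_means(self):
        beta = [logit(0.2), logit(0.8) - logit(0.2)]
        fit = self._fit_with(beta, 1e-4 * np.eye(2))
        eff = cop.effect_on_response_scale(fit, [1.0, 0.0], [1.0, 1.0])
        assert eff.delta == pytest.approx(0.6, rel=1e-12)
        assert eff.ci_low < 0.6 < eff.ci_high

    def test_null_and_antisymmetric_contrasts(self):
        fit = self._fit_with([0.3, 0.7], 1e-4 * np.eye(2))
        assert cop.effect_on_response_scale(fit, [1, 1], [1, 1]).delta == 0.0
        fwd = cop.effect_on_response_scale(fit, [1, 0], [1, 1]).delta
        rev = cop.effect_on_response_scale(fit, [1, 1], [1, 0]).delta
        assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_bootstrap_ci_brackets_the_delta_method(self):
        fit = self._fit_with([0.0, 1.0], 0.01 * np.eye(2))
        boot = cop.effect_on_response_scale(
            fit, [1, 0], [1, 1], ci_method="bootstrap",
            rng=np.random.default_rng(0), n_boot=4000,
        )
        delta = cop.effect_on_response_scale(fit, [1, 0], [1, 1])
        assert boot.ci_low == pytest.approx(delta.ci_low, abs=0.01)
        assert boot.ci_high == pytest.approx(delta.ci_high, abs=0.01)

    def test_residuals_standardized_under_correct_model(self):
        rng = np.random.default_rng(14)
        y, X = simulate_copula_series(500, [-1.386, 2.773], 40.0, 0.5, 0.3, rng)
        result = cop.fit(y, X, p=1, q=1)
        res = cop.residuals(result)
        assert abs(res.mean()) < 0.15
        assert abs(res.var(ddof=1) - 1.0) < 0.25

    def test_white_noise_independence_returns_latent_scores(self):
        rng = np.random.default_rng(15)
        y, X = simulate_copula_series(200, [0.0, 0.5], 15.0, 0.0, 0.0, rng)
        result = cop.fit(y, X, p=0, q=0)
        mu = result.margin.mu(X)
        z = ndtri(beta_dist.cdf(
            np.clip(y, 1e-6, 1 - 1e-6),
            mu * result.margin.kappa, (1 - mu) * result.margin.kappa,
        ))
        np.testing.assert_allclose(result.residuals, z, rtol=1e-10)

    def test_acf_table_shape_and_lag_zero(self):
        rng = np.random.default_rng(16)
        table = cop.acf_diagnostics(rng.standard_normal(300), max_lag=12)
        assert list(table["lag"]) == list(range(13))
        assert table["acf"].iloc[0] == 1.0
        assert table["pacf"].iloc[0] == 1.0
        np.testing.assert_allclose(table["band_high"], 1.96 / np.sqrt(300))
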