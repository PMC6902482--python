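import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def location_table(tmp_path):
    """Two animals, 4 weeks of bi-hourly fixes from circular Gaussians."""
    rng = np.random.default_rng(5)
    times = pd.date_range("2017-04-03", periods=4 * 84, freq="2h")
    rows = []
    for animal, (cx, cy) in {"A": (0.0, 0.0), "B": (1.3, 0.0)}.items():
        xs = rng.normal(cx, 1.0, len(times))
        ys = rng.normal(cy, 1.0, len(times))
        for t, x, y in zip(times, xs, ys):
            rows.append({"id": animal, "time": t, "x": x, "y": y})
    path = tmp_path / "locations.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def simulate_copula_series(n, beta, kappa, psi, lam, rng):
    """Independent draw from the copula beta model with a step covariate."""
    from scipy.special import expit
    from scipy.stats import beta as beta_dist, norm

    from overlapdyn.copula import ArmaParams, arma_correlation

    x = (np.arange(n) >= n // 2).astype(float)
    X = np.column_stack([np.ones(n), x])
    mu = expit(X @ np.asarray(beta, float))
    if psi == 0.0 and lam == 0.0:
        u = rng.uniform(size=n)
    else:
        R = arma_correlation(ArmaParams(psi=[psi], lam=[lam]), n)
        z = np.linalg.cholesky(R) @ rng.standard_normal(n)
        u = norm.cdf(z)
    y = beta_dist.ppf(u, mu * kappa, (1 - mu) * kappa)
    return y, X
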