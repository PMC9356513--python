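import numpy as np
import pytest

import promolag as pl


def make_series(
    T=150,
    beta=0.01,
    lam=0.0,
    rho=0.0,
    g_hol=0.0,
    a=0.1,
    b=-0.05,
    sigma_obs=0.1,
    sigma_rw=0.0,
    base=8.0,
    seed=0,
    x_kind="iid",
):
    """Small series generated straight from the model equations (the
    independent route used to validate inference against known truth)."""
    rng = np.random.default_rng(seed)
    cov = pl.simulate_covariates(T, 1, seed)
    woy = cov["week_of_year"].to_numpy(float)
    hol = cov["holiday"].to_numpy(float)
    if x_kind == "iid":
        x = np.clip(rng.normal(15.0, 6.0, T), 0.0, 60.0)
    else:
        x = np.zeros(T)
    sin = np.sin(2 * np.pi * woy / 52)
    cos = np.cos(2 * np.pi * woy / 52)
    rw = np.concatenate(([0.0], np.cumsum(rng.normal(0.0, sigma_rw, T - 1))))
    mu = (1 - rho) * base + rw
    y = np.empty(T)
    K = x[0] / (1 - lam) if lam else x[0]
    yp = base
    for t in range(T):
        if t:
            K = x[t] + lam * K
        y[t] = mu[t] + beta * K + rho * yp + g_hol * hol[t] + a * sin[t] + b * cos[t] + rng.normal(0, sigma_obs)
        yp = y[t]
    series = pl.CategorySeries(
        category="test",
        week=cov["week"].to_numpy(),
        servings=np.exp(y),
        discount_pct=x,
        display_prop=np.zeros(T),
        flyer_prop=np.zeros(T),
        regular_price=np.full(T, 50.0),
        holiday=hol.astype(int),
        temperature=cov["temperature"].to_numpy(),
        week_of_year=woy.astype(int),
    )
    truth = dict(beta=beta, lam=lam, rho=rho, g_hol=g_hol, a=a, b=b,
                 sigma_obs=sigma_obs, sigma_rw=sigma_rw, mu=mu, x=x, y=y)
    return series, truth


@pytest.fixture(scope="session")
def fast_cfg():
    return pl.SamplerConfig(n_chains=2, n_warmup=400, n_draws=250, seed=7)


@pytest.fixture(scope="session")
def small_profile():
    return pl.CategoryProfile(
        name="mini_soda",
        n_items=12,
        base_log_sales=8.0,
        beta_true=0.012,
        lambda_true=0.35,
        ar_coef_true=0.15,
        seasonal_amplitude=0.1,
        discount_event_rate=0.5,
        discount_depth_mean=28.0,
        baseline_price_cents_per_serving=60.0,
        package_volumes_ml=(355.0, 2000.0),
        obs_sd=0.1,
        intercept_rw_sd=0.01,
    )


@pytest.fixture(scope="session")
def small_sim(small_profile):
    series, truth = pl.simulate_category_series(small_profile, 150, seed=11)
    return series, truth


@pytest.fixture(scope="session")
def fitted_draws(small_sim, fast_cfg):
    series, _ = small_sim
    spec = pl.KoyckDLMSpec(covariates=("holiday",))
    return pl.fit(series, spec, fast_cfg)
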