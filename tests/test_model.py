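"""Koyck state, linear predictor, joint density, and the marginal likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

import promolag as pl
from promolag.inference import _Posterior
from promolag.model import (
    ModelParameters,
    build_design,
    default_k0,
    koyck_state,
    log_joint,
    regression_terms,
)

from conftest import make_series


def brute_force_koyck(x, lam):
    """Independent oracle: explicit truncated convolution sum."""
    T = len(x)
    out = np.zeros(T)
    for t in range(T):
        for h in range(t + 1):
            out[t] += lam**h * x[t - h]
    return out


class TestKoyckState:
    def test_pulse_decays_geometrically(self):
        k = koyck_state(np.array([10.0, 0, 0, 0]), 0.5, k0=0.0)
        assert np.allclose(k, [10, 5, 2.5, 1.25])

    def test_zero_lambda_identity(self):
        x = np.arange(6, dtype=float)
        assert np.array_equal(koyck_state(x, 0.0, k0=3.0), x)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        lam=st.floats(-0.95, 0.95),
    )
    def test_matches_brute_force_convolution(self, seed, lam):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 30, 50)
        assert np.max(np.abs(koyck_state(x, lam, 0.0) - brute_force_koyck(x, lam))) < 1e-10

    def test_nonstationary_lambda_rejected(self):
        with pytest.raises(ValueError):
            koyck_state(np.ones(3), 1.0)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 0.9])
    def test_sustained_unit_exposure_converges_to_geometric_sum(self, lam):
        beta = 0.7
        k = koyck_state(np.ones(400), lam, k0=0.0)
        assert abs(beta * k[-1] - beta / (1.0 - lam)) < 1e-6

    def test_steady_k0_policy_is_recursion_fixed_point(self):
        x = np.full(10, 4.0)
        lam = 0.6
        k = koyck_state(x, lam, default_k0(x, lam, "steady"))
        assert np.allclose(k, 4.0 / (1 - lam))


class TestLinearPredictor:
    def _series(self, T=40, seed=1):
        series, _ = make_series(T=T, seed=seed, sigma_rw=0.01, rho=0.2, lam=0.3)
        return series

    def test_all_zero_coefficients_constant(self):
        series = self._series()
        spec = pl.KoyckDLMSpec(covariates=("holiday",))
        par = ModelParameters(
            beta=0.0, lam=0.2, rho=0.0, gamma=[0.0], a=[0.0], b=[0.0],
            sigma_obs=1.0, sigma_rw=0.0, mu=np.full(40, 3.5),
        )
        eta = pl.linear_predictor(par, series, spec)
        assert np.allclose(eta, 3.5)

    def test_one_percent_per_percent_scaling(self):
        """beta=0.01 with sustained 10% discount lifts log sales by 0.1."""
        series, _ = make_series(T=30, x_kind="none")
        series.discount_pct[:] = 10.0
        spec = pl.KoyckDLMSpec(covariates=(), lambda_regime="none", include_ar1=False)
        par = ModelParameters(
            beta=0.01, lam=0.0, rho=0.0, gamma=[], a=[0.0], b=[0.0],
            sigma_obs=1.0, sigma_rw=0.0, mu=np.zeros(30),
        )
        eta = pl.linear_predictor(par, series, spec)
        assert np.allclose(eta, 0.1)

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(42)
        series = self._series(T=60, seed=5)
        spec = pl.KoyckDLMSpec(covariates=("holiday", "temperature"), n_harmonics=2)
        par = ModelParameters(
            beta=rng.normal(0, 0.02), lam=0.37, rho=rng.normal(0, 0.3),
            gamma=rng.normal(0, 0.5, 2), a=rng.normal(0, 0.3, 2), b=rng.normal(0, 0.3, 2),
            sigma_obs=0.1, sigma_rw=0.01, mu=rng.normal(8, 0.5, 60),
        )
        eta = pl.linear_predictor(par, series, spec)

        # independent naive recomputation
        d = build_design(series, spec)
        K = brute_force_koyck(d.x, par.lam) + par.lam ** np.arange(1, 61) * default_k0(d.x, par.lam, "steady")
        expect = np.empty(60)
        for t in range(60):
            v = par.mu[t] + par.beta * K[t] + par.rho * d.y_lag[t]
            v += d.Z[t, 0] * par.gamma[0] + d.Z[t, 1] * par.gamma[1]
            for m in (1, 2):
                ang = 2 * np.pi * m * series.week_of_year[t] / 52.0
                v += par.a[m - 1] * np.sin(ang) + par.b[m - 1] * np.cos(ang)
            expect[t] = v
        assert np.max(np.abs(eta - expect)) < 1e-10


class TestLogJoint:
    def _tiny(self):
        T = 3
        series = pl.CategorySeries(
            category="t", week=[1, 2, 3], servings=np.exp([8.0, 8.1, 7.9]),
            discount_pct=[10.0, 0.0, 5.0], display_prop=np.zeros(T),
            flyer_prop=np.zeros(T), regular_price=np.full(T, 50.0),
            holiday=[0, 1, 0], temperature=np.zeros(T), week_of_year=[1, 2, 3],
        )
        return series

    def test_hand_computed_value(self):
        series = self._tiny()
        spec = pl.KoyckDLMSpec(covariates=(), lambda_regime="none", include_ar1=False)
        pr = spec.priors
        par = ModelParameters(
            beta=0.01, lam=0.0, rho=0.0, gamma=[], a=[0.1], b=[-0.1],
            sigma_obs=0.2, sigma_rw=0.05, mu=np.array([8.0, 8.05, 8.02]),
        )
        y = np.log(series.servings)
        eta = np.array(
            [
                par.mu[t]
                + 0.01 * series.discount_pct[t]
                + 0.1 * np.sin(2 * np.pi * (t + 1) / 52)
                - 0.1 * np.cos(2 * np.pi * (t + 1) / 52)
                for t in range(3)
            ]
        )
        expected = norm.logpdf(y, eta, 0.2).sum()
        expected += norm.logpdf(8.0, pr.mu1_loc, pr.mu1_scale)
        expected += norm.logpdf([0.05, -0.03], 0, 0.05).sum()
        expected += norm.logpdf(0.01, pr.beta_loc, pr.beta_scale)
        expected += norm.logpdf([0.1, -0.1], 0, pr.harmonic_scale).sum()
        # half-normal priors on the two scales
        expected += norm.logpdf(0.2, 0, pr.sigma_obs_scale) + np.log(2)
        expected += norm.logpdf(0.05, 0, pr.sigma_rw_scale) + np.log(2)
        assert log_joint(par, series, spec) == pytest.approx(float(expected), abs=1e-10)

    def test_out_of_support_returns_neg_inf(self):
        series = self._tiny()
        spec = pl.KoyckDLMSpec(covariates=())
        good = dict(
            beta=0.0, lam=0.5, rho=0.0, gamma=[], a=[0.0], b=[0.0],
            sigma_obs=0.1, sigma_rw=0.01, mu=np.zeros(3),
        )
        for bad in (dict(lam=1.5), dict(sigma_obs=-0.1), dict(rho=2.0)):
            par = ModelParameters(**{**good, **bad})
            assert log_joint(par, series, spec) == -np.inf

    def test_location_equivariance_of_observation_terms(self):
        """Shifting y and mu together only moves the diffuse mu_1 prior."""
        series = self._tiny()
        spec = pl.KoyckDLMSpec(covariates=(), lambda_regime="none", include_ar1=False)
        pr = spec.priors
        par = ModelParameters(
            beta=0.0, lam=0.0, rho=0.0, gamma=[], a=[0.0], b=[0.0],
            sigma_obs=0.3, sigma_rw=0.02, mu=np.array([8.0, 8.0, 8.1]),
        )
        lj1 = log_joint(par, series, spec)
        shifted = pl.CategorySeries(
            category="t", week=series.week, servings=series.servings * np.e,
            discount_pct=series.discount_pct, display_prop=series.display_prop,
            flyer_prop=series.flyer_prop, regular_price=series.regular_price,
            holiday=series.holiday, temperature=series.temperature,
            week_of_year=series.week_of_year,
        )
        par2 = ModelParameters(
            beta=0.0, lam=0.0, rho=0.0, gamma=[], a=[0.0], b=[0.0],
            sigma_obs=0.3, sigma_rw=0.02, mu=par.mu + 1.0,
        )
        lj2 = log_joint(par2, shifted, spec)
        prior_shift = norm.logpdf(9.0, pr.mu1_loc, pr.mu1_scale) - norm.logpdf(
            8.0, pr.mu1_loc, pr.mu1_scale
        )
        assert lj2 - lj1 == pytest.approx(float(prior_shift), abs=1e-10)

    def test_degenerate_random_walk_is_static_regression(self):
        """sigma_rw fixed at 0 with constant mu: log joint equals the static
        intercept regression log-likelihood plus priors."""
        series, _ = make_series(T=25, seed=3)
        spec = pl.KoyckDLMSpec(
            covariates=(), lambda_regime="none", include_ar1=False, fixed={"sigma_rw": 0.0}
        )
        pr = spec.priors
        par = ModelParameters(
            beta=0.005, lam=0.0, rho=0.0, gamma=[], a=[0.1], b=[-0.05],
            sigma_obs=0.1, sigma_rw=0.0, mu=np.full(25, 8.0),
        )
        d = build_design(series, spec)
        eta = 8.0 + regression_terms(par, d, spec)
        expected = norm.logpdf(d.y, eta, 0.1).sum()
        expected += norm.logpdf(8.0, pr.mu1_loc, pr.mu1_scale)
        expected += norm.logpdf(0.005, pr.beta_loc, pr.beta_scale)
        expected += norm.logpdf([0.1, -0.05], 0, pr.harmonic_scale).sum()
        expected += norm.logpdf(0.1, 0, pr.sigma_obs_scale) + np.log(2)
        assert log_joint(par, series, spec) == pytest.approx(float(expected), abs=1e-10)
        # non-constant path has zero probability under the degenerate walk
        par_bad = ModelParameters(
            beta=0.005, lam=0.0, rho=0.0, gamma=[], a=[0.1], b=[-0.05],
            sigma_obs=0.1, sigma_rw=0.0, mu=np.linspace(8.0, 8.1, 25),
        )
        assert log_joint(par_bad, series, spec) == -np.inf


class TestMarginalLikelihood:
    def test_kalman_matches_direct_multivariate_normal(self):
        """The Kalman-marginalized likelihood equals the closed-form Gaussian
        integral over the intercept path (independent dense-matrix route)."""
        series, _ = make_series(T=6, seed=9, rho=0.2, lam=0.3, sigma_rw=0.05)
        spec = pl.KoyckDLMSpec(covariates=(), lambda_regime="monotonic", include_ar1=True)
        post = _Posterior(series, spec)
        theta = np.array([[0.01, 0.3, 0.2, 0.05, -0.02, np.log(0.1), np.log(0.05)]])
        ll = (post(theta) - post.log_prior(theta))[0]

        d = post.design
        par = ModelParameters(
            beta=0.01, lam=0.3, rho=0.2, gamma=[], a=[0.05], b=[-0.02],
            sigma_obs=0.1, sigma_rw=0.05, mu=np.zeros(6),
        )
        f = regression_terms(par, d, spec)
        tt = np.arange(6)
        cov = (
            spec.priors.mu1_scale**2 * np.ones((6, 6))
            + 0.05**2 * np.minimum.outer(tt, tt)
            + 0.1**2 * np.eye(6)
        )
        direct = multivariate_normal.logpdf(d.y, mean=f + spec.priors.mu1_loc, cov=cov)
        assert ll == pytest.approx(float(direct), abs=1e-8)

    def test_missing_weeks_skip_likelihood(self):
        series, _ = make_series(T=20, seed=4)
        spec = pl.KoyckDLMSpec(covariates=(), lambda_regime="none", include_ar1=False)
        post_full = _Posterior(series, spec)
        series.missing[7] = True
        post_miss = _Posterior(series, spec)
        theta = np.array([[0.0, 0.0, 0.0, np.log(0.1), np.log(0.01)]])
        assert post_miss(theta)[0] != post_full(theta)[0]


class TestSpecYaml:
    def test_round_trip_lossless(self, tmp_path):
        spec = pl.KoyckDLMSpec(
            covariates=("holiday", "display_prop"), lambda_regime="dip",
            n_harmonics=2, include_ar1=False, k0_policy="zero",
            fixed={"sigma_obs": 0.1},
        )
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        assert pl.KoyckDLMSpec.from_yaml(p) == spec

    def test_validation(self):
        with pytest.raises(ValueError, match="covariates"):
            pl.KoyckDLMSpec(covariates=("nope",))
        with pytest.raises(ValueError, match="regime"):
            pl.KoyckDLMSpec(lambda_regime="wiggly")
        with pytest.raises(ValueError, match="harmonics"):
            pl.KoyckDLMSpec(n_harmonics=0)
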