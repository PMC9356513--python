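"""Synthetic transaction generator: determinism, degenerate structure,
round-trips, and store-scale sanity."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import promolag as pl
from promolag.synthetic import HOLIDAY_WEEKS


def _flat_profile(**kw):
    base = dict(
        name="flat",
        n_items=5,
        base_log_sales=8.0,
        beta_true=0.0,
        lambda_true=0.0,
        ar_coef_true=0.0,
        trend_per_week=0.0,
        seasonal_amplitude=0.0,
        discount_event_rate=0.3,
        discount_depth_mean=25.0,
        obs_sd=0.1,
        intercept_rw_sd=0.0,
        gamma_holiday=0.0,
        gamma_temperature=0.0,
    )
    base.update(kw)
    return pl.CategoryProfile(**base)


class TestCovariates:
    def test_holiday_weeks_per_year_in_calendar_bounds(self):
        cov = pl.simulate_covariates(52, 1, seed=0)
        assert 8 <= cov["holiday"].sum() <= 14

    def test_temperature_annual_mean_is_montreal_like(self):
        cov = pl.simulate_covariates(52, 1, seed=4)
        assert 0.0 <= cov["temperature"].mean() <= 15.0

    def test_same_seed_identical_table(self):
        a = pl.simulate_covariates(120, 5, seed=9)
        b = pl.simulate_covariates(120, 5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_week_of_year_wraps_from_start(self):
        cov = pl.simulate_covariates(60, 50, seed=0)
        assert list(cov["week_of_year"][:4]) == [50, 51, 52, 1]


class TestCategorySimulation:
    def test_all_structure_off_gives_white_noise_around_base(self):
        prof = _flat_profile(trend_per_week=0.002)
        series, truth = pl.simulate_category_series(prof, 200, seed=2)
        resid = truth.y - (8.0 + 0.002 * np.arange(200))
        assert abs(resid.mean()) < 0.03
        assert abs(np.std(resid) - 0.1) < 0.02
        # residual lag-1 autocorrelation consistent with white noise
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(r1) < 2.5 / np.sqrt(200)

    def test_zero_discount_rate_gives_zero_exposure(self):
        prof = _flat_profile(discount_event_rate=0.0)
        series, truth = pl.simulate_category_series(prof, 80, seed=3)
        assert np.all(series.discount_pct == 0.0)
        assert np.all(truth.x == 0.0)

    def test_net_price_never_exceeds_baseline(self, small_profile):
        cfg = pl.ScenarioConfig(n_weeks=60, categories=[small_profile], seed=8)
        tab = pl.simulate_transactions(cfg)
        assert (tab["net_price_cents"] <= tab["baseline_price_cents"] + 1e-12).all()

    def test_nonfinite_parameters_abort_with_diagnostic(self):
        prof = _flat_profile(base_log_sales=1e308, beta_true=1e8, discount_event_rate=1.0)
        with pytest.raises(RuntimeError, match="non-finite"):
            pl.simulate_category_series(prof, 30, seed=0)

    def test_ground_truth_matches_profile(self, small_sim, small_profile):
        _, truth = small_sim
        assert truth.beta == small_profile.beta_true
        assert truth.lam == small_profile.lambda_true
        assert truth.rho == small_profile.ar_coef_true
        assert len(truth.mu) == 150


class TestDeterminism:
    def test_scenario_byte_identical_csv(self, small_profile):
        cfg = pl.ScenarioConfig(n_weeks=40, categories=[small_profile], seed=21)
        a = pl.simulate_scenario(cfg)
        b = pl.simulate_scenario(pl.ScenarioConfig(n_weeks=40, categories=[small_profile], seed=21))
        assert a.transactions.to_csv(index=False) == b.transactions.to_csv(index=False)
        assert a.covariates.to_csv(index=False) == b.covariates.to_csv(index=False)

    def test_different_seed_differs(self, small_profile):
        a = pl.simulate_scenario(pl.ScenarioConfig(n_weeks=40, categories=[small_profile], seed=1))
        b = pl.simulate_scenario(pl.ScenarioConfig(n_weeks=40, categories=[small_profile], seed=2))
        assert not a.transactions["units_sold"].equals(b.transactions["units_sold"])


class TestRoundTrip:
    def test_aggregation_recovers_generator_series_exactly(self, small_profile):
        cfg = pl.ScenarioConfig(
            n_weeks=80, categories=[small_profile], seed=5, round_units=False
        )
        sim = pl.simulate_scenario(cfg)
        agg = pl.aggregate_category(sim.transactions, small_profile.name, sim.covariates)
        gen = sim.series[small_profile.name]
        assert np.max(np.abs(agg.discount_pct - gen.discount_pct)) == 0.0
        assert np.max(np.abs(agg.servings / gen.servings - 1.0)) <= 1e-6
        # the recursion input x equals the aggregated exposure up to float error
        assert np.allclose(sim.truths[small_profile.name].x, agg.discount_pct, atol=1e-9)

    def test_single_item_no_noise_item_equals_category(self):
        prof = _flat_profile(
            n_items=1, share_noise_sd=0.0, beta_true=0.005, discount_event_rate=0.4,
            package_volumes_ml=(500.0,),
        )
        cfg = pl.ScenarioConfig(n_weeks=50, categories=[prof], seed=13, round_units=False)
        sim = pl.simulate_scenario(cfg)
        tab = sim.transactions
        ser = sim.series["flat"]
        item_servings = tab["units_sold"].to_numpy() * 500.0 / 240.0
        assert np.allclose(item_servings, ser.servings)
        d = pl.item_discount_pct(
            tab["net_price_cents"].to_numpy(),
            tab["baseline_price_cents"].to_numpy(),
            tab["volume_ml"].to_numpy(),
        )
        assert np.allclose(d, ser.discount_pct)


class TestStoreScale:
    """The default store profiles reproduce published weekly magnitudes.

    Single-realization medians wander with the random-walk intercept, so
    sanity bands (25% around the store's reported values) are checked on
    the geometric mean over a few seeds; exact values for one fixed seed
    are frozen as a regression guard on the generator."""

    def test_soda_frozen_regression(self):
        prof = [p for p in pl.default_profiles() if p.name == "soda"][0]
        series, _ = pl.simulate_category_series(prof, 311, seed=3)
        assert float(np.median(series.servings)) == pytest.approx(19606.35416666666, rel=1e-9)
        assert float(np.median(series.discount_pct)) == pytest.approx(17.892246109234026, rel=1e-9)

    @pytest.mark.parametrize(
        "name,med_servings,med_disc",
        [
            ("soda", 19062.5, 17.3),
            ("fruit_drinks", 14303.5, 9.8),
            ("sports_energy", 1178.4, 8.2),
            ("coffee_tea", 1397.0, 13.8),
            ("yogurt", 1226.7, 4.4),
        ],
    )
    def test_scale_sanity_against_store_magnitudes(self, name, med_servings, med_disc):
        prof = [p for p in pl.default_profiles() if p.name == name][0]
        serv, disc = [], []
        for seed in range(4):
            series, _ = pl.simulate_category_series(prof, 311, seed=seed)
            serv.append(np.median(series.servings))
            disc.append(np.median(series.discount_pct))
        geo_serv = float(np.exp(np.mean(np.log(serv))))
        assert abs(geo_serv - med_servings) / med_servings < 0.25
        assert abs(np.mean(disc) - med_disc) / med_disc < 0.25

    def test_default_scenario_item_counts(self):
        counts = {p.name: p.n_items for p in pl.default_profiles()}
        assert counts == {
            "soda": 109,
            "fruit_drinks": 152,
            "sports_energy": 36,
            "coffee_tea": 22,
            "yogurt": 29,
        }


class TestScenarioConfig:
    def test_yaml_round_trip(self, small_profile, tmp_path):
        cfg = pl.ScenarioConfig(n_weeks=60, categories=[small_profile], seed=3)
        p = tmp_path / "scenario.yaml"
        cfg.to_yaml(p)
        back = pl.ScenarioConfig.from_yaml(p)
        assert back.n_weeks == 60 and back.seed == 3
        assert back.categories[0] == small_profile

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            pl.ScenarioConfig(n_weeks=1)
        with pytest.raises(ValueError):
            pl.CategoryProfile(
                name="bad", n_items=0, base_log_sales=8.0, beta_true=0.0, lambda_true=0.0
            ).validate()
        with pytest.raises(ValueError):
            pl.CategoryProfile(
                name="bad", n_items=2, base_log_sales=8.0, beta_true=0.0,
                lambda_true=0.0, discount_depth_mean=120.0,
            ).validate()
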