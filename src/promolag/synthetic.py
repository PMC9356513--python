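"""Synthetic weekly retail transaction generator.

Emulates six years (311 weeks) of item-level beverage transactions for five
sugar-sweetened-beverage categories in a single store, with known ground
truth, so every downstream stage (aggregation, model fitting, selection,
attribution) is testable without proprietary scanner data.

Category log sales are generated by the same Koyck distributed-lag dynamic
linear model the package fits: a random-walk time-varying intercept (with a
deterministic trend folded in), a geometric distributed lag of the category
percent discount, an AR(1) term on lagged log sales, annual harmonics, and
holiday/temperature effects. Item-level structure below the category:

* persistent item market shares drawn once from a Dirichlet distribution
  (concentration controls how dominated the category is by a few items),
  with small weekly multiplicative share noise;
* price discounts arrive as geometric-duration promotion spells (real
  discounts persist across flyer cycles rather than flipping weekly), each
  spell with its own depth; start rates and depths are calibrated so
  category mean discounts match observed store magnitudes;
* display/flyer flags drawn conditionally on discount status;
* category servings allocated to items by the weekly share weights, then
  converted to units at each item's package volume (rounded by default).

The emitted category series is computed by running the emitted item table
through :func:`promolag.aggregation.aggregate_category`, so re-aggregation
reproduces it by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import SERVING_ML, aggregate_category
from .series import CategorySeries

#: weeks-of-year containing national/provincial statutory holidays
#: (synthetic stand-in for a Quebec retail calendar; ~11 weeks/year)
HOLIDAY_WEEKS = (1, 8, 14, 21, 26, 27, 32, 36, 41, 51, 52)


@dataclass
class CategoryProfile:
    """Ground-truth generating parameters for one beverage category."""

    name: str
    n_items: int
    base_log_sales: float
    beta_true: float
    lambda_true: float
    ar_coef_true: float = 0.15
    trend_per_week: float = 0.0
    seasonal_amplitude: float = 0.1
    market_share_concentration: float = 0.8
    discount_event_rate: float = 0.3      # mean spell start probability per off week
    discount_depth_mean: float = 25.0     # percent, per spell
    discount_depth_sd: float = 8.0
    spell_mean_weeks: float = 2.0         # geometric mean promotion duration
    # chain flyer cycles synchronize promotions across a category's items:
    # a log-AR(1) multiplier on the weekly spell start rate. Its stationary
    # SD controls the week-to-week spread of category percent discounting
    # (set per category to match observed IQRs).
    promo_cycle_sd: float = 0.8
    promo_cycle_ar: float = 0.5
    display_given_discount: float = 0.6
    flyer_given_discount: float = 0.5
    display_base_rate: float = 0.02
    flyer_base_rate: float = 0.01
    baseline_price_cents_per_serving: float = 60.0
    package_volumes_ml: tuple = (355.0, 2000.0)
    obs_sd: float = 0.1
    intercept_rw_sd: float = 0.012
    share_noise_sd: float = 0.1
    gamma_holiday: float = 0.05
    gamma_temperature: float = 0.0        # per SD of weekly temperature

    def __post_init__(self) -> None:
        self.package_volumes_ml = tuple(self.package_volumes_ml)

    def validate(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if not (0.0 <= self.discount_depth_mean < 100.0):
            raise ValueError("discount depth must be in [0, 100)")
        for p in (
            self.discount_event_rate,
            self.display_given_discount,
            self.flyer_given_discount,
            self.display_base_rate,
            self.flyer_base_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if not (-1.0 < self.lambda_true < 1.0):
            raise ValueError("lambda_true must be in (-1, 1)")
        if not (-1.0 < self.ar_coef_true < 1.0):
            raise ValueError("ar_coef_true must be in (-1, 1)")
        if self.baseline_price_cents_per_serving <= 0:
            raise ValueError("baseline price must be positive")
        if self.obs_sd <= 0 or self.intercept_rw_sd < 0:
            raise ValueError("obs_sd must be > 0 and intercept_rw_sd >= 0")
        if self.spell_mean_weeks < 1.0:
            raise ValueError("spell_mean_weeks must be >= 1")
        if not self.package_volumes_ml or min(self.package_volumes_ml) <= 0:
            raise ValueError("package volumes must be positive")


def default_profiles() -> list[CategoryProfile]:
    """Five store-scale category profiles (soda, fruit drinks, sports &
    energy drinks, sweetened coffees & teas, drinkable yogurt).

    Item counts, weekly serving magnitudes, mean percent discounts and
    their interquartile spread, and baseline per-serving prices match the
    published summary statistics of the Montreal store the analysis was
    developed on (the spell rates, depths and flyer-cycle SDs were jointly
    calibrated to the discounting mean and IQR per category); effect sizes
    follow the fitted pattern (immediate effect lowest for soda and highest
    for yogurt; carryover negligible everywhere except sports & energy
    drinks).
    """
    return [
        CategoryProfile(
            name="soda", n_items=109, base_log_sales=9.82, beta_true=0.005,
            lambda_true=0.05, ar_coef_true=0.15, trend_per_week=-0.0005,
            seasonal_amplitude=0.06, discount_event_rate=0.95,
            discount_depth_mean=34.5, promo_cycle_sd=1.1,
            display_given_discount=0.7,
            flyer_given_discount=0.6, baseline_price_cents_per_serving=56.8,
            package_volumes_ml=(355.0, 2000.0), obs_sd=0.10,
        ),
        CategoryProfile(
            name="fruit_drinks", n_items=152, base_log_sales=9.54, beta_true=0.006,
            lambda_true=0.05, ar_coef_true=0.15, trend_per_week=-0.0004,
            seasonal_amplitude=0.08, discount_event_rate=0.43,
            discount_depth_mean=32.0, promo_cycle_sd=1.3,
            baseline_price_cents_per_serving=48.2,
            package_volumes_ml=(200.0, 1000.0, 2000.0), obs_sd=0.10,
        ),
        CategoryProfile(
            name="sports_energy", n_items=36, base_log_sales=6.88, beta_true=0.012,
            lambda_true=0.35, ar_coef_true=0.2, trend_per_week=0.0,
            seasonal_amplitude=0.25, discount_event_rate=0.50,
            discount_depth_mean=23.0, promo_cycle_sd=0.9,
            baseline_price_cents_per_serving=130.1,
            package_volumes_ml=(591.0, 710.0), obs_sd=0.12,
            intercept_rw_sd=0.015, gamma_temperature=0.08,
        ),
        CategoryProfile(
            name="coffee_tea", n_items=22, base_log_sales=7.11, beta_true=0.010,
            lambda_true=0.05, ar_coef_true=0.15, trend_per_week=-0.0004,
            seasonal_amplitude=0.10, discount_event_rate=0.65,
            discount_depth_mean=34.5, promo_cycle_sd=1.3,
            baseline_price_cents_per_serving=56.1,
            package_volumes_ml=(473.0, 1000.0), obs_sd=0.12,
            intercept_rw_sd=0.015,
        ),
        CategoryProfile(
            name="yogurt", n_items=29, base_log_sales=7.05, beta_true=0.015,
            lambda_true=0.05, ar_coef_true=0.10, trend_per_week=-0.0003,
            seasonal_amplitude=0.06, discount_event_rate=0.23,
            discount_depth_mean=23.0, promo_cycle_sd=1.3,
            display_given_discount=0.5,
            flyer_given_discount=0.4, baseline_price_cents_per_serving=161.6,
            package_volumes_ml=(93.0, 200.0), obs_sd=0.12,
            intercept_rw_sd=0.015,
        ),
    ]


@dataclass
class ScenarioConfig:
    """A full simulated-store scenario."""

    n_weeks: int = 311
    categories: list = field(default_factory=default_profiles)
    seed: int = 0
    start_week_of_year: int = 1
    round_units: bool = True

    def __post_init__(self) -> None:
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        if not (1 <= self.start_week_of_year <= 52):
            raise ValueError("start_week_of_year must be in 1..52")
        self.categories = [
            c if isinstance(c, CategoryProfile) else CategoryProfile(**c)
            for c in self.categories
        ]
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("duplicate category names")
        for c in self.categories:
            c.validate()

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["categories"] = [asdict(c) for c in self.categories]
        for c in d["categories"]:
            c["package_volumes_ml"] = list(c["package_volumes_ml"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "ScenarioConfig":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        d = yaml.safe_load(text)
        if d.get("categories") in (None, "default"):
            d.pop("categories", None)
        return cls(**d)


@dataclass
class GroundTruth:
    """The generating parameters and realized latent states of one category."""

    category: str
    beta: float
    lam: float
    rho: float
    gamma: dict
    a: float
    b: float
    sigma_obs: float
    sigma_rw: float
    mu: np.ndarray          # realized intercept path (trend + random walk)
    x: np.ndarray           # category percent discount used in the recursion
    y: np.ndarray           # realized log sales
    shares: np.ndarray      # persistent item market shares

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("mu", "x", "y", "shares"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SimulationResult:
    transactions: pd.DataFrame
    covariates: pd.DataFrame
    series: dict
    truths: dict


# ------------------------------------------------------------------ covariates
def simulate_covariates(
    n_weeks: int, start_week_of_year: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Weekly holiday indicator and mean daytime temperature.

    The holiday calendar is a fixed synthetic stand-in (11 weeks/year);
    temperature follows a Montreal-like annual sinusoid (mean ~8 degC,
    winter ~-9, summer ~25) plus noise. Same seed, same table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    week = np.arange(1, n_weeks + 1)
    woy = ((start_week_of_year - 1 + week - 1) % 52) + 1
    holiday = np.isin(woy, HOLIDAY_WEEKS).astype(np.int64)
    temperature = (
        8.0
        - 17.0 * np.cos(2.0 * np.pi * (woy - 2) / 52.0)
        + rng.normal(0.0, 2.0, n_weeks)
    )
    return pd.DataFrame(
        {"week": week, "week_of_year": woy, "holiday": holiday, "temperature": temperature}
    )


# ------------------------------------------------------------------- core sim
def _simulate_category(
    profile: CategoryProfile,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    round_units: bool = True,
):
    profile.validate()
    T = len(covariates)
    n = profile.n_items

    shares = rng.dirichlet(np.full(n, profile.market_share_concentration))
    volumes = rng.choice(np.asarray(profile.package_volumes_ml, dtype=float), size=n)
    base_ps = profile.baseline_price_cents_per_serving * rng.lognormal(0.0, 0.15, n)
    unit_base = base_ps * volumes / SERVING_ML

    # category-wide flyer cycle: log-AR(1) multiplier on the start rate
    s_cyc = profile.promo_cycle_sd
    phi = profile.promo_cycle_ar
    z = np.empty(T)
    innov_sd = s_cyc * math.sqrt(1.0 - phi**2) if s_cyc > 0 else 0.0
    z[0] = rng.normal(0.0, s_cyc) if s_cyc > 0 else 0.0
    for t in range(1, T):
        z[t] = phi * z[t - 1] + (rng.normal(0.0, innov_sd) if s_cyc > 0 else 0.0)
    start_rate = np.clip(
        profile.discount_event_rate * np.exp(z - 0.5 * s_cyc**2), 0.0, 0.95
    )

    # promotion spells: geometric duration, one depth per spell
    p_cont = 1.0 - 1.0 / profile.spell_mean_weeks
    on = np.zeros(n, dtype=bool)
    depth = np.zeros(n)
    d = np.zeros((n, T))
    for t in range(T):
        u_start = rng.random(n)
        u_cont = rng.random(n)
        new_depth = np.clip(
            rng.normal(profile.discount_depth_mean, profile.discount_depth_sd, n), 1.0, 90.0
        )
        start = (~on) & (u_start < start_rate[t])
        keep = on & (u_cont < p_cont)
        depth = np.where(start, new_depth, depth)
        on = start | keep
        d[:, t] = np.where(on, depth, 0.0)

    p_disp = np.where(d > 0, profile.display_given_discount, profile.display_base_rate)
    p_fly = np.where(d > 0, profile.flyer_given_discount, profile.flyer_base_rate)
    display = (rng.random((n, T)) < p_disp).astype(np.int64)
    flyer = (rng.random((n, T)) < p_fly).astype(np.int64)

    # weekly serving-share weights: persistent shares x multiplicative noise
    if profile.share_noise_sd > 0:
        noise = rng.lognormal(0.0, profile.share_noise_sd, (n, T))
    else:
        noise = np.ones((n, T))
    w_raw = shares[:, None] * noise
    w = w_raw / w_raw.sum(axis=0)

    x = (w * d).sum(axis=0)

    # category log sales via the Koyck DLM recursion
    temp = covariates["temperature"].to_numpy(dtype=float)
    t_sd = temp.std() or 1.0
    tz = (temp - temp.mean()) / t_sd
    hol = covariates["holiday"].to_numpy(dtype=float)
    woy = covariates["week_of_year"].to_numpy(dtype=float)
    seas = profile.seasonal_amplitude * np.sin(2.0 * np.pi * woy / 52.0)

    lam = profile.lambda_true
    rho = profile.ar_coef_true
    beta = profile.beta_true
    rw = np.concatenate(([0.0], np.cumsum(rng.normal(0.0, profile.intercept_rw_sd, T - 1))))
    mu = (1.0 - rho) * (profile.base_log_sales + profile.trend_per_week * np.arange(T)) + rw
    eps = rng.normal(0.0, profile.obs_sd, T)

    y = np.empty(T)
    K = x[0] / (1.0 - lam)  # steady-state warm start, as the model's default
    y_prev = profile.base_log_sales
    for t in range(T):
        if t > 0:
            K = x[t] + lam * K
        y[t] = (
            mu[t]
            + beta * K
            + rho * y_prev
            + profile.gamma_holiday * hol[t]
            + profile.gamma_temperature * tz[t]
            + seas[t]
            + eps[t]
        )
        y_prev = y[t]
    if not np.all(np.isfinite(y)):
        bad = int(np.argwhere(~np.isfinite(y))[0][0])
        raise RuntimeError(
            f"non-finite simulated log sales for {profile.name!r} at week {bad + 1}; "
            "check profile parameters"
        )

    # allocate category servings to items and convert to units
    with np.errstate(over="ignore"):
        total = np.exp(y)
    if not np.all(np.isfinite(total)):
        bad = int(np.argwhere(~np.isfinite(total))[0][0])
        raise RuntimeError(
            f"non-finite simulated servings for {profile.name!r} at week {bad + 1}; "
            "check profile parameters"
        )
    item_serv = w * total[None, :]
    units = item_serv * SERVING_ML / volumes[:, None]
    if round_units:
        units = np.rint(units)

    item_ids = np.array([f"{profile.name}_item_{i:03d}" for i in range(n)])
    weeks = covariates["week"].to_numpy(dtype=np.int64)
    net = unit_base[:, None] * (1.0 - d / 100.0)
    table = pd.DataFrame(
        {
            "item_id": np.repeat(item_ids, T),
            "category": profile.name,
            "week": np.tile(weeks, n),
            "units_sold": units.ravel(),
            "volume_ml": np.repeat(volumes, T),
            "net_price_cents": net.ravel(),
            "baseline_price_cents": np.repeat(unit_base, T),
            "display": display.ravel(),
            "flyer": flyer.ravel(),
        }
    )

    truth = GroundTruth(
        category=profile.name,
        beta=beta,
        lam=lam,
        rho=rho,
        gamma={"holiday": profile.gamma_holiday, "temperature": profile.gamma_temperature},
        a=profile.seasonal_amplitude,
        b=0.0,
        sigma_obs=profile.obs_sd,
        sigma_rw=profile.intercept_rw_sd,
        mu=mu,
        x=x,
        y=y,
        shares=shares,
    )
    series = aggregate_category(table, profile.name, covariates)
    return table, series, truth


def simulate_category_series(
    profile: CategoryProfile, n_weeks: int = 311, seed: int = 0
) -> tuple[CategorySeries, GroundTruth]:
    """Simulate one category's weekly series and return its ground truth.

    Covariates are simulated from the same seed; the returned series is the
    aggregation of the underlying item-level table (see module docstring).
    """
    cov = simulate_covariates(n_weeks, 1, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    _, series, truth = _simulate_category(profile, cov, rng)
    return series, truth


def simulate_scenario(config: ScenarioConfig) -> SimulationResult:
    """Simulate every category of a scenario; returns transactions,
    covariates, per-category series, and per-category ground truths."""
    cov = simulate_covariates(config.n_weeks, config.start_week_of_year, config.seed)
    tables = []
    series: dict = {}
    truths: dict = {}
    for i, profile in enumerate(config.categories):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 100 + i]))
        tab, ser, tru = _simulate_category(profile, cov, rng, round_units=config.round_units)
        tables.append(tab)
        series[profile.name] = ser
        truths[profile.name] = tru
    transactions = pd.concat(tables, ignore_index=True)
    return SimulationResult(transactions=transactions, covariates=cov, series=series, truths=truths)


def simulate_transactions(config: ScenarioConfig) -> pd.DataFrame:
    """The item-level weekly transaction table for a scenario."""
    return simulate_scenario(config).transactions
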