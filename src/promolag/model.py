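"""Koyck distributed-lag dynamic linear model.

Weekly log sales ``y_t`` of one beverage category follow a Gaussian
state-space regression::

    y_t   = mu_t + beta * K_t + rho * y_{t-1} + gamma' z_t
            + sum_m [ a_m sin(2 pi m w_t / 52) + b_m cos(2 pi m w_t / 52) ]
            + eps_t,            eps_t ~ N(0, sigma_obs^2)
    mu_t  = mu_{t-1} + w_t,     w_t   ~ N(0, sigma_rw^2)
    K_t   = x_t + lambda * K_{t-1}

where ``x_t`` is the category percent discount, so ``beta * K_t`` equals the
Koyck geometric distributed lag ``sum_{h>=0} beta lambda^h x_{t-h}`` (up to
the state initialization). ``beta`` is the immediate effect of a 1%
discount on log sales (x100: approximate percent change of sales) and
``lambda`` the geometric decay rate of the carryover. The random-walk
intercept ``mu_t`` absorbs local level shifts and slow trends.

The lag coefficient is constrained to one of three regimes:

* ``monotonic`` — ``0 < lambda < 1``, a monotonically decaying carryover;
* ``dip`` — ``-1 < lambda < 0``, an oscillating "post-promotion dip";
* ``none`` — ``lambda = 0``, the immediate-effect-only baseline used for
  attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import lfilter

from .series import CategorySeries

#: covariates the model knows about, in canonical order
COVARIATES = ("display_prop", "flyer_prop", "regular_price", "holiday", "temperature")
#: continuous covariates centered and scaled to unit SD before fitting;
#: the 0/1 holiday indicator enters raw, and the discount exposure is never
#: rescaled so beta keeps its per-1%-discount interpretation
SCALED_COVARIATES = frozenset({"display_prop", "flyer_prop", "regular_price", "temperature"})

LAMBDA_INTERVALS = {"monotonic": (0.0, 1.0), "dip": (-1.0, 0.0), "none": (0.0, 0.0)}

PERIOD_WEEKS = 52.0


@dataclass
class PriorSet:
    """Priors over the structural parameters.

    All densities are proper. ``beta`` and the covariate/harmonic
    coefficients get Normal(loc, scale) priors (covariates are standardized
    first, so unit scales are weakly informative); ``lambda`` and ``rho``
    are uniform on their constrained intervals; the two error scales get
    half-Normal priors; the initial intercept ``mu_1`` is diffuse Normal.
    """

    beta_loc: float = 0.0
    beta_scale: float = 1.0
    gamma_scale: float = 1.0
    harmonic_scale: float = 1.0
    sigma_obs_scale: float = 1.0
    sigma_rw_scale: float = 0.1
    mu1_loc: float = 0.0
    mu1_scale: float = 100.0


@dataclass
class KoyckDLMSpec:
    """Model structure: covariate subset, lag regime, harmonics, priors.

    ``fixed`` maps scalar parameter names (e.g. ``"sigma_rw"``, ``"rho"``,
    ``"sigma_obs"``) to constants, removing them from sampling; fixed
    parameters contribute no prior term.
    """

    covariates: tuple[str, ...] = ()
    lambda_regime: str = "monotonic"
    n_harmonics: int = 1
    include_ar1: bool = True
    priors: PriorSet = field(default_factory=PriorSet)
    k0_policy: str = "steady"
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}; choose from {COVARIATES}")
        if self.lambda_regime not in LAMBDA_INTERVALS:
            raise ValueError(f"lambda_regime must be one of {sorted(LAMBDA_INTERVALS)}")
        if self.k0_policy not in ("steady", "zero"):
            raise ValueError("k0_policy must be 'steady' or 'zero'")
        if self.n_harmonics < 1:
            # seasonal harmonics are structural: always included, never selected over
            raise ValueError("n_harmonics must be >= 1")
        if isinstance(self.priors, dict):
            self.priors = PriorSet(**self.priors)

    # ------------------------------------------------------------- layout
    def param_names(self) -> list[str]:
        """All scalar parameter names in canonical order (fixed or free)."""
        names = ["beta"]
        if self.lambda_regime != "none":
            names.append("lam")
        if self.include_ar1:
            names.append("rho")
        names += [f"gamma_{c}" for c in self.covariates]
        for m in range(1, self.n_harmonics + 1):
            names += [f"a_{m}", f"b_{m}"]
        names += ["sigma_obs", "sigma_rw"]
        return names

    def free_names(self) -> list[str]:
        return [n for n in self.param_names() if n not in self.fixed]

    # ---------------------------------------------------------------- I/O
    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "KoyckDLMSpec":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        d = yaml.safe_load(text)
        return cls(**d)


@dataclass
class ModelParameters:
    """One full parameter configuration, including the latent intercept path."""

    beta: float
    lam: float
    rho: float
    gamma: np.ndarray
    a: np.ndarray
    b: np.ndarray
    sigma_obs: float
    sigma_rw: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)


# ---------------------------------------------------------------- Koyck state
def koyck_state(x: np.ndarray, lam: float, k0: float = 0.0) -> np.ndarray:
    """Recursive Koyck transfer state ``K_t = x_t + lam * K_{t-1}``.

    ``beta * K_t`` equals the geometric distributed lag
    ``sum_{h=0}^{t-1} beta lam^h x_{t-h}`` plus the initialization remainder
    ``beta lam^t k0``.
    """
    if abs(lam) >= 1.0:
        raise ValueError("|lambda| must be < 1 (stationary lag)")
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        return x.copy()
    # IIR filter 1/(1 - lam B) with initial condition lam * k0
    k, _ = lfilter([1.0], [1.0, -lam], x, zi=np.array([lam * k0]))
    return k


def default_k0(x: np.ndarray, lam: float, policy: str = "steady") -> float:
    """Initial lag state. ``steady`` warm-starts at the fixed point of the
    recursion under sustained exposure ``x_1`` (``K_0 = x_1 / (1 - lam)``);
    ``zero`` assumes no pre-sample exposure. The difference decays like
    ``lam^t`` and is negligible at T=311."""
    if policy == "steady":
        return float(x[0]) / (1.0 - lam)
    if policy == "zero":
        return 0.0
    raise ValueError(f"unknown k0 policy {policy!r}")


# ------------------------------------------------------------- design arrays
@dataclass
class DesignArrays:
    """Numeric arrays the likelihood consumes, precomputed from a series."""

    y: np.ndarray            # observed log sales (NaN on missing weeks)
    missing: np.ndarray      # bool mask of skipped weeks
    x: np.ndarray            # percent discount exposure (never rescaled)
    y_lag: np.ndarray        # y_{t-1}; week 1 conditions on its own value
    Z: np.ndarray            # (T, k) standardized covariates
    H: np.ndarray            # (T, 2m) harmonic columns sin/cos interleaved
    covariate_names: tuple[str, ...]
    z_means: np.ndarray
    z_scales: np.ndarray


def build_design(series: CategorySeries, spec: KoyckDLMSpec) -> DesignArrays:
    """Assemble the numeric design from a series under a model spec.

    Continuous covariates are centered and scaled to unit SD (coefficients
    are then per-SD effects); the holiday indicator stays 0/1. The AR(1)
    term uses observed lagged log sales, with week 1 conditioning on its own
    value (conditional-likelihood treatment of the initial week).
    """
    y = series.log_sales
    T = len(series)
    missing = series.missing.copy()
    x = series.discount_pct.astype(float).copy()

    y_filled = np.where(np.isnan(y), np.nanmean(y) if np.any(~np.isnan(y)) else 0.0, y)
    y_lag = np.empty(T)
    y_lag[0] = y_filled[0]
    y_lag[1:] = y_filled[:-1]

    k = len(spec.covariates)
    Z = np.zeros((T, k))
    means = np.zeros(k)
    scales = np.ones(k)
    for j, name in enumerate(spec.covariates):
        col = getattr(series, name).astype(float)
        if name in SCALED_COVARIATES:
            means[j] = col.mean()
            sd = col.std()
            scales[j] = sd if sd > 0 else 1.0
            Z[:, j] = (col - means[j]) / scales[j]
        else:
            Z[:, j] = col

    w = series.week_of_year.astype(float)
    H = np.empty((T, 2 * spec.n_harmonics))
    for m in range(1, spec.n_harmonics + 1):
        ang = 2.0 * np.pi * m * w / PERIOD_WEEKS
        H[:, 2 * (m - 1)] = np.sin(ang)
        H[:, 2 * (m - 1) + 1] = np.cos(ang)

    return DesignArrays(
        y=y,
        missing=missing,
        x=x,
        y_lag=y_lag,
        Z=Z,
        H=H,
        covariate_names=spec.covariates,
        z_means=means,
        z_scales=scales,
    )


def regression_terms(
    params: ModelParameters, design: DesignArrays, spec: KoyckDLMSpec
) -> np.ndarray:
    """The non-intercept part of the linear predictor,
    ``f_t = beta K_t + rho y_{t-1} + gamma' z_t + harmonics``."""
    lam = params.lam if spec.lambda_regime != "none" else 0.0
    k0 = default_k0(design.x, lam, spec.k0_policy)
    K = koyck_state(design.x, lam, k0)
    f = params.beta * K
    if spec.include_ar1:
        f = f + params.rho * design.y_lag
    if design.Z.shape[1]:
        f = f + design.Z @ params.gamma
    ab = np.empty(2 * spec.n_harmonics)
    ab[0::2] = params.a
    ab[1::2] = params.b
    f = f + design.H @ ab
    return f


def linear_predictor(
    params: ModelParameters, series: CategorySeries, spec: KoyckDLMSpec
) -> np.ndarray:
    """Model-scale fitted mean of log sales, ``eta_t = mu_t + f_t``."""
    design = build_design(series, spec)
    if len(params.mu) != len(series):
        raise ValueError("mu path length must equal series length")
    return params.mu + regression_terms(params, design, spec)


# ------------------------------------------------------------------ log joint
def _normal_logpdf(v: float, loc: float, scale: float) -> float:
    return -0.5 * math.log(2.0 * math.pi * scale * scale) - 0.5 * ((v - loc) / scale) ** 2


def _halfnormal_logpdf(v: float, scale: float) -> float:
    if v < 0:
        return -np.inf
    return (
        0.5 * math.log(2.0 / math.pi)
        - math.log(scale)
        - 0.5 * (v / scale) ** 2
    )


def log_prior(params: ModelParameters, spec: KoyckDLMSpec) -> float:
    """Log prior density over the free structural parameters (not mu)."""
    pr = spec.priors
    lo, hi = LAMBDA_INTERVALS[spec.lambda_regime]
    lp = 0.0
    if "beta" not in spec.fixed:
        lp += _normal_logpdf(params.beta, pr.beta_loc, pr.beta_scale)
    if spec.lambda_regime != "none" and "lam" not in spec.fixed:
        if not (lo < params.lam < hi):
            return -np.inf
        lp += -math.log(hi - lo)
    if spec.include_ar1 and "rho" not in spec.fixed:
        if not (-1.0 < params.rho < 1.0):
            return -np.inf
        lp += -math.log(2.0)
    for g in params.gamma[: len(spec.covariates)]:
        lp += _normal_logpdf(float(g), 0.0, pr.gamma_scale)
    for v in list(params.a) + list(params.b):
        lp += _normal_logpdf(float(v), 0.0, pr.harmonic_scale)
    if "sigma_obs" not in spec.fixed:
        lp += _halfnormal_logpdf(params.sigma_obs, pr.sigma_obs_scale)
    if "sigma_rw" not in spec.fixed:
        lp += _halfnormal_logpdf(params.sigma_rw, pr.sigma_rw_scale)
    return lp


def log_joint(
    params: ModelParameters, series: CategorySeries, spec: KoyckDLMSpec
) -> float:
    """Joint log density of (parameters, latent path, data).

    Sum of the observation log-likelihood (missing weeks skipped), the
    random-walk state density including the diffuse Normal prior on
    ``mu_1``, and the parameter priors. Out-of-support parameters return
    ``-inf`` rather than raising.
    """
    pr = spec.priors
    lam = params.lam if spec.lambda_regime != "none" else 0.0
    lo, hi = LAMBDA_INTERVALS[spec.lambda_regime]
    if spec.lambda_regime != "none" and not (lo <= lam <= hi):
        return -np.inf
    if params.sigma_obs <= 0 or params.sigma_rw < 0:
        return -np.inf
    if spec.include_ar1 and not (-1.0 < params.rho < 1.0):
        return -np.inf

    design = build_design(series, spec)
    T = len(series)
    if len(params.mu) != T:
        raise ValueError("mu path length must equal series length")
    eta = params.mu + regression_terms(params, design, spec)

    ll = 0.0
    for t in range(T):
        if design.missing[t]:
            continue
        ll += _normal_logpdf(float(design.y[t]), float(eta[t]), params.sigma_obs)

    # state: mu_1 diffuse, mu_t | mu_{t-1} ~ N(mu_{t-1}, sigma_rw^2)
    ll += _normal_logpdf(float(params.mu[0]), pr.mu1_loc, pr.mu1_scale)
    dmu = np.diff(params.mu)
    if params.sigma_rw == 0.0:
        # degenerate random walk: point mass at a constant path
        if np.any(dmu != 0.0):
            return -np.inf
    else:
        for d in dmu:
            ll += _normal_logpdf(float(d), 0.0, params.sigma_rw)

    lp = log_prior(params, spec)
    if not np.isfinite(lp):
        return -np.inf
    return ll + lp
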