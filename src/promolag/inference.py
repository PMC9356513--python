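"""Posterior sampling and summaries for the Koyck DLM.

The random-walk intercept path is integrated out analytically (scalar
Kalman filter), so MCMC runs only over the handful of structural
parameters; the intercept path is then re-sampled exactly per retained
draw by forward-filter backward-sampling. Sampling uses the emcee
affine-invariant ensemble with the error scales proposed on the log scale
(with the Jacobian correction), which is the documented reparameterization
that keeps mixing healthy when ``sigma_rw`` is small.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import emcee
import numpy as np
import pandas as pd
import yaml

from . import _engine
from .model import DesignArrays, KoyckDLMSpec, build_design
from .series import CategorySeries

logger = logging.getLogger(__name__)

_LOG_SCALE_PARAMS = ("sigma_obs", "sigma_rw")


@dataclass
class SamplerConfig:
    """MCMC settings.

    ``n_chains * n_draws`` retained draws are produced in total.
    ``n_warmup`` is the number of discarded ensemble adaptation steps.
    ``target_accept`` is kept for config compatibility with
    gradient-based engines and is inert for the ensemble sampler.
    ``n_walkers`` defaults to ``max(2 * ndim + 2, 16)``.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    n_walkers: int | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Flattened posterior draws plus per-draw latent paths and fitted values.

    ``params`` maps every canonical parameter name (fixed ones included, as
    constant columns) to a vector of length ``n``; ``mu``, ``eta`` and
    ``log_lik`` are ``(n, T)`` matrices — the sampled intercept paths, the
    fitted log-sales means, and the pointwise one-step-ahead predictive log
    densities (intercept path marginalized) used by WAIC; missing weeks are
    zero columns.
    """

    params: dict
    mu: np.ndarray
    eta: np.ndarray
    log_lik: np.ndarray
    diagnostics: dict
    spec: KoyckDLMSpec
    config: SamplerConfig
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros(self.mu.shape[1], dtype=bool)

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.params.values())))

    @property
    def n_weeks(self) -> int:
        return self.mu.shape[1]

    def param_matrix(self) -> np.ndarray:
        """Full-layout parameter matrix for the numerical kernels."""
        return _full_matrix_from_params(self.params, self.spec, self.n_draws)

    # ----------------------------------------------------------- persistence
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.params).to_csv(out / "params.csv", index=False)
        np.savez_compressed(
            out / "arrays.npz",
            mu=self.mu,
            eta=self.eta,
            log_lik=self.log_lik,
            missing=self.missing,
        )
        meta = {
            "spec": yaml.safe_load(self.spec.to_yaml()),
            "config": vars(self.config).copy(),
            "diagnostics": _plain(self.diagnostics),
        }
        (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, out_dir: str | Path) -> "PosteriorDraws":
        out = Path(out_dir)
        meta = yaml.safe_load((out / "meta.yaml").read_text())
        arrays = np.load(out / "arrays.npz")
        params = {c: v.to_numpy() for c, v in pd.read_csv(out / "params.csv").items()}
        return cls(
            params=params,
            mu=arrays["mu"],
            eta=arrays["eta"],
            log_lik=arrays["log_lik"],
            diagnostics=meta["diagnostics"],
            spec=KoyckDLMSpec(**meta["spec"]),
            config=SamplerConfig(**meta["config"]),
            missing=arrays["missing"].astype(bool),
        )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ----------------------------------------------------------------- layout
def _full_layout(spec: KoyckDLMSpec) -> list[str]:
    k = len(spec.covariates)
    names = ["beta", "lam", "rho"]
    names += [f"gamma_{c}" for c in spec.covariates]
    for m in range(1, spec.n_harmonics + 1):
        names += [f"a_{m}", f"b_{m}"]
    names += ["sigma_obs", "sigma_rw"]
    assert len(names) == 3 + k + 2 * spec.n_harmonics + 2
    return names


def _full_matrix_from_params(params: dict, spec: KoyckDLMSpec, n: int) -> np.ndarray:
    layout = _full_layout(spec)
    P = np.zeros((n, len(layout)))
    for j, name in enumerate(layout):
        if name in params:
            P[:, j] = params[name]
        elif name in spec.fixed:
            P[:, j] = spec.fixed[name]
        # else stays 0 (lam under regime 'none', rho without AR)
    return P


class _Posterior:
    """Vectorized marginal log-posterior over the free parameters."""

    def __init__(self, series: CategorySeries, spec: KoyckDLMSpec):
        self.spec = spec
        self.design = build_design(series, spec)
        self.free = spec.free_names()
        self.layout = _full_layout(spec)
        self.k = len(spec.covariates)
        self.m = spec.n_harmonics
        self.k0_steady = spec.k0_policy == "steady"
        pr = spec.priors
        self.m0 = pr.mu1_loc
        self.C0 = pr.mu1_scale**2
        from .model import LAMBDA_INTERVALS

        self.lam_interval = LAMBDA_INTERVALS[spec.lambda_regime]
        y = self.design.y
        self._y_safe = np.where(np.isnan(y), 0.0, y)

    @property
    def ndim(self) -> int:
        return len(self.free)

    # free coordinate <-> natural value (sigmas sampled on log scale)
    def to_natural(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        out = {}
        for j, name in enumerate(self.free):
            col = theta[:, j]
            out[name] = np.exp(col) if name in _LOG_SCALE_PARAMS else col.copy()
        return out

    def full_matrix(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        nat = self.to_natural(theta)
        return _full_matrix_from_params(nat, self.spec, theta.shape[0])

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized prior in the *sampled* coordinates (incl. Jacobians)."""
        theta = np.atleast_2d(theta)
        pr = self.spec.priors
        lp = np.zeros(theta.shape[0])
        lo, hi = self.lam_interval
        for j, name in enumerate(self.free):
            col = theta[:, j]
            if name == "beta":
                lp += _norm_logpdf(col, pr.beta_loc, pr.beta_scale)
            elif name == "lam":
                bad = (col <= lo) | (col >= hi)
                lp = np.where(bad, -np.inf, lp - math.log(hi - lo))
            elif name == "rho":
                bad = (col <= -1.0) | (col >= 1.0)
                lp = np.where(bad, -np.inf, lp - math.log(2.0))
            elif name.startswith("gamma_"):
                lp += _norm_logpdf(col, 0.0, pr.gamma_scale)
            elif name.startswith(("a_", "b_")):
                lp += _norm_logpdf(col, 0.0, pr.harmonic_scale)
            elif name == "sigma_obs":
                sig = np.exp(col)
                lp += _halfnorm_logpdf(sig, pr.sigma_obs_scale) + col
            elif name == "sigma_rw":
                sig = np.exp(col)
                lp += _halfnorm_logpdf(sig, pr.sigma_rw_scale) + col
        return lp

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.log_prior(theta)
        ok = np.isfinite(lp)
        out = np.full(theta.shape[0], -np.inf)
        if np.any(ok):
            P = self.full_matrix(theta[ok])
            d = self.design
            ll = _engine.marginal_loglik_batch(
                P,
                self._y_safe,
                d.missing,
                d.x,
                d.y_lag,
                d.Z,
                d.H,
                self.k,
                self.m,
                self.k0_steady,
                self.m0,
                self.C0,
            )
            out[ok] = lp[ok] + ll
        return out


def _norm_logpdf(v, loc, scale):
    return -0.5 * np.log(2.0 * np.pi * scale**2) - 0.5 * ((v - loc) / scale) ** 2


def _halfnorm_logpdf(v, scale):
    out = 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (v / scale) ** 2
    return np.where(v < 0, -np.inf, out)


def _initial_walkers(post: _Posterior, nwalkers: int, rng: np.random.RandomState) -> np.ndarray:
    """Weakly dispersed starting ensemble in the sampled coordinates."""
    y = post.design.y
    sd_y = float(np.nanstd(y)) or 1.0
    lo, hi = post.lam_interval
    p0 = np.empty((nwalkers, post.ndim))
    for j, name in enumerate(post.free):
        if name == "beta":
            p0[:, j] = rng.normal(0.0, 0.01, nwalkers)
        elif name == "lam":
            width = hi - lo
            p0[:, j] = rng.uniform(lo + 0.2 * width, hi - 0.2 * width, nwalkers)
        elif name == "rho":
            p0[:, j] = rng.uniform(-0.2, 0.5, nwalkers)
        elif name.startswith(("gamma_", "a_", "b_")):
            p0[:, j] = rng.normal(0.0, 0.05, nwalkers)
        elif name == "sigma_obs":
            p0[:, j] = np.log(0.5 * sd_y) + rng.normal(0.0, 0.3, nwalkers)
        elif name == "sigma_rw":
            p0[:, j] = np.log(0.02) + rng.normal(0.0, 0.3, nwalkers)
    return p0


def fit(series: CategorySeries, spec: KoyckDLMSpec, cfg: SamplerConfig) -> PosteriorDraws:
    """Draw posterior samples of the model parameters given one series.

    Runs the ensemble sampler on the Kalman-marginalized posterior, then
    re-samples the latent intercept path per retained draw (FFBS) and
    stores fitted trajectories and the pointwise log-likelihood matrix.
    A diagnostics warning (never an error) is raised when the maximum
    split-R-hat exceeds 1.01. Identical (series, spec, cfg) reproduce
    identical draws.
    """
    post = _Posterior(series, spec)
    ndim = post.ndim
    if ndim == 0:
        raise ValueError("model has no free parameters to sample")
    nwalkers = cfg.n_walkers or max(2 * ndim + 2, 16)
    nwalkers = int(nwalkers + (nwalkers % 2))

    n_total = cfg.n_chains * cfg.n_draws
    keep_steps = max(1, math.ceil(n_total / nwalkers))

    rs = np.random.RandomState(cfg.seed % (2**32))
    p0 = _initial_walkers(post, nwalkers, rs)
    state = emcee.State(p0, random_state=rs.get_state())

    # differential-evolution moves mix much faster than the default stretch
    # move on the correlated (beta, lambda, rho) posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, post, vectorize=True, moves=moves)
    sampler.run_mcmc(state, cfg.n_warmup + keep_steps, progress=False)

    chain = sampler.get_chain(discard=cfg.n_warmup)  # (steps, walkers, ndim)
    if not np.all(np.isfinite(chain)):
        raise RuntimeError("sampler produced non-finite coordinates")

    # diagnostics: walkers act as chains for split-R-hat / ESS
    diag: dict = {"divergences": 0, "accept_fraction": float(np.mean(sampler.acceptance_fraction))}
    rhat = {}
    ess = {}
    posterior_dict = {}
    for j, name in enumerate(post.free):
        arr = chain[:, :, j].T  # (chain, draw)
        arr_nat = np.exp(arr) if name in _LOG_SCALE_PARAMS else arr
        posterior_dict[name] = arr_nat
    if chain.shape[0] >= 4:
        idata = az.convert_to_dataset(posterior_dict)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(idata)
            e = az.ess(idata)
        rhat = {name: float(r[name].values) for name in post.free}
        ess = {name: float(e[name].values) for name in post.free}
    diag["rhat"] = rhat
    diag["ess"] = ess
    max_rhat = max(rhat.values()) if rhat else float("nan")
    if rhat and max_rhat > 1.01:
        warnings.warn(
            f"max split-R-hat {max_rhat:.3f} > 1.01; consider longer warmup", RuntimeWarning
        )

    flat = chain.reshape(-1, ndim)[:n_total]
    nat = post.to_natural(flat)
    params = dict(nat)
    # expose fixed parameters as constant columns for downstream summaries
    for name, val in spec.fixed.items():
        params.setdefault(name, np.full(n_total, float(val)))
    if spec.lambda_regime == "none":
        params.setdefault("lam", np.zeros(n_total))

    P = _full_matrix_from_params(params, spec, n_total)
    d = post.design
    z = rs.standard_normal((n_total, len(series)))
    mu = _engine.ffbs_batch(
        P, post._y_safe, d.missing, d.x, d.y_lag, d.Z, d.H,
        post.k, post.m, post.k0_steady, post.m0, post.C0, z,
    )
    f = _engine.regression_batch(
        P, d.x, d.y_lag, d.Z, d.H, post.k, post.m, post.k0_steady
    )
    eta = mu + f
    # pointwise log-likelihoods for WAIC use the marginal (intercept path
    # integrated out) one-step predictive decomposition; the conditional
    # form rewards models that soak residual structure into the random walk
    log_lik = _engine.marginal_pointwise_batch(
        P, post._y_safe, d.missing, d.x, d.y_lag, d.Z, d.H,
        post.k, post.m, post.k0_steady, post.m0, post.C0,
    )

    return PosteriorDraws(
        params=params,
        mu=mu,
        eta=eta,
        log_lik=log_lik,
        diagnostics=diag,
        spec=spec,
        config=cfg,
        missing=d.missing.copy(),
    )


# -------------------------------------------------------------- summaries
@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, median and central 95% interval."""

    table: pd.DataFrame

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def summarize(draws: PosteriorDraws, params: list[str] | None = None) -> PosteriorSummary:
    """Posterior mean/median/95% CrI per parameter.

    Quantiles use linear interpolation of the empirical quantile function
    (numpy's default rule). When ``beta`` is summarized, a ``beta_pct`` row
    (x100) is added: the approximate percent change of non-log sales per 1%
    discount.
    """
    available = sorted(draws.params)
    if params is None:
        params = list(draws.params)
    unknown = [p for p in params if p not in draws.params]
    if unknown:
        raise KeyError(f"unknown parameters {unknown}; available: {available}")
    rows = {}
    for name in params:
        v = np.asarray(draws.params[name], dtype=float)
        rows[name] = _row(v)
        if name == "beta":
            rows["beta_pct"] = _row(100.0 * v)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PosteriorSummary(table=table)


def _row(v: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(v)),
        "median": float(np.quantile(v, 0.5)),
        "q2.5": float(np.quantile(v, 0.025)),
        "q97.5": float(np.quantile(v, 0.975)),
    }


@dataclass
class ResidualAcf:
    """Autocorrelations of posterior-mean residuals with a white-noise band."""

    acf: np.ndarray
    band: float
    degenerate: bool = False


def residual_acf(draws: PosteriorDraws, series: CategorySeries, max_lag: int = 10) -> ResidualAcf:
    """ACF of ``y_t - E[eta_t]`` up to ``max_lag``, with the ±2/sqrt(T) band.

    A constant residual vector has no defined autocorrelation; it is
    flagged and zeros are returned (with a warning) rather than NaNs.
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    ok = ~draws.missing
    resid = series.log_sales[ok] - draws.eta.mean(axis=0)[ok]
    n = len(resid)
    band = 2.0 / math.sqrt(n)
    if np.allclose(resid, resid[0]):
        warnings.warn("constant residual vector; autocorrelation undefined", RuntimeWarning)
        out = np.zeros(max_lag + 1)
        return ResidualAcf(acf=out, band=band, degenerate=True)
    vals = sm_acf(resid, nlags=max_lag, fft=True)
    return ResidualAcf(acf=vals, band=band)
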