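"""Model comparison: WAIC, covariate-subset selection, lag-regime sensitivity.

WAIC here is the variance-based (p_waic) form on the deviance scale::

    lppd   = sum_t log mean_s exp(ll_st)
    p_waic = sum_t var_s(ll_st)
    WAIC   = -2 (lppd - p_waic)

computed from the pointwise observation log-likelihood matrix stored with
every posterior fit. Lower WAIC indicates better expected predictive fit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorDraws, SamplerConfig, fit
from .model import KoyckDLMSpec
from .series import CategorySeries

logger = logging.getLogger(__name__)


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-week deviance-scale contributions
    mc_se: float

    def __post_init__(self) -> None:
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def waic(draws: PosteriorDraws) -> WaicResult:
    """WAIC from the stored (draws x weeks) pointwise log-likelihoods.

    Missing weeks contribute nothing. Raises on any non-finite entry,
    naming the offending (draw, week).
    """
    ll = draws.log_lik
    if hasattr(draws, "missing") and draws.missing is not None and np.any(draws.missing):
        ll = ll[:, ~draws.missing]
    bad = ~np.isfinite(ll)
    if np.any(bad):
        s, t = np.argwhere(bad)[0]
        raise ValueError(f"non-finite log-likelihood at draw {s}, week index {t}")
    S, T = ll.shape
    lppd_t = logsumexp(ll, axis=0) - np.log(S)
    p_t = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(T)
    pointwise = -2.0 * (lppd_t - p_t)
    lppd = float(lppd_t.sum())
    p_waic = float(p_t.sum())
    mc_se = float(np.sqrt(T * pointwise.var(ddof=1))) if T > 1 else 0.0
    return WaicResult(
        waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic, pointwise=pointwise, mc_se=mc_se
    )


def waic_diff_se(a: WaicResult, b: WaicResult) -> float:
    """Monte-Carlo SE of the paired WAIC difference (pointwise)."""
    if len(a.pointwise) != len(b.pointwise):
        raise ValueError("pointwise vectors differ in length")
    d = a.pointwise - b.pointwise
    T = len(d)
    return float(np.sqrt(T * d.var(ddof=1))) if T > 1 else 0.0


@dataclass
class SelectionReport:
    """Ranked WAIC table over candidate covariate subsets and the chosen spec."""

    table: pd.DataFrame
    chosen: KoyckDLMSpec
    fits: dict
    failures: dict


def select_covariates(
    series: CategorySeries,
    base_spec: KoyckDLMSpec,
    candidates: list[str],
    cfg: SamplerConfig,
) -> SelectionReport:
    """Exhaustive WAIC-guided search over all subsets of the candidates.

    Seasonal harmonics, the discounting terms, and the AR(1) term are
    structural and present in every candidate model; only the listed
    covariates are selected over. All fits share the same seed. Ties within
    one Monte-Carlo SE of the best WAIC are broken toward the smaller model
    (then lexicographically, so the ranking is independent of candidate
    ordering). Fits that fail are recorded and excluded from the ranking.
    """
    candidates = sorted(set(candidates))
    rows = []
    fits: dict = {}
    failures: dict = {}
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            spec = replace(base_spec, covariates=tuple(combo))
            key = ",".join(combo) if combo else "(none)"
            try:
                d = fit(series, spec, cfg)
                w = waic(d)
            except Exception as exc:  # recorded, not raised: one bad fit must not kill the search
                logger.warning("fit failed for subset %s: %s", key, exc)
                failures[key] = str(exc)
                continue
            fits[key] = d
            rows.append(
                {
                    "subset": key,
                    "n_covariates": len(combo),
                    "waic": w.waic,
                    "lppd": w.lppd,
                    "p_waic": w.p_waic,
                    "mc_se": w.mc_se,
                    "_combo": combo,
                    "_waic_obj": w,
                }
            )
    if not rows:
        raise RuntimeError("every candidate fit failed")
    table = pd.DataFrame(rows).sort_values(["waic", "n_covariates", "subset"]).reset_index(drop=True)

    best = table.iloc[0]
    chosen_row = best
    for _, row in table.iterrows():
        se = waic_diff_se(row["_waic_obj"], best["_waic_obj"])
        if row["waic"] - best["waic"] <= se and row["n_covariates"] < chosen_row["n_covariates"]:
            chosen_row = row
    chosen = replace(base_spec, covariates=tuple(chosen_row["_combo"]))
    table = table.drop(columns=["_combo", "_waic_obj"])
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return SelectionReport(table=table, chosen=chosen, fits=fits, failures=failures)


@dataclass
class LambdaSensitivity:
    """WAIC comparison between the monotonic-decay and post-promotion-dip
    constraints on the lag coefficient."""

    waic_monotonic: WaicResult
    waic_dip: WaicResult
    preferred: str
    fits: dict


def lambda_sensitivity(
    series: CategorySeries, spec: KoyckDLMSpec, cfg: SamplerConfig
) -> LambdaSensitivity:
    """Fit both lag-coefficient regimes and compare their WAIC.

    The primary specification constrains ``0 < lambda < 1`` (monotonic
    decay); the alternative allows ``-1 < lambda < 0`` (post-promotion
    dip). The regime with lower WAIC is preferred.
    """
    if spec.lambda_regime != "monotonic":
        raise ValueError("sensitivity analysis starts from the monotonic regime")
    fits = {}
    results = {}
    for regime in ("monotonic", "dip"):
        s = replace(spec, lambda_regime=regime)
        d = fit(series, s, cfg)
        fits[regime] = d
        results[regime] = waic(d)
    preferred = "monotonic" if results["monotonic"].waic <= results["dip"].waic else "dip"
    return LambdaSensitivity(
        waic_monotonic=results["monotonic"],
        waic_dip=results["dip"],
        preferred=preferred,
        fits=fits,
    )
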