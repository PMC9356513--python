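"""Headline outputs: impulse responses and excess-sales attribution.

The impulse response traces the Koyck lag profile ``100 * beta * lambda^h``
per posterior draw. The attribution compares, draw by draw, the
exponentiated fitted sales under three nested configurations of the same
parameter vector:

* full model (immediate + lagged discounting),
* ``lambda := 0`` with the Koyck state recomputed (immediate effect only),
* ``beta := 0`` (no discounting effect at all),

and sums the differences over the study weeks. Both counterfactual arms
condition on the observed lagged sales in the AR term (one-step-ahead
fitted values), so the contrast isolates the discounting channel; a fully
dynamic propagation through the AR term is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .inference import PosteriorDraws, _row
from .model import KoyckDLMSpec, build_design
from .series import CategorySeries


@dataclass
class ImpulseResponse:
    """Per-lag posterior summary of the lag profile on the percent scale."""

    lags: np.ndarray
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "mean": self.mean,
                "median": self.median,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )


def impulse_response(draws: PosteriorDraws, H: int = 10) -> ImpulseResponse:
    """Posterior impulse response ``100 * beta * lambda^h`` for ``h = 0..H``.

    Lag 0 is the immediate effect (percent change of sales per 1%
    discount); under the monotonic regime the median curve is
    non-increasing in ``h``.
    """
    beta = np.asarray(draws.params["beta"], dtype=float)
    lam = np.asarray(draws.params.get("lam", np.zeros_like(beta)), dtype=float)
    lags = np.arange(H + 1)
    curves = 100.0 * beta[:, None] * lam[:, None] ** lags[None, :]
    return ImpulseResponse(
        lags=lags,
        mean=curves.mean(axis=0),
        median=np.quantile(curves, 0.5, axis=0),
        lo95=np.quantile(curves, 0.025, axis=0),
        hi95=np.quantile(curves, 0.975, axis=0),
    )


@dataclass
class AttributionResult:
    """Posterior attribution of excess servings to discounting.

    ``excess_lag``: servings attributable to the lagged (carryover) effect
    alone; ``total_discount``: servings attributable to immediate plus
    lagged discounting; ``ratio_pct``: their ratio x100 on the
    posterior-mean scale. ``summary`` holds mean/median/95% CrI rows for
    both quantities; ``per_draw`` the underlying draw-level sums.
    """

    summary: pd.DataFrame
    ratio_pct: float
    per_draw: pd.DataFrame


def excess_sales(
    draws: PosteriorDraws,
    series: CategorySeries,
    spec: KoyckDLMSpec | None = None,
    dynamic_ar: bool = False,
) -> AttributionResult:
    """Posterior excess servings due to the lagged effect and total discounting.

    Per draw ``s`` with parameters ``theta_s`` and sampled intercept path:
    ``fitted_lag = exp(eta(theta_s))``; ``fitted_nolag`` recomputes the
    Koyck state with ``lambda := 0`` (never just zeroing the stale state);
    ``fitted_nodisc`` sets ``beta := 0``. Excess-lag and total-discount
    servings are the week sums of the respective differences.

    With ``dynamic_ar=True`` the counterfactual arms propagate their own
    fitted log sales through the AR(1) term instead of conditioning on the
    observed series; totals then compound and differ from the one-step-ahead
    default.
    """
    spec = spec or draws.spec
    design = build_design(series, spec)
    P = draws.param_matrix()
    beta = P[:, 0]
    lam = P[:, 1]
    ok = ~design.missing

    K = _engine.koyck_batch(design.x, lam, spec.k0_policy == "steady")
    eta_lag = draws.eta
    if dynamic_ar and spec.include_ar1:
        eta_nolag = _dynamic_eta(draws, design, spec, zero_lambda=True)
        eta_nodisc = _dynamic_eta(draws, design, spec, zero_beta=True)
    else:
        # one-step-ahead: both arms share the observed AR input, so the
        # difference is exactly the discounting term on the log scale
        eta_nolag = eta_lag - beta[:, None] * (K - design.x[None, :])
        eta_nodisc = eta_lag - beta[:, None] * K

    with np.errstate(over="raise"):
        try:
            f_lag = np.exp(eta_lag[:, ok])
            f_nolag = np.exp(eta_nolag[:, ok])
            f_nodisc = np.exp(eta_nodisc[:, ok])
        except FloatingPointError:
            bad = np.argwhere(eta_lag > 700)
            where = tuple(bad[0]) if len(bad) else "unknown"
            raise OverflowError(f"exponentiated fitted sales overflow at (draw, week) {where}")

    excess_lag = (f_lag - f_nolag).sum(axis=1)
    total_disc = (f_lag - f_nodisc).sum(axis=1)

    summary = pd.DataFrame.from_dict(
        {"excess_lag": _row(excess_lag), "total_discount": _row(total_disc)}, orient="index"
    )
    total_mean = float(total_disc.mean())
    ratio = worked_ratio(float(excess_lag.mean()), total_mean) if total_mean > 0 else float("nan")
    per_draw = pd.DataFrame({"excess_lag": excess_lag, "total_discount": total_disc})
    return AttributionResult(summary=summary, ratio_pct=ratio, per_draw=per_draw)


def _dynamic_eta(draws, design, spec, zero_lambda=False, zero_beta=False):
    """Counterfactual fitted path with the AR term fed its own fitted values."""
    P = draws.param_matrix().copy()
    if zero_lambda:
        P[:, 1] = 0.0
    if zero_beta:
        P[:, 0] = 0.0
    rho = P[:, 2]
    beta = P[:, 0]
    lam = P[:, 1]
    K = _engine.koyck_batch(design.x, lam, spec.k0_policy == "steady")
    # static part excluding AR
    base = draws.mu + beta[:, None] * K
    kcov = len(spec.covariates)
    if kcov:
        base = base + P[:, 3 : 3 + kcov] @ design.Z.T
    m2 = 2 * spec.n_harmonics
    base = base + P[:, 3 + kcov : 3 + kcov + m2] @ design.H.T
    T = base.shape[1]
    eta = np.empty_like(base)
    prev = np.full(P.shape[0], design.y_lag[0])
    for t in range(T):
        eta[:, t] = base[:, t] + rho * prev
        prev = eta[:, t]
    return eta


def worked_ratio(excess_mean: float, total_mean: float) -> float:
    """Share of discount-attributable servings due to the lagged effect,
    ``100 * excess / total`` percent (unrounded; round only for reporting)."""
    if total_mean <= 0:
        raise ValueError("total attributable servings must be positive")
    return 100.0 * excess_mean / total_mean
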