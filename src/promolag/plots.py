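"""Figure analogues of the headline result surfaces: per-category effect
forests and impulse-response curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .attribution import ImpulseResponse
from .inference import PosteriorSummary


def plot_impulse_response(irf: ImpulseResponse, title: str = "", ax=None):
    """Median lag profile ``100*beta*lambda^h`` with its 95% credible band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(irf.lags, irf.lo95, irf.hi95, color="0.8", label="95% CrI")
    ax.plot(irf.lags, irf.median, "o-", color="C0", label="posterior median")
    ax.axhline(0.0, color="0.4", lw=0.8)
    ax.set_xlabel("lag (weeks)")
    ax.set_ylabel("% change of sales per 1% discount")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def plot_effect_intervals(
    summaries: dict[str, PosteriorSummary], param: str = "beta_pct", ax=None
):
    """Forest plot of one parameter's posterior median and 95% CrI across
    categories (the immediate-effect and lag-coefficient summaries)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * len(summaries) + 1.2))
    names = list(summaries)
    for i, name in enumerate(names):
        row = summaries[name][param]
        ax.errorbar(
            row["median"], i,
            xerr=[[row["median"] - row["q2.5"]], [row["q97.5"] - row["median"]]],
            fmt="o", color="C0", capsize=3,
        )
    ax.axvline(0.0, color="0.4", lw=0.8)
    ax.set_yticks(np.arange(len(names)), names)
    ax.set_xlabel(param)
    ax.figure.tight_layout()
    return ax.figure
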