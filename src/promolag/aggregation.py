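"""Item-to-category aggregation of weekly retail transactions.

Transforms item-level weekly transaction rows into one
:class:`~promolag.series.CategorySeries` per beverage category:

* sales quantities are standardized to 240 ml servings (the FDA single
  serving size for beverages),
* each item's percent discount is the percent decrease of its
  serving-standardized net price from its serving-standardized baseline
  (regular) price,
* category exposure is the market-share-weighted mean of item discounts,
  with weights equal to each item's share of serving-standardized sales,
* display/flyer promotion covariates are share-weighted proportions of
  promoted items, and the category regular price is the share-weighted
  baseline price per serving.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .series import CategorySeries

logger = logging.getLogger(__name__)

SERVING_ML = 240.0

#: mandatory columns of a transaction table
TRANSACTION_COLUMNS = [
    "item_id",
    "category",
    "week",
    "units_sold",
    "volume_ml",
    "net_price_cents",
    "baseline_price_cents",
    "display",
    "flyer",
]


def servings(units_sold, volume_ml):
    """Serving-standardized sales volume: ``units * volume_ml / 240``.

    Accepts scalars or arrays. Raises ``ValueError`` on non-positive
    volume (scalar use); in :func:`aggregate_category` such rows are
    rejected with a logged warning instead.
    """
    units = np.asarray(units_sold, dtype=float)
    vol = np.asarray(volume_ml, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("volume_ml must be positive")
    out = units * vol / SERVING_ML
    return float(out) if out.ndim == 0 else out


def item_discount_pct(net_price_cents, baseline_price_cents, volume_ml):
    """Percent decrease of serving-standardized net price from baseline.

    The per-serving standardization cancels within an item (both prices are
    divided by the same servings-per-unit) but is applied explicitly so
    that discounts on different package sizes are directly comparable.
    A net price above baseline (price increase) is clamped to a 0% discount
    with a warning.
    """
    net = np.asarray(net_price_cents, dtype=float)
    base = np.asarray(baseline_price_cents, dtype=float)
    vol = np.asarray(volume_ml, dtype=float)
    if np.any(base <= 0):
        raise ValueError("baseline price must be positive")
    if np.any(vol <= 0):
        raise ValueError("volume_ml must be positive")
    serv_per_unit = vol / SERVING_ML
    net_ps = net / serv_per_unit
    base_ps = base / serv_per_unit
    pct = 100.0 * (base_ps - net_ps) / base_ps
    n_neg = int(np.sum(pct < 0))
    if n_neg:
        logger.warning("clamping %d price increases to 0%% discount", n_neg)
        pct = np.clip(pct, 0.0, None)
    return float(pct) if pct.ndim == 0 else pct


def filter_diet_items(table: pd.DataFrame, exclusion_terms: list[str]) -> pd.DataFrame:
    """Drop items whose name contains any exclusion term, case-insensitively.

    Mirrors the manual exclusion of artificially sweetened ("diet", "zero",
    "non-sugar") products from sugar-sweetened categories. Raises if the
    filter removes every row.
    """
    if not exclusion_terms:
        return table
    names = table["item_id"].astype(str).str.lower()
    mask = np.zeros(len(table), dtype=bool)
    for term in exclusion_terms:
        mask |= names.str.contains(str(term).lower(), regex=False)
    removed = int(mask.sum())
    if removed:
        logger.info(
            "filter_diet_items: removed %d of %d rows (%d items)",
            removed,
            len(table),
            table.loc[mask, "item_id"].nunique(),
        )
    out = table.loc[~mask].copy()
    if out.empty:
        raise ValueError("exclusion terms removed every item in the table")
    return out


def aggregate_category(
    table: pd.DataFrame,
    category: str,
    covariates: pd.DataFrame,
    weights: str = "weekly",
) -> CategorySeries:
    """Aggregate one category's item rows into a weekly CategorySeries.

    Parameters
    ----------
    table:
        Transaction rows (see :data:`TRANSACTION_COLUMNS`). Only rows of
        ``category`` are used.
    category:
        Category label to aggregate.
    covariates:
        Weekly covariate table with columns ``week``, ``week_of_year``,
        ``holiday``, ``temperature``; its length defines ``T``.
    weights:
        ``"weekly"`` (default) weights item discounts by the item's share of
        that week's serving-standardized sales; ``"period"`` uses the item's
        share of total servings over the whole study period instead.

    Weeks with zero category servings get exposure and promotion
    proportions of 0 and are flagged missing (the log outcome is undefined
    there and never evaluated).
    """
    if weights not in ("weekly", "period"):
        raise ValueError("weights must be 'weekly' or 'period'")
    sub = table[table["category"] == category]
    if sub.empty:
        raise ValueError(f"no rows for category {category!r}")
    bad_vol = sub["volume_ml"] <= 0
    if bad_vol.any():
        logger.warning(
            "rejecting %d rows with non-positive volume in %r", int(bad_vol.sum()), category
        )
        sub = sub[~bad_vol]

    cov = covariates.sort_values("week").reset_index(drop=True)
    weeks = cov["week"].to_numpy(dtype=np.int64)
    T = len(weeks)
    week_pos = {int(w): i for i, w in enumerate(weeks)}

    items = np.sort(sub["item_id"].unique())
    item_pos = {it: i for i, it in enumerate(items)}
    n = len(items)

    serv = np.zeros((n, T))
    disc = np.zeros((n, T))
    disp = np.zeros((n, T))
    fly = np.zeros((n, T))
    base_ps = np.zeros((n, T))
    stocked = np.zeros((n, T), dtype=bool)

    rows_i = sub["item_id"].map(item_pos).to_numpy()
    rows_t = sub["week"].map(week_pos).to_numpy()
    if np.any(pd.isna(rows_t)):
        raise ValueError("transaction weeks not covered by the covariate table")
    rows_t = rows_t.astype(np.int64)

    serv[rows_i, rows_t] = servings(
        sub["units_sold"].to_numpy(), sub["volume_ml"].to_numpy()
    )
    disc[rows_i, rows_t] = item_discount_pct(
        sub["net_price_cents"].to_numpy(),
        sub["baseline_price_cents"].to_numpy(),
        sub["volume_ml"].to_numpy(),
    )
    disp[rows_i, rows_t] = sub["display"].to_numpy(dtype=float)
    fly[rows_i, rows_t] = sub["flyer"].to_numpy(dtype=float)
    base_ps[rows_i, rows_t] = (
        sub["baseline_price_cents"].to_numpy() / (sub["volume_ml"].to_numpy() / SERVING_ML)
    )
    stocked[rows_i, rows_t] = True

    total = serv.sum(axis=0)
    zero = total <= 0.0
    if zero.any():
        logger.warning("%d weeks with zero servings in %r flagged missing", int(zero.sum()), category)

    if weights == "weekly":
        denom = np.where(zero, 1.0, total)
        w = serv / denom
    else:
        item_tot = serv.sum(axis=1)
        grand = item_tot.sum()
        w_items = item_tot / grand if grand > 0 else np.full(n, 1.0 / n)
        w = np.where(stocked, w_items[:, None], 0.0)
        col = w.sum(axis=0)
        w = w / np.where(col > 0, col, 1.0)

    x = (w * disc).sum(axis=0)
    display_prop = (w * disp).sum(axis=0)
    flyer_prop = (w * fly).sum(axis=0)
    regular_price = (w * base_ps).sum(axis=0)
    if weights == "weekly" and zero.any():
        x[zero] = 0.0
        display_prop[zero] = 0.0
        flyer_prop[zero] = 0.0
        regular_price[zero] = 0.0

    return CategorySeries(
        category=category,
        week=weeks,
        servings=total,
        discount_pct=x,
        display_prop=display_prop,
        flyer_prop=flyer_prop,
        regular_price=regular_price,
        holiday=cov["holiday"].to_numpy(dtype=np.int64),
        temperature=cov["temperature"].to_numpy(dtype=float),
        week_of_year=cov["week_of_year"].to_numpy(dtype=np.int64),
        missing=zero,
    )
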