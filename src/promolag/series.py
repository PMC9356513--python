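"""Weekly category-level time series container.

A :class:`CategorySeries` holds one beverage category's weekly outcome
(serving-standardized sales), exposure (market-share-weighted percent
discount), promotion covariates, and calendar covariates, all aligned on a
common week index ``1..T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: columns persisted to / read from CSV, in order
_COLUMNS = [
    "week",
    "servings",
    "discount_pct",
    "display_prop",
    "flyer_prop",
    "regular_price",
    "holiday",
    "temperature",
    "week_of_year",
    "missing",
]


@dataclass
class CategorySeries:
    """One category's weekly outcome, exposure and covariate vectors.

    Parameters
    ----------
    category:
        Category label (e.g. ``"soda"``).
    week:
        Integer week index ``1..T``.
    servings:
        Total 240 ml servings sold per week (non-negative).
    discount_pct:
        Market-share-weighted mean percent discount per serving, in
        ``[0, 100)``.
    display_prop, flyer_prop:
        Share-weighted proportion of items on display / flyer promotion.
    regular_price:
        Share-weighted baseline (non-promoted) price in cents per serving.
    holiday:
        0/1 indicator for statutory-holiday weeks.
    temperature:
        Mean daytime temperature (degrees Celsius).
    week_of_year:
        Calendar week index in ``1..52``.
    missing:
        True for weeks with zero category servings; the log outcome is
        undefined there and such weeks are skipped by the model likelihood.
    """

    category: str
    week: np.ndarray
    servings: np.ndarray
    discount_pct: np.ndarray
    display_prop: np.ndarray
    flyer_prop: np.ndarray
    regular_price: np.ndarray
    holiday: np.ndarray
    temperature: np.ndarray
    week_of_year: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arrays = {
            "week": np.asarray(self.week, dtype=np.int64),
            "servings": np.asarray(self.servings, dtype=float),
            "discount_pct": np.asarray(self.discount_pct, dtype=float),
            "display_prop": np.asarray(self.display_prop, dtype=float),
            "flyer_prop": np.asarray(self.flyer_prop, dtype=float),
            "regular_price": np.asarray(self.regular_price, dtype=float),
            "holiday": np.asarray(self.holiday, dtype=np.int64),
            "temperature": np.asarray(self.temperature, dtype=float),
            "week_of_year": np.asarray(self.week_of_year, dtype=np.int64),
        }
        lengths = {k: len(v) for k, v in arrays.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"vector lengths differ: {lengths}")
        for k, v in arrays.items():
            setattr(self, k, v)
        if self.missing is None:
            self.missing = arrays["servings"] <= 0.0
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.missing) != lengths["week"]:
            raise ValueError("missing mask length mismatch")

    def __len__(self) -> int:
        return len(self.week)

    @property
    def n_weeks(self) -> int:
        return len(self.week)

    @property
    def log_sales(self) -> np.ndarray:
        """Natural log of total servings; NaN on zero-sales (missing) weeks."""
        out = np.full(len(self), np.nan)
        ok = ~self.missing
        out[ok] = np.log(self.servings[ok])
        return out

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in _COLUMNS})
        df.insert(0, "category", self.category)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, category: str | None = None) -> "CategorySeries":
        if category is None:
            cats = df["category"].unique()
            if len(cats) != 1:
                raise ValueError(f"frame holds {len(cats)} categories; pass one explicitly")
            category = str(cats[0])
        else:
            df = df[df["category"] == category]
            if df.empty:
                raise ValueError(f"category {category!r} not present")
        df = df.sort_values("week")
        kwargs = {c: df[c].to_numpy() for c in _COLUMNS if c in df.columns}
        return cls(category=category, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, category: str | None = None) -> "CategorySeries":
        return cls.from_frame(pd.read_csv(path), category=category)
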