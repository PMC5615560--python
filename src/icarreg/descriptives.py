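"""Descriptive geography of county outcome rates.

Cross-tabulated mean rates by pairs of county categorisations (urbanicity x
poverty quintile, poverty x majority ethnicity, census division x poverty),
top-vs-bottom gradient ratios, and per-quintile outcome profiles against a
continuous indicator.

Cell statistics are unweighted means of county rates; a population-weight
column may optionally be supplied, in which case cells are population-
weighted means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import quintile_assign

logger = logging.getLogger(__name__)

__all__ = ["CrossTab", "crosstab_rates", "gradient_ratio", "quintile_profile"]


@dataclass(frozen=True)
class CrossTab:
    """Mean outcome per (row level, column level) cell with margins.

    ``cells`` and ``counts`` are DataFrames indexed by row-factor level and
    columned by col-factor level, each carrying an ``"All"`` margin row and
    column.  Empty cells are NaN, never zero.
    """

    row_factor: str
    col_factor: str
    outcome: str
    cells: pd.DataFrame
    counts: pd.DataFrame

    def grand_mean(self) -> float:
        return float(self.cells.loc["All", "All"])

    def to_text(self, fmt: str = "{:.1f}") -> str:
        """Aligned plain-text rendering of the table."""
        df = self.cells.map(lambda v: "" if pd.isna(v) else fmt.format(v))
        return df.to_string()


def _cell_means(
    df: pd.DataFrame, outcome: str, by: list[str], weights: str | None
) -> pd.Series:
    if weights is None:
        return df.groupby(by, observed=True)[outcome].mean()
    g = df.groupby(by, observed=True)
    return g.apply(
        lambda d: np.average(d[outcome], weights=d[weights]), include_groups=False
    )


def crosstab_rates(
    data: pd.DataFrame,
    outcome: str,
    rows: str,
    cols: str,
    weights: str | None = None,
) -> CrossTab:
    """Cross-tabulate mean county outcome rates by two categorical factors."""
    for col in (outcome, rows, cols):
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")
    df = data[[outcome, rows, cols] + ([weights] if weights else [])]
    n_missing = int(df[outcome].isna().sum())
    if n_missing:
        logger.info("dropping %d counties with missing %s", n_missing, outcome)
        df = df.dropna(subset=[outcome])
    if df[rows].isna().any() or df[cols].isna().any():
        raise ValueError("factors must be fully observed for all counties")

    row_levels = sorted(df[rows].unique())
    col_levels = sorted(df[cols].unique())
    interior = _cell_means(df, outcome, [rows, cols], weights).unstack(cols)
    interior = interior.reindex(index=row_levels, columns=col_levels)
    counts = (
        df.groupby([rows, cols], observed=True)[outcome]
        .size()
        .unstack(cols)
        .reindex(index=row_levels, columns=col_levels)
        .fillna(0)
        .astype(int)
    )

    cells = interior.copy()
    cells["All"] = _cell_means(df, outcome, [rows], weights).reindex(row_levels)
    col_margin = _cell_means(df, outcome, [cols], weights).reindex(col_levels)
    overall = (
        float(df[outcome].mean())
        if weights is None
        else float(np.average(df[outcome], weights=df[weights]))
    )
    cells.loc["All"] = list(col_margin) + [overall]
    counts["All"] = counts.sum(axis=1)
    counts.loc["All"] = counts.sum(axis=0)

    return CrossTab(rows, cols, outcome, cells, counts)


def gradient_ratio(
    data: pd.DataFrame, outcome: str, factor: str, order: list | None = None
) -> float:
    """Ratio of mean outcome in the top factor level to the bottom level.

    Levels are ordered by ``order`` if given, else by sorted level value;
    the top level is the last.
    """
    levels = order if order is not None else sorted(data[factor].unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 ordered levels")
    bottom = data.loc[data[factor] == levels[0], outcome]
    top = data.loc[data[factor] == levels[-1], outcome]
    if bottom.empty or top.empty:
        raise ValueError("extreme factor levels must be non-empty")
    denom = bottom.mean()
    if denom == 0:
        raise ZeroDivisionError("bottom-level mean outcome is zero")
    return float(top.mean() / denom)


def quintile_profile(
    data: pd.DataFrame, outcome: str, indicator: str
) -> pd.Series:
    """Mean outcome per quintile of a continuous indicator.

    Quintile 1 holds the counties with the lowest indicator values.
    """
    x = data[indicator].to_numpy(dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("indicator needs at least 5 distinct values")
    q = quintile_assign(x)
    out = data[outcome].groupby(q.labels).mean()
    out.index.name = f"{indicator}_quintile"
    out.name = outcome
    return out
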