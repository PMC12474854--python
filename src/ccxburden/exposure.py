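"""Exposure processing: grid aggregation, lagged moving averages, flags.

Daily pollutant predictions on a grid are aggregated to districts by
unweighted averaging over the cells whose centroids fall inside each
district (the membership table is assumed precomputed upstream); the
analysis exposure is then a lagged moving average — lag 0-1 (mean of the
same and previous day) for the main model, lag 0-2/0-3 for sensitivity,
and a lag 0-3 moving average of temperature for confounder adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_grid_to_district",
    "build_lagged_exposure",
    "moving_average",
    "who_exceedance",
]

#: Default WHO 2021 24-hour guideline value for PM2.5 (ug/m3).
WHO_DAILY_PM25 = 15.0


def aggregate_grid_to_district(
    grid_table: pd.DataFrame,
    membership: pd.DataFrame,
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Average grid-cell values to districts by centroid membership.

    Parameters
    ----------
    grid_table : DataFrame
        Columns ``grid_cell_id``, ``date`` and one or more value columns.
        At most one row per (cell, date).
    membership : DataFrame
        Columns ``grid_cell_id``, ``district_id``; each cell belongs to at
        most one district.

    Returns
    -------
    DataFrame with one row per (district_id, date); the district value is
    the unweighted arithmetic mean over member cells present on that date.
    Districts with no member cells are absent from the output.
    """
    if membership.empty:
        raise ValueError("membership table is empty")
    if membership["grid_cell_id"].duplicated().any():
        dupes = membership.loc[
            membership["grid_cell_id"].duplicated(), "grid_cell_id"
        ].unique()
        raise ValueError(f"grid cells mapped to multiple districts: {list(dupes)[:5]}")
    if grid_table.duplicated(subset=["grid_cell_id", "date"]).any():
        raise ValueError("duplicate (grid_cell_id, date) rows in grid table")

    if value_cols is None:
        value_cols = [
            c for c in grid_table.columns if c not in ("grid_cell_id", "date")
        ]
    merged = grid_table.merge(membership, on="grid_cell_id", how="inner")
    out = (
        merged.groupby(["district_id", "date"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    return out


def moving_average(series: pd.Series, max_lag: int) -> pd.Series:
    """Trailing moving average over lags 0..max_lag of a daily series.

    ``out[t] = mean(series[t-max_lag .. t])``; the first ``max_lag``
    entries (and any window touching a missing day) are NaN.
    """
    return series.rolling(max_lag + 1, min_periods=max_lag + 1).mean()


def _complete_daily_calendar(table: pd.DataFrame) -> pd.DataFrame:
    """Reindex each district to a full daily calendar, inserting NaN days."""
    filled = []
    n_gaps = 0
    for district, g in table.groupby("district_id", sort=True):
        g = g.sort_values("date").set_index("date")
        full = pd.date_range(g.index.min(), g.index.max(), freq="D")
        n_gaps += len(full) - len(g)
        g = g.reindex(full)
        g.index.name = "date"
        g["district_id"] = district
        filled.append(g.reset_index())
    if n_gaps:
        logger.warning(
            "daily calendar has %d missing district-days; affected lag windows "
            "will be missing",
            n_gaps,
        )
    return pd.concat(filled, ignore_index=True)


def build_lagged_exposure(
    district_table: pd.DataFrame,
    pm25_lags: tuple[int, ...] = (1, 2, 3),
    temp_lags: tuple[int, ...] = (1, 3),
) -> pd.DataFrame:
    """Build the analysis-ready lagged exposure table.

    Adds ``pm25_lag01`` / ``pm25_lag02`` / ``pm25_lag03`` (trailing means of
    PM2.5 over lags 0-1/0-2/0-3), ``no2_lag01`` when NO2 is present, and
    ``temp_ma01`` / ``temp_ma03`` temperature moving averages (the lag 0-3
    one is the default confounder; 0-1 supports sensitivity analyses).
    Calendar gaps are tolerated: affected windows come out missing and a
    count is logged.
    """
    table = _complete_daily_calendar(district_table)
    g = table.groupby("district_id", sort=False)
    for k in pm25_lags:
        table[f"pm25_lag0{k}"] = g["pm25"].transform(lambda s, k=k: moving_average(s, k))
    if "no2" in table.columns:
        table["no2_lag01"] = g["no2"].transform(lambda s: moving_average(s, 1))
    if "temperature" in table.columns:
        for k in temp_lags:
            table[f"temp_ma0{k}"] = g["temperature"].transform(
                lambda s, k=k: moving_average(s, k)
            )
    return table


def who_exceedance(values, threshold: float = WHO_DAILY_PM25) -> np.ndarray:
    """Flag values strictly above the guideline threshold (default 15 ug/m3).

    By default the flag is evaluated on the same exposure metric used in the
    regression (the lag 0-1 mean); pass raw daily values for the
    daily-average variant.
    """
    arr = np.asarray(values, dtype=float)
    return arr > threshold
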