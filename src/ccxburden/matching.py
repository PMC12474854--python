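"""Time-stratified referent matching for the case-crossover design.

Each death defines a case day; its referents are the other days of the same
weekday within the same calendar month and year.  Every 2015-2019 stratum
contains 4 or 5 same-weekday dates, so each case gets 3 or 4 controls.
Confounders that are constant within a month (age, sex, district-level
characteristics) are constant within a matched set and cancel from the
conditional likelihood.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["referent_days", "stratum_days", "build_case_crossover"]

#: Covariates that must be present on every row of a matched set for the
#: default model design.
DEFAULT_REQUIRED = ("pm25_lag01", "temp_ma03", "relative_humidity", "precipitation")


def stratum_days(date: dt.date) -> list[dt.date]:
    """All days in ``date``'s month/year sharing its weekday (case included)."""
    n_days = calendar.monthrange(date.year, date.month)[1]
    first = dt.date(date.year, date.month, 1)
    # first day-of-month with the case's weekday (ISO: Monday=1)
    offset = (date.weekday() - first.weekday()) % 7
    return [
        dt.date(date.year, date.month, d)
        for d in range(1 + offset, n_days + 1, 7)
    ]


def referent_days(case_date: dt.date | str | pd.Timestamp) -> list[dt.date]:
    """Control days for a case day: same weekday, same month, same year.

    Returns the dates in ascending order, excluding the case day itself;
    every calendar month yields 3 or 4 referents.
    """
    if isinstance(case_date, str):
        case_date = dt.date.fromisoformat(case_date)
    elif isinstance(case_date, pd.Timestamp):
        case_date = case_date.date()
    return [d for d in stratum_days(case_date) if d != case_date]


def build_case_crossover(
    mortality_records: pd.DataFrame,
    lagged_exposure: pd.DataFrame,
    required: tuple[str, ...] = DEFAULT_REQUIRED,
    carry_cols: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the matched case-crossover dataset.

    One matched set per death record (identical same-day same-district
    deaths are retained as separate strata; the conditional likelihood is
    equivalent up to multiplicity).  Covariates are joined by
    (district, date); sets in which any row is missing a ``required``
    covariate, or whose district is absent from the exposure table, are
    dropped and counted.

    Returns
    -------
    (ccdata, summary)
        ``ccdata`` is a long DataFrame with one row per case/control day:
        ``set_id``, ``is_case``, ``date``, ``district_id``, the case's
        ``age_group``/``cause``/``sex`` copied to all rows of the set, and
        all exposure covariates.  ``summary`` counts records in, sets built
        and sets dropped.
    """
    records = mortality_records.reset_index(drop=True).copy()
    records["set_id"] = np.arange(len(records))
    case_dates = pd.to_datetime(records["date"])
    records["case_date"] = case_dates.dt.normalize()

    # enumerate all (year, month, weekday) strata touched by the records
    span = pd.date_range(
        records["case_date"].min().replace(day=1),
        records["case_date"].max() + pd.offsets.MonthEnd(0),
        freq="D",
    )
    strata = pd.DataFrame(
        {
            "date": span,
            "_stratum": span.year * 1000 + span.month * 10 + span.weekday,
        }
    )

    records["_stratum"] = (
        records["case_date"].dt.year * 1000
        + records["case_date"].dt.month * 10
        + records["case_date"].dt.weekday
    )

    keep_cols = ["set_id", "district_id", "case_date", "_stratum"]
    label_cols = [c for c in ("age_group", "cause", "sex") if c in records.columns]
    long = records[keep_cols + label_cols].merge(strata, on="_stratum", how="left")
    long["is_case"] = long["date"] == long["case_date"]

    covs = lagged_exposure.copy()
    covs["date"] = pd.to_datetime(covs["date"]).dt.normalize()
    if carry_cols is None:
        carry_cols = tuple(
            c for c in covs.columns if c not in ("district_id", "date")
        )
    long = long.merge(
        covs[["district_id", "date", *carry_cols]],
        on=["district_id", "date"],
        how="left",
    )

    required = tuple(c for c in required if c in long.columns)
    bad = long[list(required)].isna().any(axis=1)
    # a row absent from the exposure table entirely also shows up as NaN
    dropped_sets = long.loc[bad, "set_id"].unique()
    if len(dropped_sets):
        logger.info(
            "dropping %d matched sets with missing exposure/covariates",
            len(dropped_sets),
        )
        long = long[~long["set_id"].isin(dropped_sets)]

    long = long.sort_values(["set_id", "date"]).reset_index(drop=True)
    long = long.drop(columns=["case_date", "_stratum"])

    summary = {
        "records_in": int(len(records)),
        "sets_built": int(long["set_id"].nunique()),
        "sets_dropped": int(len(dropped_sets)),
    }
    return long, summary
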