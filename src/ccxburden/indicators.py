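"""Tertile categorization of district-level indicators.

District indicators (population density, distance to parks, hospital beds
per 1,000 persons, distance to emergency medical facilities) are summarized
as study-period averages per district and classified into low / middle /
high thirds for the effect-modification analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tertile_categorize"]

CATEGORIES = ("low", "middle", "high")


def tertile_categorize(
    values: pd.Series | pd.DataFrame,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Assign each district to the low/middle/high third of an indicator.

    ``values`` is either a Series indexed by district id or a DataFrame with
    ``district_id`` and a value column.  Cut points are the 1/3 and 2/3
    empirical quantiles (linear-interpolation / type-7 definition, recorded
    in ``attrs["cutpoints"]``); assignment is by rank with ties broken by
    district id, so the three groups always have sizes within one of each
    other and any strictly increasing transform of the values leaves the
    categorization unchanged.
    """
    if isinstance(values, pd.DataFrame):
        if value_col is None:
            candidates = [c for c in values.columns if c != "district_id"]
            if len(candidates) != 1:
                raise ValueError("value_col must be named for multi-column input")
            value_col = candidates[0]
        district = values["district_id"].to_numpy()
        vals = values[value_col].to_numpy(dtype=float)
    else:
        district = values.index.to_numpy()
        vals = values.to_numpy(dtype=float)

    n = vals.size
    if n < 3:
        raise ValueError("tertiles need at least 3 districts")
    if not np.all(np.isfinite(vals)):
        raise ValueError("indicator values must be finite")
    if np.min(vals) == np.max(vals):
        raise ValueError("all indicator values identical; tertiles undefined")

    order = np.lexsort((district, vals))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    i1, i2 = n // 3, (2 * n) // 3
    category = np.where(ranks < i1, "low", np.where(ranks < i2, "middle", "high"))

    out = pd.DataFrame(
        {
            "district_id": district,
            "value": vals,
            "category": pd.Categorical(category, categories=list(CATEGORIES), ordered=True),
        }
    ).sort_values("district_id").reset_index(drop=True)
    out.attrs["cutpoints"] = tuple(np.quantile(vals, [1 / 3, 2 / 3]))
    return out
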