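"""Published descriptive mortality counts, South Korea 2015-2019.

National counts of registered deaths by major cause of death and age group
over 2015-2019, used as worked-example inputs: the share arithmetic
(percent of total non-accidental deaths) is recomputed from these counts by
:func:`cause_age_shares`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["MORTALITY_COUNTS_2015_2019", "cause_age_shares"]

#: (cause group, age category) -> number of deaths, 2015-2019.
MORTALITY_COUNTS_2015_2019: dict[tuple[str, str], int] = {
    ("non_accidental", "total"): 1_270_499,
    ("non_accidental", "0-59"): 180_893,
    ("non_accidental", "60-69"): 166_658,
    ("non_accidental", "70-79"): 323_411,
    ("non_accidental", "80+"): 599_336,
    ("circulatory", "total"): 298_838,
    ("circulatory", "0-59"): 33_493,
    ("circulatory", "60-69"): 31_457,
    ("circulatory", "70-79"): 74_205,
    ("circulatory", "80+"): 159_643,
    ("respiratory", "total"): 161_059,
    ("respiratory", "0-59"): 6_396,
    ("respiratory", "60-69"): 11_741,
    ("respiratory", "70-79"): 39_628,
    ("respiratory", "80+"): 103_271,
}


def cause_age_shares(
    counts: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Percent of total non-accidental deaths per (cause, age) cell.

    The denominator is the all-ages non-accidental total, matching the
    published descriptive-table convention.
    """
    counts = MORTALITY_COUNTS_2015_2019 if counts is None else counts
    denom = counts[("non_accidental", "total")]
    rows = [
        {
            "cause": cause,
            "age": age,
            "deaths": n,
            "share_pct": 100.0 * n / denom,
        }
        for (cause, age), n in counts.items()
    ]
    return pd.DataFrame(rows)
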