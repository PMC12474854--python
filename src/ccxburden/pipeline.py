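"""End-to-end study orchestration.

``run_study`` wires the stages together: simulate (or load) the four input
tables, build lagged exposures, assemble the time-stratified case-crossover
dataset once, then for every cause-of-death x age-group combination fit the
conditional logistic model and translate it into attributable burden; on
top of that, tertile-interaction effect modification per district indicator
and an optional sensitivity grid (lag windows, temperature spline df, NO2
co-adjustment).  Everything is deterministic under the configured seed, and
a manifest records row counts at every stage.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import attributable_burden, daily_deaths_table
from .config import CAUSE_GROUPS, DesignSpec, StudyConfig
from .exposure import build_lagged_exposure
from .indicators import tertile_categorize
from .matching import build_case_crossover
from .regression import fit_conditional_logistic, fit_with_interaction
from .synthetic import (
    make_life_table,
    simulate_exposure,
    simulate_indicators,
    simulate_mortality,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_study", "write_study_outputs"]


@dataclass
class StudyResult:
    """Bundle of study outputs.

    ``fits``: one row per (cause, age) stratum with the exposure estimate;
    strata without informative sets appear as NA rows.  ``burden``: one row
    per stratum and scope.  ``modification``: per indicator and cause, the
    tertile ORs and interaction p-values.  ``sensitivity``: the estimate
    under alternative specifications.  ``manifest``: seeds, config and
    row-count accounting.
    """

    fits: pd.DataFrame
    burden: pd.DataFrame
    modification: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict
    ccdata: pd.DataFrame = field(repr=False, default=None)


def _stratum_mask(ccdata: pd.DataFrame, cause: str, age: str) -> pd.Series:
    mask = ccdata["cause"].isin(CAUSE_GROUPS[cause])
    if age != "total":
        mask &= ccdata["age_group"] == age
    return mask


def run_study(config: StudyConfig, keep_ccdata: bool = False) -> StudyResult:
    """Run the full simulated study defined by ``config``."""
    sim = config.simulation.replace(seed=config.simulation.seed + config.seed)
    logger.info("simulating exposure for %d districts", sim.n_districts)
    exposure = simulate_exposure(sim)
    lagged = build_lagged_exposure(exposure)
    indicators = simulate_indicators(sim)

    categories = {
        name: tertile_categorize(indicators[["district_id", name]], name)
        for name in config.indicators
    }
    active_cats = None
    if any(s != 0.0 for s in sim.interaction_shift):
        first = config.indicators[0]
        active_cats = dict(
            zip(categories[first]["district_id"], categories[first]["category"])
        )
    records = simulate_mortality(exposure, sim, district_categories=active_cats)
    logger.info("simulated %d mortality records", len(records))

    ccdata, match_summary = build_case_crossover(records, lagged)
    life_table = make_life_table(config.life_table_style)

    rng = np.random.default_rng([config.seed, 17])

    fit_rows, burden_rows = [], []
    for cause in config.causes:
        for age in config.ages:
            sub = ccdata[_stratum_mask(ccdata, cause, age)]
            row = {"cause": cause, "age": age}
            if sub["set_id"].nunique() == 0:
                fit_rows.append({**row, "n_sets": 0})
                continue
            try:
                fit = fit_conditional_logistic(sub, config.design)
            except ValueError as exc:
                logger.warning("stratum (%s, %s) not fit: %s", cause, age, exc)
                fit_rows.append({**row, "n_sets": int(sub["set_id"].nunique())})
                continue
            fit_rows.append({**row, **fit.summary_row()})

            stratum_records = records[
                records["cause"].isin(CAUSE_GROUPS[cause])
                & (records["age_group"] == age if age != "total" else True)
            ]
            daily = daily_deaths_table(stratum_records, lagged)
            for scope in ("all", "who"):
                res = attributable_burden(
                    daily,
                    fit.beta_exposure,
                    fit.se_exposure,
                    scope=scope,
                    threshold=config.burden_threshold,
                    life_table=life_table,
                    n_rep=config.burden_n_rep,
                    seed=int(rng.integers(2**31)),
                )
                burden_rows.append({**row, **res.summary_row()})

    fits = pd.DataFrame(fit_rows)
    burden = pd.DataFrame(burden_rows)

    # effect modification by district indicator tertiles
    mod_rows = []
    for name, cat_table in categories.items():
        cat_map = dict(zip(cat_table["district_id"], cat_table["category"].astype(str)))
        for cause in config.modification_causes:
            sub = ccdata[_stratum_mask(ccdata, cause, "total")]
            if sub["set_id"].nunique() == 0:
                continue
            cats = sub["district_id"].map(cat_map)
            try:
                res = fit_with_interaction(sub, cats, config.design)
            except ValueError as exc:
                logger.warning("modification (%s, %s) not fit: %s", name, cause, exc)
                continue
            for level in ("low", "middle", "high"):
                orr, lo, hi = res.ors[level]
                mod_rows.append(
                    {
                        "indicator": name,
                        "cause": cause,
                        "category": level,
                        "or_per_10": orr,
                        "or_lo": lo,
                        "or_hi": hi,
                        "p_vs_low": {
                            "low": float("nan"),
                            "middle": res.p_middle,
                            "high": res.p_high,
                        }[level],
                    }
                )
    modification = pd.DataFrame(mod_rows)

    # sensitivity grid on the total-population non-accidental stratum
    sens_rows = []
    if config.run_sensitivity:
        sub = ccdata[_stratum_mask(ccdata, "non_accidental", "total")]
        variants: list[tuple[str, DesignSpec]] = []
        for lag in config.sensitivity_lags:
            variants.append((f"lag={lag}", config.design.replace(exposure_col=lag)))
        for df_t in config.sensitivity_temp_df:
            variants.append((f"temp_df={df_t}", config.design.replace(temp_df=df_t)))
        for col in config.sensitivity_temp_cols:
            if col in sub.columns:
                variants.append((f"temp={col}", config.design.replace(temp_col=col)))
        variants.append(("no2_adjusted", config.design.replace(include_no2=True)))
        for label, spec in variants:
            need = [c for c in spec.required_columns() if c in sub.columns]
            ok = sub[~sub["set_id"].isin(sub.loc[sub[need].isna().any(axis=1), "set_id"])]
            try:
                fit = fit_conditional_logistic(ok, spec)
            except ValueError as exc:
                logger.warning("sensitivity %s not fit: %s", label, exc)
                continue
            sens_rows.append({"variant": label, **fit.summary_row()})
    sensitivity = pd.DataFrame(sens_rows)

    manifest = {
        "seed": config.seed,
        "simulation_seed": sim.seed,
        "n_districts": sim.n_districts,
        "date_start": sim.date_start.isoformat(),
        "date_end": sim.date_end.isoformat(),
        "beta_true": sim.beta_true,
        "exposure_rows": int(len(exposure)),
        "mortality_records": int(len(records)),
        **match_summary,
        "n_strata_fit": int(fits.get("converged", pd.Series(dtype=bool)).notna().sum())
        if "converged" in fits
        else 0,
    }
    return StudyResult(
        fits=fits,
        burden=burden,
        modification=modification,
        sensitivity=sensitivity,
        manifest=manifest,
        ccdata=ccdata if keep_ccdata else None,
    )


def write_study_outputs(result: StudyResult, outdir: str) -> dict[str, str]:
    """Write the result bundle as CSV tables plus a JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, frame in (
        ("fits", result.fits),
        ("burden", result.burden),
        ("modification", result.modification),
        ("sensitivity", result.sensitivity),
    ):
        path = os.path.join(outdir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    paths["manifest"] = manifest_path
    return paths
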