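"""Synthetic inputs with known ground truth.

Generates the four tables the analysis consumes — district-by-date exposure
and weather, individual mortality records, district indicators, and a life
table — from a :class:`~ccxburden.config.SimulationConfig` whose parameters
are the generative truth.  Mortality counts are Poisson at district-day
level with log mean

    log(baseline) + beta_true * (lag 0-1 mean PM2.5, centred)
                  + U-shaped temperature term (centred)
                  + per-tertile interaction shift * exposure

then exploded into individual records with age group, cause of death and
sex drawn from configurable mixture vectors.  Because the case-crossover
likelihood conditions on within-month strata, any stationary baseline is
compatible with the design; centring keeps the realized count near the
configured baseline regardless of the effect sizes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (
    AGE_CATEGORIES,
    AGE_GROUPS,
    CAUSE_GROUPS,
    CAUSE_LEAVES,
    SimulationConfig,
)

__all__ = [
    "AGE_CATEGORIES",
    "AGE_GROUPS",
    "CAUSE_GROUPS",
    "CAUSE_LEAVES",
    "LifeTable",
    "make_life_table",
    "simulate_exposure",
    "simulate_indicators",
    "simulate_mortality",
]

_DAYS_PER_YEAR = 365.25

INDICATOR_NAMES = (
    "population_density",
    "distance_to_parks",
    "hospital_beds_per_1000",
    "distance_to_emergency",
)


@dataclass(frozen=True)
class LifeTable:
    """Remaining life expectancy (years) by age group at death.

    Stores the four mutually exclusive age groups plus the pooled "total"
    category (a mixture-weighted average), so every one of the five age
    categories used in the analysis can be looked up.  Expectancy must be
    strictly decreasing across the four ordered exclusive groups.
    """

    expectancy: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AGE_CATEGORIES) - set(self.expectancy)
        if missing:
            raise ValueError(f"life table missing age categories: {sorted(missing)}")
        values = [float(self.expectancy[g]) for g in AGE_GROUPS]
        if any(v <= 0 for v in values) or self.expectancy["total"] <= 0:
            raise ValueError("remaining life expectancy must be positive")
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError(
                "remaining life expectancy must be non-increasing with age group"
            )

    def __getitem__(self, age_group: str) -> float:
        return float(self.expectancy[age_group])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": list(AGE_CATEGORIES),
                "remaining_life_expectancy": [self[g] for g in AGE_CATEGORIES],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        mapping = dict(
            zip(df["age_group"].astype(str), df["remaining_life_expectancy"])
        )
        if "total" not in mapping:
            weights = _DEFAULT_TOTAL_WEIGHTS
            mapping["total"] = sum(mapping[g] * w for g, w in weights.items())
        return cls(mapping)


_DEFAULT_TOTAL_WEIGHTS = {"0-59": 0.142, "60-69": 0.131, "70-79": 0.255, "80+": 0.472}

# Representative remaining life expectancies at age of death (years),
# loosely shaped like the 2017 national abridged life table.
_KOREA_LIKE_2017 = {"0-59": 40.0, "60-69": 22.5, "70-79": 13.9, "80+": 7.2}


def make_life_table(style: str = "korea-like-2017", constant: float = 10.0) -> LifeTable:
    """Return a built-in life table.

    ``"flat"`` assigns ``constant`` years to every age group (useful for
    analytic identities: YLL is then exactly ``constant`` times the excess
    deaths).  ``"korea-like-2017"`` is a realistic monotone table.
    """
    if style == "flat":
        return LifeTable({g: float(constant) for g in AGE_CATEGORIES})
    if style == "korea-like-2017":
        table = dict(_KOREA_LIKE_2017)
        table["total"] = sum(
            table[g] * w for g, w in _DEFAULT_TOTAL_WEIGHTS.items()
        )
        return LifeTable(table)
    raise ValueError(f"unknown life table style: {style!r}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent substreams per operation so exposure and mortality draws
    # do not interleave when one of them is re-run.
    return np.random.default_rng([int(config.seed), stream])


def _seasonal(day_of_year: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (day_of_year - peak_doy) / _DAYS_PER_YEAR)


def simulate_exposure(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the district-by-date exposure/weather table.

    One row per (district, date) with columns ``pm25``, ``no2``,
    ``temperature`` (Celsius), ``relative_humidity`` (%) and
    ``precipitation`` (mm).  PM2.5 is a district-level mean plus a winter-
    peaking seasonal sinusoid plus AR(1) noise, coupled to the temperature
    anomaly (stagnation-like co-variation) and truncated at zero.  NO2 is
    correlated with PM2.5 with configurable strength.  Deterministic for a
    given config and seed.
    """
    rng = _rng(config, 1)
    n_days = config.dates
    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    n_d = config.n_districts

    district_base = config.pm25_mean + config.pm25_district_sd * rng.standard_normal(n_d)

    # temperature: summer-peaking sinusoid + AR-free noise (anomaly)
    temp_season = config.temp_mean + _seasonal(doy, config.temp_seasonal_amplitude, 208.0)
    temp_anom = config.temp_noise_sd * rng.standard_normal((n_d, n_days))
    temperature = temp_season[None, :] + temp_anom

    # pm2.5: winter-peaking sinusoid + AR(1) noise + temperature coupling
    pm_season = _seasonal(doy, config.pm25_seasonal_amplitude, 15.0)
    innovations = rng.standard_normal((n_d, n_days))
    if config.pm25_ar1 > 0:
        innovation_sd = config.pm25_noise_sd * math.sqrt(1.0 - config.pm25_ar1**2)
        noise = lfilter([1.0], [1.0, -config.pm25_ar1], innovation_sd * innovations, axis=1)
    else:
        noise = config.pm25_noise_sd * innovations
    pm25 = (
        district_base[:, None]
        + pm_season[None, :]
        + noise
        + config.pm25_temp_coupling * temp_anom
    )
    np.clip(pm25, 0.0, None, out=pm25)

    # no2 correlated with pm2.5 through its deviation from the expected level
    pm_total_sd = math.sqrt(
        config.pm25_noise_sd**2
        + config.pm25_district_sd**2
        + 0.5 * config.pm25_seasonal_amplitude**2
        + (config.pm25_temp_coupling * config.temp_noise_sd) ** 2
    )
    rho = config.no2_pm25_corr
    pm_dev = pm25 - config.pm25_mean
    no2 = config.no2_mean + rho * (config.no2_sd / max(pm_total_sd, 1e-12)) * pm_dev
    no2 = no2 + math.sqrt(max(1.0 - rho**2, 0.0)) * config.no2_sd * rng.standard_normal(
        (n_d, n_days)
    )
    np.clip(no2, 0.0, None, out=no2)

    rh_season = config.rh_mean + _seasonal(doy, config.rh_seasonal_amplitude, 208.0)
    rh = rh_season[None, :] + config.rh_noise_sd * rng.standard_normal((n_d, n_days))
    np.clip(rh, 1.0, 100.0, out=rh)

    wet = rng.random((n_d, n_days)) < config.precip_wet_prob
    precip = np.where(
        wet, rng.exponential(config.precip_mean_mm, (n_d, n_days)), 0.0
    )

    out = pd.DataFrame(
        {
            "district_id": np.repeat(np.arange(n_d), n_days),
            "date": np.tile(dates.to_numpy(), n_d),
            "pm25": pm25.ravel(),
            "no2": no2.ravel(),
            "temperature": temperature.ravel(),
            "relative_humidity": rh.ravel(),
            "precipitation": precip.ravel(),
        }
    )
    return out


def simulate_indicators(config: SimulationConfig) -> pd.DataFrame:
    """Simulate district-level indicator values (one row per district).

    Values are independent lognormals per indicator; downstream tertile
    categorization gives the three-level structure used for effect
    modification.  Deterministic given the config seed.
    """
    rng = _rng(config, 3)
    n_d = config.n_districts
    out = pd.DataFrame({"district_id": np.arange(n_d)})
    scales = {
        "population_density": (math.log(1500.0), 1.0),
        "distance_to_parks": (math.log(1.2), 0.6),
        "hospital_beds_per_1000": (math.log(8.0), 0.5),
        "distance_to_emergency": (math.log(4.0), 0.7),
    }
    for name in INDICATOR_NAMES:
        mu, sd = scales[name]
        out[name] = rng.lognormal(mu, sd, n_d)
    return out


_HINGE_WIDTH = 3.0  # degC smoothing of the V-shaped temperature response


def _temperature_log_rate(temp_ma03: np.ndarray, config: SimulationConfig) -> np.ndarray:
    # smooth V/J shape: linear cold and heat wings joined by a softplus
    # hinge at the optimum, the shape reported for daily temperature-
    # mortality curves (linear wings keep the effect inside the span of a
    # natural cubic spline adjustment)
    optimum, cold_slope, heat_slope = config.temp_effect
    w = _HINGE_WIDTH
    cold = w * np.logaddexp(0.0, (optimum - temp_ma03) / w)
    heat = w * np.logaddexp(0.0, (temp_ma03 - optimum) / w)
    return cold_slope * cold + heat_slope * heat


def simulate_mortality(
    exposure: pd.DataFrame,
    config: SimulationConfig,
    district_categories: Mapping[int, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate individual mortality records from an exposure table.

    District-day death counts are Poisson with log mean ``log(baseline) +
    beta_true * x + f(temp)`` where ``x`` is the centred lag 0-1 PM2.5 mean
    and ``f`` the centred U-shaped function of the lag 0-3 temperature
    moving average; when ``district_categories`` maps districts to
    low/middle/high, the per-tertile ``interaction_shift`` is added to
    ``beta_true``.  Counts are exploded to one row per death with
    ``age_group``, ``cause`` (leaf label) and ``sex`` sampled from the
    configured mixtures.  The first three days of the series are excluded
    from case eligibility because the lagged covariates are undefined there.
    """
    rng = _rng(config, 2)
    required = pd.date_range(config.date_start, config.date_end, freq="D")
    df = exposure.sort_values(["district_id", "date"]).reset_index(drop=True)

    # verify full daily coverage for every district over the simulation window
    for district, g in df.groupby("district_id", sort=True):
        have = pd.DatetimeIndex(g["date"])
        missing = required.difference(have)
        if len(missing):
            raise ValueError(
                "exposure table missing required lag days: district "
                f"{district}, date {missing[0].date()}"
            )

    g = df.groupby("district_id", sort=True)
    x_lag01 = (df["pm25"] + g["pm25"].shift(1)) / 2.0
    temp_ma03 = (
        g["temperature"]
        .rolling(4, min_periods=4)
        .mean()
        .reset_index(level=0, drop=True)
    )

    day_index = g.cumcount()
    eligible = (day_index >= 3).to_numpy()

    x = x_lag01.to_numpy()[eligible]
    t = temp_ma03.to_numpy()[eligible]
    districts = df["district_id"].to_numpy()[eligible]
    dates = df["date"].to_numpy()[eligible]

    beta = np.full(x.shape, config.beta_true)
    if district_categories is not None:
        if isinstance(district_categories, pd.Series):
            district_categories = district_categories.to_dict()
        shift = dict(zip(("low", "middle", "high"), config.interaction_shift))
        beta = beta + np.array(
            [shift[district_categories[d]] for d in districts]
        )

    f_temp = _temperature_log_rate(t, config)
    log_lambda = (
        math.log(config.baseline_deaths_per_district_day)
        + beta * (x - x.mean())
        + (f_temp - f_temp.mean())
    )
    counts = rng.poisson(np.exp(log_lambda))

    total = int(counts.sum())
    rows = np.repeat(np.arange(x.size), counts)
    age = rng.choice(
        np.array(AGE_GROUPS, dtype=object),
        size=total,
        p=[config.age_mix[a] for a in AGE_GROUPS],
    )
    cause = rng.choice(
        np.array(CAUSE_LEAVES, dtype=object),
        size=total,
        p=[config.cause_mix[c] for c in CAUSE_LEAVES],
    )
    sex = np.where(rng.random(total) < config.sex_male_prob, "male", "female")

    return pd.DataFrame(
        {
            "date": dates[rows],
            "district_id": districts[rows],
            "age_group": age,
            "cause": cause,
            "sex": sex,
        }
    )


def write_simulation(
    outdir,
    config: SimulationConfig,
    life_table_style: str = "korea-like-2017",
) -> dict[str, str]:
    """Generate and write all four input tables as headered CSV files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    exposure = simulate_exposure(config)
    indicators = simulate_indicators(config)
    mortality = simulate_mortality(exposure, config)
    life = make_life_table(life_table_style)
    paths = {}
    for name, frame in (
        ("exposure", exposure),
        ("mortality", mortality),
        ("indicators", indicators),
        ("life_table", life.to_frame()),
    ):
        path = os.path.join(outdir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
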