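"""Configuration objects for simulation, model design and full study runs."""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Mutually exclusive age groups at death (years); "total" pools all four.
AGE_GROUPS = ("0-59", "60-69", "70-79", "80+")
AGE_CATEGORIES = ("total",) + AGE_GROUPS

#: Mutually exclusive "leaf" causes carried by individual records.
CAUSE_LEAVES = (
    "ischemic_heart",
    "cerebrovascular",
    "other_circulatory",
    "pneumonia",
    "chronic_lower_respiratory",
    "other_respiratory",
    "other_nonaccidental",
)

#: Analysis cause groups (three major + six specific) as sets of leaves.
#: Groups overlap: non-accidental contains everything, circulatory and
#: respiratory contain their three leaves each.
CAUSE_GROUPS: dict[str, tuple[str, ...]] = {
    "non_accidental": CAUSE_LEAVES,
    "circulatory": ("ischemic_heart", "cerebrovascular", "other_circulatory"),
    "respiratory": ("pneumonia", "chronic_lower_respiratory", "other_respiratory"),
    "ischemic_heart": ("ischemic_heart",),
    "cerebrovascular": ("cerebrovascular",),
    "other_circulatory": ("other_circulatory",),
    "pneumonia": ("pneumonia",),
    "chronic_lower_respiratory": ("chronic_lower_respiratory",),
    "other_respiratory": ("other_respiratory",),
}

# Default leaf mixture. The circulatory total (23.5%) and respiratory total
# (12.7%) match the national 2015-2019 descriptive shares; the split within
# each system is a plausible fixed choice (not published at leaf level).
_DEFAULT_CAUSE_MIX = {
    "ischemic_heart": 0.063,
    "cerebrovascular": 0.070,
    "other_circulatory": 0.102,
    "pneumonia": 0.070,
    "chronic_lower_respiratory": 0.022,
    "other_respiratory": 0.035,
    "other_nonaccidental": 0.638,
}

# National 2015-2019 age-at-death distribution of non-accidental mortality.
_DEFAULT_AGE_MIX = {"0-59": 0.142, "60-69": 0.131, "70-79": 0.255, "80+": 0.472}


def _as_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(value)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    The defaults describe the study conditions the package is validated
    under: 2015-2019 daily series, a national mean PM2.5 of 25.04 ug/m3,
    and a true log odds ratio per 1 ug/m3 (lag 0-1) of ``log(1.008)/10``.

    Parameters
    ----------
    beta_true : float
        Log rate ratio of mortality per 1 ug/m3 of lag 0-1 mean PM2.5.
    temp_effect : (float, float, float)
        ``(optimum_celsius, cold_slope, heat_slope)`` of the U-shaped
        temperature-mortality term: the log rate rises linearly (per degree
        Celsius) away from the optimum on each side, with a smooth 3-degree
        hinge at the optimum — the V/J shape reported for daily
        temperature-mortality associations.  The whole term is centred so
        the baseline count keeps its interpretation.
    interaction_shift : (float, float, float)
        Additive shift on ``beta_true`` for districts in the (low, middle,
        high) tertile of the active district indicator; all zero by default.
    """

    n_districts: int = 10
    date_start: dt.date = dt.date(2015, 1, 1)
    date_end: dt.date = dt.date(2019, 12, 31)
    beta_true: float = math.log(1.008) / 10.0
    pm25_mean: float = 25.04
    pm25_seasonal_amplitude: float = 8.0
    pm25_ar1: float = 0.5
    pm25_noise_sd: float = 6.0
    pm25_district_sd: float = 3.0
    pm25_temp_coupling: float = -0.3
    no2_mean: float = 22.0
    no2_pm25_corr: float = 0.6
    no2_sd: float = 8.0
    temp_mean: float = 12.5
    temp_seasonal_amplitude: float = 11.0
    temp_noise_sd: float = 3.0
    temp_effect: tuple[float, float, float] = (20.0, 0.012, 0.03)
    rh_mean: float = 65.0
    rh_seasonal_amplitude: float = 12.0
    rh_noise_sd: float = 8.0
    precip_wet_prob: float = 0.3
    precip_mean_mm: float = 5.0
    baseline_deaths_per_district_day: float = 1.0
    age_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE_MIX))
    cause_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CAUSE_MIX)
    )
    sex_male_prob: float = 0.5
    interaction_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.date_start = _as_date(self.date_start)
        self.date_end = _as_date(self.date_end)
        if self.date_end < self.date_start:
            raise ValueError("date_end must be on or after date_start")
        if self.n_districts < 1:
            raise ValueError("n_districts must be a positive integer")
        for name in (
            "beta_true",
            "pm25_mean",
            "pm25_seasonal_amplitude",
            "pm25_ar1",
            "pm25_noise_sd",
            "pm25_district_sd",
            "pm25_temp_coupling",
            "no2_mean",
            "no2_pm25_corr",
            "no2_sd",
            "temp_mean",
            "temp_seasonal_amplitude",
            "temp_noise_sd",
            "rh_mean",
            "rh_seasonal_amplitude",
            "rh_noise_sd",
            "precip_wet_prob",
            "precip_mean_mm",
            "baseline_deaths_per_district_day",
            "sex_male_prob",
        ):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"non-finite simulation parameter: {name}")
        if not all(math.isfinite(v) for v in self.temp_effect):
            raise ValueError("non-finite simulation parameter: temp_effect")
        if not all(math.isfinite(v) for v in self.interaction_shift):
            raise ValueError("non-finite simulation parameter: interaction_shift")
        if not (0.0 <= self.pm25_ar1 < 1.0):
            raise ValueError("pm25_ar1 must lie in [0, 1)")
        for label, mix, keys in (
            ("age_mix", self.age_mix, AGE_GROUPS),
            ("cause_mix", self.cause_mix, CAUSE_LEAVES),
        ):
            if set(mix) != set(keys):
                raise ValueError(f"{label} must have exactly the keys {keys}")
            total = math.fsum(mix.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{label} must sum to 1 (got {total!r})")

    @property
    def dates(self) -> int:
        return (self.date_end - self.date_start).days + 1

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("temp_effect", "interaction_shift"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


@dataclass
class DesignSpec:
    """Covariate design of the conditional logistic model.

    The default mirrors the main specification: a linear term for lag 0-1
    PM2.5 (per 1 ug/m3) adjusted for the lag 0-3 temperature moving average
    through a natural cubic spline with six degrees of freedom, plus linear
    relative humidity and precipitation.  Setting ``spline_weather`` splines
    humidity and precipitation too; ``include_no2`` adds lag 0-1 NO2
    linearly (double-pollutant sensitivity model).
    """

    exposure_col: str = "pm25_lag01"
    temp_col: str = "temp_ma03"
    temp_df: int = 6
    spline_weather: bool = False
    weather_df: int = 6
    include_no2: bool = False
    no2_col: str = "no2_lag01"
    rh_col: str = "relative_humidity"
    precip_col: str = "precipitation"
    extra_cols: tuple[str, ...] = ()

    def replace(self, **kwargs) -> "DesignSpec":
        return dataclasses.replace(self, **kwargs)

    def required_columns(self) -> tuple[str, ...]:
        cols = [self.exposure_col, self.temp_col, self.rh_col, self.precip_col]
        if self.include_no2:
            cols.append(self.no2_col)
        cols.extend(self.extra_cols)
        return tuple(cols)


@dataclass
class StudyConfig:
    """End-to-end study configuration (simulate -> match -> fit -> burden)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    causes: Sequence[str] = tuple(CAUSE_GROUPS)
    ages: Sequence[str] = AGE_CATEGORIES
    design: DesignSpec = field(default_factory=DesignSpec)
    indicators: Sequence[str] = (
        "population_density",
        "distance_to_parks",
        "hospital_beds_per_1000",
        "distance_to_emergency",
    )
    modification_causes: Sequence[str] = ("non_accidental", "circulatory", "respiratory")
    burden_threshold: float = 15.0
    burden_n_rep: int = 1000
    life_table_style: str = "korea-like-2017"
    run_sensitivity: bool = False
    sensitivity_lags: Sequence[str] = ("pm25_lag01", "pm25_lag02", "pm25_lag03")
    sensitivity_temp_df: Sequence[int] = (4, 6, 8)
    sensitivity_temp_cols: Sequence[str] = ("temp_ma01",)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.causes) - set(CAUSE_GROUPS)
        if unknown:
            raise ValueError(f"unknown cause groups: {sorted(unknown)}")
        unknown = set(self.ages) - set(AGE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown age categories: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], Mapping):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "design" in d and isinstance(d["design"], Mapping):
            d["design"] = DesignSpec(**d["design"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
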