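"""Attributable-fraction algebra, YLL and Monte-Carlo intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ccxburden as cx
from ccxburden.burden import attributable_burden, daily_attributable, total_burden


class TestDailyAttributable:
    def test_zero_beta_zero_burden(self):
        out = daily_attributable(0.0, [10.0, 30.0, 50.0], [5, 3, 1])
        assert np.allclose(out["af"], 0.0)
        assert np.allclose(out["excess_deaths"], 0.0)

    def test_closed_form_at_printed_constants(self):
        # beta per ug/m3 implied by OR 1.008 per 10 ug/m3, at the national
        # mean exposure level
        beta = 0.00079681
        out = daily_attributable(beta, [25.04], [1.0])
        assert out["af"][0] == pytest.approx(1 - math.exp(-beta * 25.04), abs=1e-15)
        assert out["af"][0] == pytest.approx(0.01976, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(
        beta=st.floats(-0.01, 0.01),
        x=st.floats(0.0, 150.0),
        deaths=st.integers(0, 500),
    )
    def test_algebraic_identity_rr_form(self, beta, x, deaths):
        # AF = (RR - 1) / RR with RR = exp(beta x)
        out = daily_attributable(beta, [x], [deaths])
        rr = math.exp(beta * x)
        assert out["af"][0] == pytest.approx(1 - 1 / rr, abs=1e-12)
        assert out["excess_deaths"][0] == pytest.approx(
            (1 - 1 / rr) * deaths, abs=1e-9
        )

    def test_counterfactual_attributes_increment_only(self):
        beta = 0.001
        out = daily_attributable(beta, [10.0, 20.0], [1.0, 1.0], counterfactual=15.0)
        assert out["af"][0] == 0.0
        assert out["af"][1] == pytest.approx(1 - math.exp(-beta * 5.0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            daily_attributable(0.001, [float("nan")], [1.0])


class TestTotalBurden:
    def _table(self, beta, x, deaths):
        att = daily_attributable(beta, x, deaths)
        return pd.DataFrame(
            {"x": x, "deaths": deaths, "excess_deaths": att["excess_deaths"]}
        )

    def test_all_days_below_threshold_gives_zero_who_fraction(self):
        t = self._table(0.001, [10.0, 12.0, 14.0], [5, 5, 5])
        out = total_burden(t, scope="who", threshold=15.0)
        assert out["excess_deaths"] == 0.0
        assert out["excess_fraction_pct"] == 0.0

    def test_constant_exposure_above_threshold_scope_identity(self):
        t = self._table(0.001, [25.0] * 10, [3] * 10)
        all_range = total_burden(t, scope="all")
        who = total_burden(t, scope="who")
        assert who == {**all_range, "scope": "who"}

    def test_fraction_is_percent_of_all_deaths(self):
        t = self._table(0.002, [10.0, 40.0], [100, 100])
        who = total_burden(t, scope="who", threshold=15.0)
        # only day 2 is in scope, denominator still both days
        expected = 100 * (1 - math.exp(-0.002 * 40.0)) * 100 / 200
        assert who["excess_fraction_pct"] == pytest.approx(expected)

    def test_who_scope_bounded_by_all_range_for_positive_beta(self):
        rng = np.random.default_rng(3)
        t = self._table(0.001, rng.uniform(0, 60, 50), rng.poisson(4, 50))
        assert (
            total_burden(t, scope="who")["excess_deaths"]
            <= total_burden(t, scope="all")["excess_deaths"]
        )

    def test_fraction_increasing_in_beta(self):
        x = np.linspace(5, 45, 20)
        deaths = np.full(20, 3.0)
        fracs = [
            total_burden(self._table(b, x, deaths), scope="all")["excess_fraction_pct"]
            for b in (0.0005, 0.001, 0.002, 0.004)
        ]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            total_burden(self._table(0.001, [], []))


class TestYll:
    def test_flat_table_is_constant_times_excess(self):
        lt = cx.make_life_table("flat", constant=20.0)
        excess = {"0-59": 4.0, "60-69": 3.0, "70-79": 2.0, "80+": 1.0}
        assert cx.yll(excess, lt) == pytest.approx(20.0 * 10.0)

    def test_zero_excess_zero_yll(self):
        lt = cx.make_life_table("korea-like-2017")
        assert cx.yll({g: 0.0 for g in cx.AGE_GROUPS}, lt) == 0.0

    def test_mixed_age_dot_product(self):
        lt = cx.LifeTable(
            {"total": 20.0, "0-59": 35.0, "60-69": 20.0, "70-79": 12.0, "80+": 6.0}
        )
        excess = {"0-59": 2.0, "60-69": 1.5, "70-79": 0.5}
        assert cx.yll(excess, lt) == pytest.approx(2 * 35 + 1.5 * 20 + 0.5 * 12)

    def test_missing_age_group_rejected(self):
        lt = cx.make_life_table("flat")
        with pytest.raises(KeyError, match="centenarian"):
            cx.yll({"centenarian": 1.0}, lt)


class TestMonteCarloCI:
    def test_zero_se_collapses_to_point(self):
        lo, hi = cx.monte_carlo_ci(0.002, 0.0, lambda b: 100 * b, n_rep=200, seed=1)
        assert lo == hi == pytest.approx(0.2)

    def test_deterministic_given_seed(self):
        f = lambda b: 1 - math.exp(-b * 25.0)
        a = cx.monte_carlo_ci(0.001, 0.0004, f, seed=7)
        b = cx.monte_carlo_ci(0.001, 0.0004, f, seed=7)
        assert a == b
        c = cx.monte_carlo_ci(0.001, 0.0004, f, n_rep=2000, seed=8)
        assert a != c
        assert abs(a[0] - c[0]) < 0.2 * abs(a[0])

    def test_linear_functional_matches_delta_method(self):
        beta, se = 0.001, 0.0003
        lo, hi = cx.monte_carlo_ci(
            beta, se, lambda b: 50.0 * b, n_rep=100_000, seed=3
        )
        z = 1.959963984540054
        assert lo == pytest.approx(50 * (beta - z * se), rel=2e-2)
        assert hi == pytest.approx(50 * (beta + z * se), rel=2e-2)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            cx.monte_carlo_ci(0.0, -1.0, lambda b: b)


class TestAssembledBurden:
    def test_null_fit_gives_null_burden(self, small_study):
        daily = cx.daily_deaths_table(
            small_study["records"], small_study["lagged"]
        )
        res = attributable_burden(daily, 0.0, 0.0, scope="all", n_rep=50, seed=0)
        assert res.excess_deaths == 0.0
        assert res.excess_fraction_ci == (0.0, 0.0)

    def test_death_counts_conserved(self, small_study):
        daily = cx.daily_deaths_table(small_study["records"], small_study["lagged"])
        # lag columns are defined from day 4 onward, and all records are
        # eligible by construction, so every death lands in the table
        assert daily["deaths"].sum() == len(small_study["records"])
        age_cols = [f"deaths_{g}" for g in cx.AGE_GROUPS]
        assert np.allclose(daily[age_cols].sum(axis=1), daily["deaths"])

    def test_district_additivity(self, small_study):
        daily = cx.daily_deaths_table(small_study["records"], small_study["lagged"])
        res = attributable_burden(daily, 0.0008, 0.0, n_rep=10, seed=0)
        per_district = [
            attributable_burden(g, 0.0008, 0.0, n_rep=10, seed=0).excess_deaths
            for _, g in daily.groupby("district_id")
        ]
        assert res.excess_deaths == pytest.approx(sum(per_district), rel=1e-10)

    def test_yll_with_flat_table_proportional_to_excess(self, small_study):
        daily = cx.daily_deaths_table(small_study["records"], small_study["lagged"])
        lt = cx.make_life_table("flat", constant=10.0)
        res = attributable_burden(
            daily, 0.0008, 0.0002, life_table=lt, n_rep=100, seed=4
        )
        assert res.excess_yll == pytest.approx(10.0 * res.excess_deaths, rel=1e-9)
        assert res.excess_yll_ci[0] == pytest.approx(
            10.0 * res.excess_deaths_ci[0], rel=1e-9
        )

    def test_who_totals_below_all_range(self, small_study):
        daily = cx.daily_deaths_table(small_study["records"], small_study["lagged"])
        all_r = attributable_burden(daily, 0.0008, 0.0002, scope="all", n_rep=50, seed=2)
        who = attributable_burden(daily, 0.0008, 0.0002, scope="who", n_rep=50, seed=2)
        assert who.excess_deaths <= all_r.excess_deaths
        assert who.excess_fraction_pct <= all_r.excess_fraction_pct
        # under the study-like regime (mean ~25, threshold 15) the restricted
        # fraction is well below the all-range fraction but not negligible
        ratio = who.excess_fraction_pct / all_r.excess_fraction_pct
        assert 0.05 < ratio < 1.0
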