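"""Conditional logistic likelihood and Newton fitter against oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import ccxburden as cx
from ccxburden.regression import clogit_loglik

from _util import random_matched_sets


def brute_force_loglik(ccdata, columns, beta):
    """Independent enumeration of the within-set softmax."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for _, g in ccdata.groupby("set_id"):
        eta = g[list(columns)].to_numpy(dtype=float) @ beta
        case_eta = eta[g["is_case"].to_numpy(dtype=bool)][0]
        total += case_eta - math.log(np.exp(eta).sum())
    return total


# printed six-set fixture: single exposure column, 1 case + 3 controls each
TINY_SETS = pd.DataFrame(
    {
        "set_id": sum([[s] * 4 for s in range(6)], []),
        "is_case": [True, False, False, False] * 6,
        "x": [
            31.2, 24.0, 18.5, 27.3,
            12.8, 15.1, 22.4, 9.6,
            28.9, 30.5, 19.7, 25.2,
            35.0, 21.6, 26.8, 29.4,
            17.3, 14.9, 20.2, 23.8,
            26.1, 33.7, 11.4, 16.0,
        ],
    }
)


class TestLoglik:
    def test_uniform_probability_at_beta_zero(self):
        cc = random_matched_sets(0, n_sets=40)
        # force sets of size 4
        cc = cc.groupby("set_id").head(4)
        cc = cc.groupby("set_id").filter(lambda g: g["is_case"].any())
        n_sets = cc["set_id"].nunique()
        ll, grad, hess = clogit_loglik(cc, [0.0, 0.0], columns=["x", "z"])
        assert ll == pytest.approx(-n_sets * math.log(4), rel=1e-12)

    def test_symmetric_pairs_maximized_at_zero(self):
        # 1:1 pairs with exposure differences +1 and -1: likelihood is an
        # even function of beta, maximized at 0
        cc = pd.DataFrame(
            {
                "set_id": [0, 0, 1, 1],
                "is_case": [True, False, True, False],
                "x": [1.0, 0.0, 0.0, 1.0],
            }
        )
        ll0, grad0, _ = clogit_loglik(cc, [0.0], columns=["x"])
        assert grad0[0] == pytest.approx(0.0, abs=1e-14)
        for b in (-0.5, 0.3, 1.0):
            ll, _, _ = clogit_loglik(cc, [b], columns=["x"])
            assert ll < ll0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cc = random_matched_sets(seed, n_sets=5)
        beta = rng.normal(0, 0.3, 2)
        ll, _, _ = clogit_loglik(cc, beta, columns=["x", "z"])
        assert ll == pytest.approx(
            brute_force_loglik(cc, ["x", "z"], beta), abs=1e-10
        )

    def test_gradient_matches_finite_differences(self):
        cc = random_matched_sets(9, n_sets=30)
        beta = np.array([0.02, -0.4])
        ll, grad, hess = clogit_loglik(cc, beta, columns=["x", "z"])
        eps = 1e-6
        for j in range(2):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += eps
            bm[j] -= eps
            lp, _, _ = clogit_loglik(cc, bp, columns=["x", "z"])
            lm, _, _ = clogit_loglik(cc, bm, columns=["x", "z"])
            assert grad[j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)
            # second differences at eps=1e-6 carry noticeable truncation error
            assert hess[j, j] == pytest.approx(
                (lp - 2 * ll + lm) / eps**2, rel=5e-3
            )

    def test_two_cases_in_a_set_rejected(self):
        cc = pd.DataFrame(
            {
                "set_id": [0, 0, 0],
                "is_case": [True, True, False],
                "x": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="set 0 has 2"):
            clogit_loglik(cc, [0.0], columns=["x"])


class TestFit:
    def test_tiny_fixture_matches_grid_search(self):
        fit = cx.fit_conditional_logistic(TINY_SETS, columns=["x"])
        grid = np.linspace(-0.5, 0.5, 200001)
        lls = np.array(
            [clogit_loglik(TINY_SETS, [b], columns=["x"])[0] for b in grid[::2000]]
        )
        coarse = grid[::2000][np.argmax(lls)]
        fine = np.linspace(coarse - 0.01, coarse + 0.01, 20001)
        lls = np.array(
            [clogit_loglik(TINY_SETS, [b], columns=["x"])[0] for b in fine]
        )
        assert fit.params["x"] == pytest.approx(fine[np.argmax(lls)], abs=1e-6)

    def test_matches_statsmodels_reference(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        cc = random_matched_sets(5, n_sets=200)
        fit = cx.fit_conditional_logistic(cc, columns=["x", "z"])
        ref = ConditionalLogit(
            cc["is_case"].astype(int), cc[["x", "z"]], groups=cc["set_id"]
        ).fit(method="newton", maxiter=200, disp=0)
        assert np.abs(fit.params.to_numpy() - ref.params.values).max() < 1e-6
        se = np.sqrt(np.diag(fit.cov))
        assert np.abs(se - ref.bse.values).max() < 1e-6

    def test_one_to_one_reduces_to_paired_logistic(self):
        # with one control per set, the conditional likelihood equals a
        # plain logistic likelihood on within-pair differences, no intercept
        rng = np.random.default_rng(11)
        rows = []
        for s in range(150):
            x = rng.normal(25, 8, 2)
            z = rng.normal(0, 1, 2)
            eta = 0.05 * x - 0.3 * z
            p = np.exp(eta) / np.exp(eta).sum()
            case = rng.choice(2, p=p)
            for j in range(2):
                rows.append(
                    {"set_id": s, "is_case": j == case, "x": x[j], "z": z[j]}
                )
        cc = pd.DataFrame(rows)
        fit = cx.fit_conditional_logistic(cc, columns=["x", "z"])

        import statsmodels.api as sm

        wide = cc.set_index(["set_id", "is_case"]).unstack()
        diff = wide.xs(True, axis=1, level=1) - wide.xs(False, axis=1, level=1)
        ref = sm.GLM(
            np.ones(len(diff)), diff[["x", "z"]], family=sm.families.Binomial()
        ).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params.values, atol=1e-6)

    def test_set_constant_covariate_leaves_beta_unchanged(self, small_study):
        cc = small_study["ccdata"].copy()
        base = cx.fit_conditional_logistic(cc)
        # set-constant covariate: one value per matched set
        rng = np.random.default_rng(0)
        const = pd.Series(
            rng.normal(size=cc["set_id"].nunique()),
            index=cc["set_id"].unique(),
        )
        cc["month_constant"] = cc["set_id"].map(const)
        spec = cx.DesignSpec(extra_cols=("month_constant",))
        with_const = cx.fit_conditional_logistic(cc, spec)
        assert (
            abs(with_const.beta_exposure - base.beta_exposure) < 1e-8
        )
        assert "month_constant" in with_const.dropped
        assert np.isnan(with_const.params["month_constant"])

    def test_or_conversion_per_10_units(self):
        # the printed convention: beta = 0.00079681 per ug/m3 -> OR 1.008
        assert math.exp(10 * 0.00079681) == pytest.approx(1.008, abs=5e-7)
        fit = cx.fit_conditional_logistic(TINY_SETS, columns=["x"])
        assert fit.or_per_10 == pytest.approx(
            math.exp(10 * fit.params["x"]), rel=1e-12
        )

    def test_aic_internal_consistency(self, small_study):
        fit = cx.fit_conditional_logistic(small_study["ccdata"])
        p = fit.params.notna().sum()
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * p, rel=1e-12)

    def test_exposure_without_variation_rejected(self):
        cc = pd.DataFrame(
            {
                "set_id": [0, 0, 1, 1],
                "is_case": [True, False, True, False],
                "x": [5.0, 5.0, 7.0, 7.0],
            }
        )
        with pytest.raises(ValueError, match="not identifiable"):
            cx.fit_conditional_logistic(cc, columns=["x"])

    def test_complete_separation_detected(self):
        # case always has the (much) larger exposure: beta diverges
        rows = []
        for s in range(30):
            rows.append({"set_id": s, "is_case": True, "x": 100.0 + s})
            rows.append({"set_id": s, "is_case": False, "x": float(s)})
        cc = pd.DataFrame(rows)
        fit = cx.fit_conditional_logistic(cc, columns=["x"], max_iter=200)
        assert not fit.converged
        assert "separation" in fit.message or "converge" in fit.message
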