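"""Conditional logistic regression for matched case-crossover sets.

The conditional likelihood for a matched set with one case among m rows is
the within-set softmax

    l(beta) = sum_sets [ x_case . beta - log sum_{j in set} exp(x_j . beta) ]

maximized by Newton-Raphson with analytic gradient and Hessian and
step-halving.  Set-constant covariates carry no information (their within-
set contribution to the gradient is identically zero); such columns are
detected and excluded from the optimization, which is exactly the
self-matching property of the design.

On top of the core fitter this module provides the analysis designs:
spline-adjusted main fits, tertile-interaction effect modification,
nonlinear exposure-response curves and AIC-based lag selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DesignSpec
from .spline import SplineBasis, natural_cubic_spline_basis

__all__ = [
    "FitResult",
    "InteractionResult",
    "build_design",
    "clogit_loglik",
    "exposure_response_curve",
    "fit_conditional_logistic",
    "fit_with_interaction",
    "select_lag_by_aic",
]

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# set bookkeeping


def _prepare_sets(ccdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (is_case, starts, sizes) after validating one case per set."""
    set_ids = ccdata["set_id"].to_numpy()
    if np.any(set_ids[1:] < set_ids[:-1]):
        raise ValueError("ccdata must be sorted by set_id")
    starts = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
    sizes = np.diff(np.r_[starts, set_ids.size])
    is_case = ccdata["is_case"].to_numpy(dtype=bool)
    cases_per_set = np.add.reduceat(is_case.astype(np.int64), starts)
    bad = np.flatnonzero(cases_per_set != 1)
    if bad.size:
        sid = set_ids[starts[bad[0]]]
        raise ValueError(
            f"matched set {sid} has {cases_per_set[bad[0]]} case rows (expected 1)"
        )
    return is_case, starts, sizes


def _loglik_core(
    X: np.ndarray,
    is_case: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    beta: np.ndarray,
    order: int = 2,
):
    """Log-likelihood and, optionally, analytic gradient and Hessian."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    m_rows = np.repeat(m, sizes)
    w = np.exp(eta - m_rows)
    Z = np.add.reduceat(w, starts)
    ll = float(eta[is_case].sum() - (np.log(Z) + m).sum())
    if order == 0:
        return ll, None, None
    p = w / np.repeat(Z, sizes)
    pX = p[:, None] * X
    M = np.add.reduceat(pX, starts, axis=0)  # per-set mean profile
    grad = X[is_case].sum(axis=0) - M.sum(axis=0)
    if order == 1:
        return ll, grad, None
    hess = -(X.T @ pX - M.T @ M)
    return ll, grad, hess


def clogit_loglik(
    ccdata: pd.DataFrame,
    beta,
    design: DesignSpec | None = None,
    columns: list[str] | None = None,
):
    """Conditional log-likelihood (and gradient, Hessian) at ``beta``.

    ``columns`` selects raw covariate columns of ``ccdata`` as the design
    matrix; otherwise the design matrix is built from ``design``
    (default :class:`DesignSpec`).  Returns ``(loglik, gradient, hessian)``.
    """
    is_case, starts, sizes = _prepare_sets(ccdata)
    if columns is not None:
        X = ccdata[list(columns)].to_numpy(dtype=float)
    else:
        X, _, _ = build_design(ccdata, design or DesignSpec())
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError("beta length does not match design matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return _loglik_core(X, is_case, starts, sizes, beta)


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    ccdata: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], dict]:
    """Build the design matrix for a :class:`DesignSpec`.

    The exposure term is always the first column.  Temperature (and, when
    ``spline_weather`` is set, humidity and precipitation) enters through a
    natural cubic spline whose knots are placed at quantiles of the
    analyzed rows; humidity and precipitation are linear by default.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    info: dict = {}

    blocks.append(ccdata[design.exposure_col].to_numpy(dtype=float)[:, None])
    names.append(design.exposure_col)

    def add_spline(col: str, df: int) -> None:
        basis = natural_cubic_spline_basis(
            ccdata[col].to_numpy(dtype=float), df=df, placement="quantile"
        )
        info[col] = basis
        blocks.append(basis.matrix)
        names.extend(f"{col}_ns{i+1}" for i in range(basis.df))

    add_spline(design.temp_col, design.temp_df)
    if design.spline_weather:
        add_spline(design.rh_col, design.weather_df)
        add_spline(design.precip_col, design.weather_df)
    else:
        for col in (design.rh_col, design.precip_col):
            blocks.append(ccdata[col].to_numpy(dtype=float)[:, None])
            names.append(col)
    if design.include_no2:
        blocks.append(ccdata[design.no2_col].to_numpy(dtype=float)[:, None])
        names.append(design.no2_col)
    for col in design.extra_cols:
        blocks.append(ccdata[col].to_numpy(dtype=float)[:, None])
        names.append(col)

    X = np.hstack(blocks)
    return X, names, info


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit.

    ``params``/``cov`` are indexed by column name; columns excluded as
    set-constant carry NaN coefficients.  ``or_per_10`` is ``exp(10 *
    beta_exposure)`` — the odds ratio per 10 ug/m3 when the exposure is in
    ug/m3 — with a Wald 95% interval.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    n_sets: int
    exposure: str
    converged: bool
    n_iter: int
    message: str = ""
    dropped: tuple[str, ...] = ()
    info: dict = field(default_factory=dict, repr=False)

    @property
    def beta_exposure(self) -> float:
        return float(self.params[self.exposure])

    @property
    def se_exposure(self) -> float:
        return float(np.sqrt(self.cov.loc[self.exposure, self.exposure]))

    @property
    def or_per_10(self) -> float:
        return math.exp(10.0 * self.beta_exposure)

    @property
    def ci95(self) -> tuple[float, float]:
        b, se = self.beta_exposure, self.se_exposure
        return (
            math.exp(10.0 * (b - _Z975 * se)),
            math.exp(10.0 * (b + _Z975 * se)),
        )

    def summary_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "beta": self.beta_exposure,
            "se": self.se_exposure,
            "or_per_10": self.or_per_10,
            "or_lo": lo,
            "or_hi": hi,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_sets": self.n_sets,
            "converged": self.converged,
        }


def _fit_matrix(
    X: np.ndarray,
    names: list[str],
    is_case: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    exposure: str,
    tol: float = 1e-8,
    max_iter: int = 100,
    info: dict | None = None,
) -> FitResult:
    n_sets = starts.size

    # set-constant columns carry no information: exclude from optimization
    set_means = np.repeat(
        np.add.reduceat(X, starts, axis=0) / sizes[:, None], sizes, axis=0
    )
    within_dev = np.abs(X - set_means).max(axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    informative = within_dev > 1e-10 * scale
    dropped = tuple(n for n, keep in zip(names, informative) if not keep)
    if exposure in dropped:
        raise ValueError(
            "exposure has no within-set variation; model is not identifiable"
        )
    Xa = X[:, informative]
    kept = [n for n, keep in zip(names, informative) if keep]

    # standardize internally so the gradient tolerance is meaningful across
    # columns of very different scale (e.g. cubic spline terms); centring is
    # likelihood-invariant and scaling a pure reparametrization, so the
    # reported coefficients are transformed back exactly
    centre = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd[sd == 0] = 1.0
    Xa = (Xa - centre) / sd

    beta = np.zeros(Xa.shape[1])
    ll, grad, hess = _loglik_core(Xa, is_case, starts, sizes, beta)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            converged = True
            break
        fisher = -hess
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(fisher, grad, rcond=None)[0]
        # Newton decrement: estimated log-likelihood gap to the optimum.
        # Near machine precision the gradient itself can stall just above
        # an absolute tolerance; a gap far below float64 noise in the
        # log-likelihood means the maximizer is reached.
        if 0.0 <= float(grad @ step) / 2.0 < 1e-12:
            converged = True
            break
        # step-halving keeps the likelihood monotone
        t = 1.0
        improved = False
        for _ in range(40):
            cand = beta + t * step
            ll_new, _, _ = _loglik_core(Xa, is_case, starts, sizes, cand, order=0)
            if ll_new >= ll - 1e-12:
                improved = True
                break
            t *= 0.5
        if not improved:
            message = "step-halving failed to improve the likelihood"
            break
        beta = beta + t * step
        ll, grad, hess = _loglik_core(Xa, is_case, starts, sizes, beta)
    else:
        message = f"did not converge in {max_iter} iterations"
    if converged and ll > -1e-6:
        # the conditional likelihood of a finite MLE is strictly negative;
        # a numerically perfect fit means the case is always the most
        # exposed profile and the true maximizer lies at infinity
        converged = False
        message = "complete separation suspected: perfect within-set prediction"
    if converged:
        message = message or "converged"

    fisher = -hess
    try:
        cov_a = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov_a = np.linalg.pinv(fisher)

    # undo the internal standardization
    beta = beta / sd
    cov_a = cov_a / np.outer(sd, sd)

    params = pd.Series(np.nan, index=names)
    params[kept] = beta
    cov = pd.DataFrame(np.nan, index=names, columns=names)
    cov.loc[kept, kept] = cov_a
    p = len(kept)
    return FitResult(
        params=params,
        cov=cov,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * p,
        n_sets=int(n_sets),
        exposure=exposure,
        converged=converged,
        n_iter=it,
        message=message,
        dropped=dropped,
        info=info or {},
    )


def fit_conditional_logistic(
    ccdata: pd.DataFrame,
    design: DesignSpec | None = None,
    columns: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit the conditional logistic model by Newton-Raphson.

    ``design`` (default :class:`DesignSpec`) specifies the standard
    exposure + spline-confounder design; alternatively ``columns`` names
    raw covariate columns to use directly (first column = exposure).
    Convergence is declared at max-norm of the gradient below ``tol``.
    """
    is_case, starts, sizes = _prepare_sets(ccdata)
    if columns is not None:
        X = ccdata[list(columns)].to_numpy(dtype=float)
        names = list(columns)
        info: dict = {}
    else:
        X, names, info = build_design(ccdata, design or DesignSpec())
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return _fit_matrix(
        X, names, is_case, starts, sizes, names[0], tol=tol, max_iter=max_iter, info=info
    )


# ---------------------------------------------------------------------------
# effect modification


@dataclass
class InteractionResult:
    """Per-tertile odds ratios and interaction tests.

    ``ors`` maps category -> (OR per 10 ug/m3, lo, hi); a category with no
    informative sets comes out NaN.  ``p_middle``/``p_high`` are two-sided
    Wald p-values on the interaction contrasts against the low tertile
    (H0: no difference in OR between categories).
    """

    ors: dict[str, tuple[float, float, float]]
    p_middle: float
    p_high: float
    fit: FitResult


def fit_with_interaction(
    ccdata: pd.DataFrame,
    category,
    design: DesignSpec | None = None,
    **kwargs,
) -> InteractionResult:
    """Fit with PM2.5 x tertile interaction terms (low = reference).

    ``category`` is either the name of a column of ``ccdata`` or a Series
    aligned with its rows, with values in {"low", "middle", "high"}; the
    label must be constant within each matched set (it is a district-level,
    study-period attribute).
    """
    design = design or DesignSpec()
    if isinstance(category, str):
        cat = ccdata[category]
    else:
        cat = pd.Series(np.asarray(category), index=ccdata.index)
    bad = ~cat.isin(("low", "middle", "high"))
    if bad.any():
        raise ValueError(f"unknown indicator categories: {sorted(cat[bad].unique())}")

    work = ccdata.copy()
    x = work[design.exposure_col].to_numpy(dtype=float)
    work["_x_middle"] = x * (cat == "middle").to_numpy()
    work["_x_high"] = x * (cat == "high").to_numpy()
    design_i = design.replace(extra_cols=design.extra_cols + ("_x_middle", "_x_high"))
    fit = fit_conditional_logistic(work, design_i, **kwargs)

    b = fit.params
    V = fit.cov
    e = design.exposure_col

    def category_or(extra: str | None) -> tuple[float, float, float]:
        if extra is None:
            est = b[e]
            var = V.loc[e, e]
        else:
            est = b[e] + b[extra]
            var = V.loc[e, e] + V.loc[extra, extra] + 2.0 * V.loc[e, extra]
        if not np.isfinite(est) or not np.isfinite(var):
            return (float("nan"),) * 3
        se = math.sqrt(var)
        return (
            math.exp(10.0 * est),
            math.exp(10.0 * (est - _Z975 * se)),
            math.exp(10.0 * (est + _Z975 * se)),
        )

    def wald_p(name: str) -> float:
        est, var = b[name], V.loc[name, name]
        if not np.isfinite(est) or not np.isfinite(var) or var <= 0:
            return float("nan")
        from scipy.stats import norm

        return float(2.0 * norm.sf(abs(est) / math.sqrt(var)))

    ors = {
        "low": category_or(None),
        "middle": category_or("_x_middle"),
        "high": category_or("_x_high"),
    }
    return InteractionResult(
        ors=ors, p_middle=wald_p("_x_middle"), p_high=wald_p("_x_high"), fit=fit
    )


# ---------------------------------------------------------------------------
# nonlinear exposure-response


def exposure_response_curve(
    ccdata: pd.DataFrame,
    design: DesignSpec | None = None,
    n_internal_knots: int = 3,
    grid=None,
    x_ref: float | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Flexible exposure-response curve with pointwise Wald bands.

    Replaces the linear exposure term with a natural cubic spline whose
    ``n_internal_knots`` internal knots are equally spaced over the
    observed exposure range.  The curve is the odds ratio relative to
    ``x_ref`` (default: minimum observed exposure), evaluated on ``grid``
    (default: 100 points over the observed range).
    """
    design = design or DesignSpec()
    x = ccdata[design.exposure_col].to_numpy(dtype=float)
    basis = natural_cubic_spline_basis(
        x, df=n_internal_knots + 1, placement="uniform"
    )
    work = ccdata.copy()
    spline_names = []
    for i in range(basis.df):
        name = f"_er_ns{i+1}"
        work[name] = basis.matrix[:, i]
        spline_names.append(name)

    # confounders only; the first spline column stands in as "exposure"
    conf = design.replace(exposure_col=spline_names[0], extra_cols=design.extra_cols + tuple(spline_names[1:]))
    fit = fit_conditional_logistic(work, conf, **kwargs)

    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    ref = float(x.min()) if x_ref is None else float(x_ref)

    beta_s = fit.params[spline_names].to_numpy()
    V = fit.cov.loc[spline_names, spline_names].to_numpy()
    contrast = basis.evaluate(grid) - basis.evaluate(np.array([ref]))
    log_or = contrast @ beta_s
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, V, contrast))
    out = pd.DataFrame(
        {
            "x": grid,
            "or": np.exp(log_or),
            "or_lo": np.exp(log_or - _Z975 * se),
            "or_hi": np.exp(log_or + _Z975 * se),
        }
    )
    out.attrs["x_ref"] = ref
    out.attrs["fit"] = fit
    return out


# ---------------------------------------------------------------------------
# lag selection


def select_lag_by_aic(
    ccdata: pd.DataFrame,
    lag_cols: tuple[str, ...] = ("pm25_lag01", "pm25_lag02", "pm25_lag03"),
    design: DesignSpec | None = None,
    **kwargs,
) -> tuple[str, pd.DataFrame]:
    """Choose the exposure lag window by AIC on identical matched sets.

    Sets missing any candidate lag column are removed first so every
    candidate model sees the same data.  Ties break deterministically
    toward the earliest (shortest) candidate in ``lag_cols``.
    """
    design = design or DesignSpec()
    missing = [c for c in lag_cols if c not in ccdata.columns]
    if missing:
        raise ValueError(f"candidate lag columns absent: {missing}")
    bad_rows = ccdata[list(lag_cols)].isna().any(axis=1)
    bad_sets = ccdata.loc[bad_rows, "set_id"].unique()
    work = ccdata[~ccdata["set_id"].isin(bad_sets)]

    rows = []
    fits = {}
    for col in lag_cols:
        fit = fit_conditional_logistic(work, design.replace(exposure_col=col), **kwargs)
        fits[col] = fit
        rows.append({"lag": col, "aic": fit.aic, "loglik": fit.loglik, **{
            "beta": fit.beta_exposure, "se": fit.se_exposure, "n_sets": fit.n_sets
        }})
    table = pd.DataFrame(rows)
    best = table.loc[table["aic"].idxmin(), "lag"]  # idxmin -> first minimum
    table.attrs["fits"] = fits
    return str(best), table
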