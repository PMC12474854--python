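"""Natural cubic spline bases with stored knots.

The basis is the classical truncated-power construction of a natural cubic
spline: piecewise cubic between knots, constrained to be linear beyond the
boundary knots.  With K knots in total (internal plus the two boundary
knots) the basis has K-1 columns once the intercept is excluded — the
intercept is omitted because in a conditional logistic model any
set-constant column cancels from the likelihood.

Two placement rules are supported, matching the two uses in the analysis:
``df``-mode places internal knots at equally spaced quantiles of the data
(boundary knots at min/max) for confounder adjustment, and explicit-knot
mode at equally spaced locations over the observed range for the nonlinear
exposure-response curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "natural_cubic_spline_basis"]


@dataclass
class SplineBasis:
    """A natural cubic spline basis evaluable at new points.

    Attributes
    ----------
    internal_knots, boundary_knots : ndarray / (float, float)
        Stored knot locations; evaluation at new x uses these, so fitted
        curves extend linearly outside the boundary.
    matrix : ndarray, shape (n, df)
        Basis evaluated at the construction points.
    """

    internal_knots: np.ndarray
    boundary_knots: tuple[float, float]
    matrix: np.ndarray = field(repr=False)

    @property
    def df(self) -> int:
        return self.matrix.shape[1]

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate([[lo], np.asarray(self.internal_knots, float), [hi]])

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new points using the stored knots."""
        return _ncs_design(np.asarray(x, dtype=float), self.all_knots)


def _ncs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (no intercept).

    For knots t_1 < ... < t_K the columns are x and
    d_k(x) - d_{K-1}(x), k = 1..K-2, with
    d_k(x) = ((x - t_k)_+^3 - (x - t_K)_+^3) / (t_K - t_k).
    Each column is linear outside [t_1, t_K], so any linear combination is
    a natural cubic spline; the column x makes the basis reproduce linear
    functions exactly.
    """
    K = len(knots)
    t_last = knots[-1]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - t_last, 0.0, None) ** 3
        return num / (t_last - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def natural_cubic_spline_basis(
    x,
    df: int | None = None,
    internal_knots=None,
    placement: str = "quantile",
) -> SplineBasis:
    """Construct a natural cubic spline basis for ``x``.

    Parameters
    ----------
    df : int, optional
        Number of basis columns.  Internal knots (``df - 1`` of them) are
        placed at equally spaced quantiles of ``x`` (``placement=
        "quantile"``) or equally spaced over the range (``placement=
        "uniform"``); boundary knots at min/max.
    internal_knots : array-like, optional
        Explicit internal knot locations (mutually exclusive with ``df``);
        if a plain count is wanted use ``df = n_internal + 1``.

    Notes
    -----
    ``df >= 1`` is required; ``df = 1`` degenerates to the linear column
    alone.  The construction needs at least ``df + 1`` distinct values in
    ``x`` so that all knots are distinct.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if (df is None) == (internal_knots is None):
        raise ValueError("specify exactly one of df or internal_knots")

    lo, hi = float(np.min(x)), float(np.max(x))
    if internal_knots is not None:
        knots_in = np.sort(np.asarray(internal_knots, dtype=float))
    else:
        if df < 1:
            raise ValueError("df must be >= 1")
        n_internal = df - 1
        if placement == "quantile":
            probs = np.arange(1, n_internal + 1) / (n_internal + 1)
            knots_in = np.quantile(x, probs)
        elif placement == "uniform":
            knots_in = lo + (hi - lo) * np.arange(1, n_internal + 1) / (n_internal + 1)
        else:
            raise ValueError(f"unknown placement: {placement!r}")

    all_knots = np.concatenate([[lo], knots_in, [hi]])
    if np.unique(all_knots).size != all_knots.size:
        raise ValueError(
            "knots are not distinct; x has too few distinct values for the "
            "requested degrees of freedom"
        )
    basis = SplineBasis(
        internal_knots=np.asarray(knots_in, float),
        boundary_knots=(lo, hi),
        matrix=_ncs_design(x, all_knots),
    )
    return basis
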