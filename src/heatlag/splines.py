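"""Spline basis construction for DLNM exposure- and lag-response functions.

Two families are provided:

* ``quadratic_bspline`` — degree-2 B-splines (Cox–de Boor, via
  :class:`scipy.interpolate.BSpline`), the exposure-response basis.  The full
  basis (``intercept=True``) is a partition of unity; without the intercept
  the first column of the full basis is dropped, so the default summer
  configuration (one interior knot at the location's 75th temperature
  percentile, no intercept) has 3 columns.
* ``natural_cubic`` — natural cubic splines with zero second derivative at
  the boundary knots, built by projecting a cubic B-spline basis onto the
  natural constraint (the R ``ns()`` construction).  ``intercept=True``
  prepends a literal column of ones, so the default lag-response basis
  (intercept + 2 interior knots log-spaced on lags 0–10) has 4 columns.

Points outside the boundary interval are evaluated by linear extrapolation
from the nearest boundary (the natural-spline convention, applied to both
families) and flagged in :attr:`BasisMatrix.out_of_range`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "BasisMatrix",
    "eval_basis",
    "eval_quadratic_bspline",
    "eval_natural_cubic",
    "log_spaced_lag_knots",
    "percentile_knots",
]

_FAMILIES = ("quadratic_bspline", "natural_cubic", "constant")


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a one-dimensional spline basis.

    Parameters
    ----------
    family : {"quadratic_bspline", "natural_cubic"}
    knots : tuple of float
        Interior knots, strictly inside ``boundary`` and strictly increasing.
    boundary : (float, float)
        Boundary knots ``[min, max]``.
    intercept : bool
        Whether the basis spans the constant function.
    """

    family: str
    knots: tuple[float, ...]
    boundary: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown spline family {self.family!r}")
        lo, hi = self.boundary
        ok = lo <= hi if self.family == "constant" else lo < hi
        if not (np.isfinite(lo) and np.isfinite(hi)) or not ok:
            raise ValueError(f"invalid boundary {self.boundary!r}")
        ks = tuple(float(k) for k in self.knots)
        if any(not lo < k < hi for k in ks):
            raise ValueError(f"interior knots {ks} not strictly inside {self.boundary}")
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise ValueError(f"interior knots must be strictly increasing, got {ks}")
        object.__setattr__(self, "knots", ks)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def df(self) -> int:
        """Number of basis columns."""
        n = len(self.knots)
        if self.family == "constant":
            return 1
        if self.family == "quadratic_bspline":
            return n + 2 + (1 if self.intercept else 0)
        return n + 1 + (1 if self.intercept else 0)


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: ``values`` is ``len(points) x spec.df``."""

    values: np.ndarray
    spec: SplineSpec
    points: np.ndarray
    out_of_range: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.out_of_range is None:
            lo, hi = self.spec.boundary
            oob = (self.points < lo) | (self.points > hi)
            object.__setattr__(self, "out_of_range", oob)


def _full_knot_vector(spec: SplineSpec, degree: int) -> np.ndarray:
    lo, hi = spec.boundary
    return np.concatenate([[lo] * (degree + 1), spec.knots, [hi] * (degree + 1)])


def _bspline_design(x: np.ndarray, t: np.ndarray, degree: int, deriv: int = 0) -> np.ndarray:
    """All B-spline basis functions (columns) at points x, via Cox–de Boor."""
    n_basis = len(t) - degree - 1
    b = BSpline(t, np.eye(n_basis), degree, extrapolate=False)
    if deriv:
        b = b.derivative(deriv)
    out = b(x)
    return np.nan_to_num(out, nan=0.0)


def _eval_linear_extrapolated(x: np.ndarray, value_fn, deriv_fn, boundary) -> np.ndarray:
    """Evaluate a basis with linear extrapolation beyond the boundary knots."""
    lo, hi = boundary
    xc = np.clip(x, lo, hi)
    vals = value_fn(xc)
    below = x < lo
    above = x > hi
    if below.any():
        vals[below] += (x[below] - lo)[:, None] * deriv_fn(np.array([lo]))
    if above.any():
        vals[above] += (x[above] - hi)[:, None] * deriv_fn(np.array([hi]))
    return vals


def eval_quadratic_bspline(points, spec: SplineSpec) -> BasisMatrix:
    """Degree-2 B-spline basis at ``points``.

    The full basis (``intercept=True``) has ``len(knots) + 3`` columns and
    its rows sum to one inside the boundary; with ``intercept=False`` the
    first column of the full basis is dropped.
    """
    if spec.family != "quadratic_bspline":
        raise ValueError(f"spec family is {spec.family!r}, expected 'quadratic_bspline'")
    x = np.atleast_1d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation points must be finite")
    t = _full_knot_vector(spec, degree=2)
    vals = _eval_linear_extrapolated(
        x,
        lambda z: _bspline_design(z, t, 2),
        lambda z: _bspline_design(z, t, 2, deriv=1),
        spec.boundary,
    )
    if not spec.intercept:
        vals = vals[:, 1:]
    return BasisMatrix(values=vals, spec=spec, points=x)


def _natural_constraint_projection(t: np.ndarray, boundary) -> np.ndarray:
    """Projection matrix removing the 2 boundary-curvature degrees of freedom.

    QR of the transposed constraint matrix (second derivatives of the cubic
    B-spline basis at the two boundary knots); the trailing columns of Q span
    the natural-spline subspace.
    """
    const = _bspline_design(np.asarray(boundary, dtype=float), t, 3, deriv=2)
    q, _ = np.linalg.qr(const.T, mode="complete")
    return q[:, 2:]


def eval_natural_cubic(points, spec: SplineSpec) -> BasisMatrix:
    """Natural cubic spline basis at ``points``.

    Zero second derivative at both boundary knots; linear beyond them.  With
    ``intercept=True`` a column of ones is prepended (the basis then spans
    constants); the remaining columns are the R ``ns()`` basis with its first
    column dropped.
    """
    if spec.family != "natural_cubic":
        raise ValueError(f"spec family is {spec.family!r}, expected 'natural_cubic'")
    x = np.atleast_1d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation points must be finite")
    t = _full_knot_vector(spec, degree=3)
    h = _natural_constraint_projection(t, spec.boundary)
    vals = _eval_linear_extrapolated(
        x,
        lambda z: _bspline_design(z, t, 3) @ h,
        lambda z: _bspline_design(z, t, 3, deriv=1) @ h,
        spec.boundary,
    )
    # drop the column standing in for the constant; optionally put back an
    # explicit ones column (the DLNM lag-basis convention)
    vals = vals[:, 1:]
    if spec.intercept:
        vals = np.column_stack([np.ones(len(x)), vals])
    return BasisMatrix(values=vals, spec=spec, points=x)


def eval_basis(points, spec: SplineSpec) -> BasisMatrix:
    """Dispatch to the family-specific evaluator."""
    if spec.family == "quadratic_bspline":
        return eval_quadratic_bspline(points, spec)
    if spec.family == "constant":
        x = np.atleast_1d(np.asarray(points, dtype=float))
        return BasisMatrix(values=np.ones((len(x), 1)), spec=spec, points=x)
    return eval_natural_cubic(points, spec)


def log_spaced_lag_knots(lag_max: float = 10, n_knots: int = 2) -> np.ndarray:
    """Interior lag knots equally spaced on the log-lag scale.

    ``exp(k * log(lag_max) / (n_knots + 1))`` for ``k = 1..n_knots``; with
    the defaults (lag 10, 2 knots) this gives ``10**(1/3), 10**(2/3)``.
    """
    if lag_max < 2:
        raise ValueError("lag_max must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    k = np.arange(1, n_knots + 1)
    return np.exp(k * np.log(lag_max) / (n_knots + 1))


def percentile_knots(series, percentiles) -> np.ndarray:
    """Empirical percentiles of a temperature series (type-7 quantiles)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    knots = np.percentile(x, np.atleast_1d(percentiles), method="linear")
    if np.unique(knots).size < knots.size:
        raise ValueError(f"tied percentiles produce duplicate knots: {knots}")
    return knots
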