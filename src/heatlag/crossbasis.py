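"""DLNM cross-basis: tensor product of exposure and lag spline bases.

The cross-basis row for day ``t`` is

    cb[t, (j, k)] = sum_{l=0}^{lag_max} R_j(x[t-l]) * C_k(l)

with ``R`` the exposure-response basis evaluated at the lagged temperatures
and ``C`` the lag-response basis evaluated at integer lags.  Columns are
ordered exposure-major: column index ``(j, k) -> j * df_lag + k``.

Series are seasonal (summer-only): lag windows never cross between summers.
Rows whose window would reach before the start of their summer segment are
marked unusable unless burn-in temperatures (rows with ``day_of_season <= 0``)
are part of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from heatlag.splines import BasisMatrix, SplineSpec, eval_basis

__all__ = ["CrossBasis", "InteractionBasis", "build_crossbasis", "build_interaction"]


@dataclass(frozen=True)
class CrossBasis:
    """Cross-basis matrix with its generating specs.

    ``values`` is ``n x (df_exposure * df_lag)``; ``usable`` marks rows with a
    complete within-summer lag window (unusable rows are zero-filled).
    """

    values: np.ndarray
    exposure_spec: SplineSpec
    lag_spec: SplineSpec
    lag_range: tuple[int, int]
    usable: np.ndarray

    @property
    def df_exposure(self) -> int:
        return self.exposure_spec.df

    @property
    def df_lag(self) -> int:
        return self.lag_spec.df

    @property
    def lag_values(self) -> np.ndarray:
        """Integer lags at which the lag basis is evaluated."""
        return np.arange(self.lag_range[0], self.lag_range[1] + 1)

    def lag_basis(self) -> BasisMatrix:
        return eval_basis(self.lag_values, self.lag_spec)

    def exposure_basis(self, points) -> BasisMatrix:
        return eval_basis(points, self.exposure_spec)


@dataclass(frozen=True)
class InteractionBasis:
    """Cross-basis columns multiplied row-wise by centred day of season."""

    values: np.ndarray
    center_day: float
    crossbasis: CrossBasis


def _as_segments(n: int, segments) -> np.ndarray:
    if segments is None:
        return np.zeros(n, dtype=int)
    seg = np.asarray(segments)
    if seg.shape != (n,):
        raise ValueError("segments must align with the temperature series")
    return seg


def build_crossbasis(
    temps,
    exposure_spec: SplineSpec,
    lag_spec: SplineSpec,
    *,
    lag_range: tuple[int, int] = (0, 10),
    segments=None,
) -> CrossBasis:
    """Build the cross-basis for a (possibly multi-summer) temperature series.

    Parameters
    ----------
    temps : array-like
        Daily mean temperatures in time order, burn-in days included.
    exposure_spec, lag_spec : SplineSpec
        Exposure-response and lag-response bases.
    lag_range : (int, int)
        Inclusive lag window in days, default ``(0, 10)``.
    segments : array-like of int, optional
        Summer identifier per row; lag windows never cross a segment change.
        Omitted means a single continuous segment.
    """
    x = np.asarray(temps, dtype=float)
    lag0, lag1 = lag_range
    if lag0 != 0:
        raise ValueError("lag_range must start at 0")
    if x.ndim != 1 or x.size < lag1 + 1:
        raise ValueError(f"series must be 1-d with length > lag_max={lag1}")
    n = x.size
    seg = _as_segments(n, segments)

    r = eval_basis(x, exposure_spec).values                      # n x df_x
    c = eval_basis(np.arange(lag0, lag1 + 1), lag_spec).values   # (lag1+1) x df_l
    df_x, df_l = r.shape[1], c.shape[1]

    # rlag[t, l, :] = R(x[t-l]); usable only when t-l stays in t's segment
    rlag = np.zeros((n, lag1 + 1, df_x))
    usable = np.ones(n, dtype=bool)
    idx = np.arange(n)
    for lag in range(lag0, lag1 + 1):
        src = idx - lag
        ok = src >= 0
        rlag[ok, lag, :] = r[src[ok]]
        same_seg = ok.copy()
        same_seg[ok] &= seg[src[ok]] == seg[ok]
        usable &= same_seg

    values = np.einsum("tlj,lk->tjk", rlag, c).reshape(n, df_x * df_l)
    values[~usable] = 0.0
    return CrossBasis(
        values=values,
        exposure_spec=exposure_spec,
        lag_spec=lag_spec,
        lag_range=(lag0, lag1),
        usable=usable,
    )


def build_interaction(cb: CrossBasis, day_of_season, center_day: float) -> InteractionBasis:
    """Cross-basis x (day_of_season - center_day) interaction block.

    The main cross-basis coefficients of a model containing this block are
    then interpreted as the exposure-lag-response surface on day
    ``center_day`` of the season.
    """
    dos = np.asarray(day_of_season, dtype=float)
    if dos.shape != (cb.values.shape[0],):
        raise ValueError("day_of_season must align with cross-basis rows")
    values = cb.values * (dos - float(center_day))[:, None]
    return InteractionBasis(values=values, center_day=float(center_day), crossbasis=cb)
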