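"""Reduction of cross-basis coefficients to one-dimensional summaries.

A fitted cross-basis carries ``df_x * df_l`` coefficients describing the full
exposure-lag-response surface.  Two linear maps collapse them, with exact
covariance propagation ``M V M'``:

* overall cumulative: summing the lag basis over integer lags 0..10 yields
  ``df_x`` coefficients of the exposure basis for the lag-cumulated
  exposure-response curve;
* lag-response at ``x*``: contrasting the exposure basis between ``x*`` and a
  reference ``x_ref`` yields ``df_l`` coefficients of the lag basis for the
  lag-response curve of a day at ``x*``.

For the time-varying model, :func:`predict_at_day` translates the joint
(main, interaction) coefficient block to any day of season before reduction:
``theta(d) = theta_main + (d - d0) * theta_int``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from heatlag.crossbasis import CrossBasis
from heatlag.splines import SplineSpec, eval_basis

__all__ = ["ReducedSet", "predict_at_day", "reduce_overall", "reduce_lag"]


@dataclass(frozen=True)
class ReducedSet:
    """Coefficients and covariance of one summary curve.

    ``kind`` is ``overall_cumulative`` (coefficients on the exposure basis)
    or ``lag_at_value`` (coefficients on the lag basis).  ``reference_value``
    is the temperature at which the curve is anchored to zero;
    ``at_value`` is the exposure ``x*`` of a lag-response set.
    """

    kind: str
    coefficients: np.ndarray
    vcov: np.ndarray
    spec: SplineSpec
    reference_value: float | None = None
    at_value: float | None = None
    center_day: float | str = "whole-summer"

    def __post_init__(self) -> None:
        k = len(self.coefficients)
        if self.vcov.shape != (k, k):
            raise ValueError("vcov shape does not match coefficients")

    def curve(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Curve value and pointwise variance at ``points``.

        Overall-cumulative sets are referenced at ``reference_value`` (the
        curve is exactly zero there, with zero variance); lag sets evaluate
        the lag basis directly.
        """
        b = eval_basis(points, self.spec).values
        if self.kind == "overall_cumulative" and self.reference_value is not None:
            b = b - eval_basis([self.reference_value], self.spec).values
        val = b @ self.coefficients
        var = np.einsum("ij,jk,ik->i", b, self.vcov, b)
        return val, np.maximum(var, 0.0)


def predict_at_day(
    theta_joint: np.ndarray,
    vcov_joint: np.ndarray,
    center_day: float,
    day: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-basis coefficients + covariance for day ``day`` of the season.

    The joint block stacks 12 main over 12 interaction coefficients from a
    time-varying fit centred at ``center_day``; the translated block is
    ``theta_main + (d - d0) theta_int`` with the matching quadratic form on
    the joint covariance.
    """
    theta_joint = np.asarray(theta_joint, dtype=float)
    vcov_joint = np.asarray(vcov_joint, dtype=float)
    m = theta_joint.size // 2
    if theta_joint.size != 2 * m or vcov_joint.shape != (2 * m, 2 * m):
        raise ValueError("joint block must stack main and interaction coefficients")
    delta = float(day) - float(center_day)
    a = np.hstack([np.eye(m), delta * np.eye(m)])
    return a @ theta_joint, a @ vcov_joint @ a.T


def _check_dims(theta: np.ndarray, vcov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if vcov.shape != (theta.size, theta.size):
        raise ValueError("coefficient/covariance dimension mismatch")
    return theta, vcov


def overall_reduction_matrix(cb: CrossBasis) -> np.ndarray:
    """``df_x x (df_x * df_l)`` map summing the lag basis over integer lags."""
    u = cb.lag_basis().values.sum(axis=0)  # (df_l,)
    m = np.zeros((cb.df_exposure, cb.df_exposure * cb.df_lag))
    for j in range(cb.df_exposure):
        m[j, j * cb.df_lag : (j + 1) * cb.df_lag] = u
    return m


def lag_reduction_matrix(cb: CrossBasis, x_star: float, x_ref: float) -> np.ndarray:
    """``df_l x (df_x * df_l)`` map contrasting the exposure basis at x* vs ref."""
    rb = cb.exposure_basis([x_star, x_ref]).values
    r = rb[0] - rb[1]  # (df_x,)
    m = np.zeros((cb.df_lag, cb.df_exposure * cb.df_lag))
    for j in range(cb.df_exposure):
        m[:, j * cb.df_lag : (j + 1) * cb.df_lag] = r[j] * np.eye(cb.df_lag)
    return m


def reduce_overall(
    theta: np.ndarray,
    vcov: np.ndarray,
    cb: CrossBasis,
    *,
    reference_value: float | None = None,
    center_day: float | str = "whole-summer",
) -> ReducedSet:
    """Collapse cross-basis coefficients to the overall cumulative curve set."""
    theta, vcov = _check_dims(theta, vcov)
    m = overall_reduction_matrix(cb)
    if theta.size != m.shape[1]:
        raise ValueError(f"expected {m.shape[1]} cross-basis coefficients, got {theta.size}")
    return ReducedSet(
        kind="overall_cumulative",
        coefficients=m @ theta,
        vcov=m @ vcov @ m.T,
        spec=cb.exposure_spec,
        reference_value=reference_value,
        center_day=center_day,
    )


def reduce_lag(
    theta: np.ndarray,
    vcov: np.ndarray,
    cb: CrossBasis,
    x_star: float,
    x_ref: float,
    *,
    center_day: float | str = "whole-summer",
) -> ReducedSet:
    """Collapse cross-basis coefficients to the lag-response set at ``x_star``.

    ``x_star == x_ref`` yields the all-zero set (a flat zero lag curve).
    """
    theta, vcov = _check_dims(theta, vcov)
    m = lag_reduction_matrix(cb, float(x_star), float(x_ref))
    if theta.size != m.shape[1]:
        raise ValueError(f"expected {m.shape[1]} cross-basis coefficients, got {theta.size}")
    return ReducedSet(
        kind="lag_at_value",
        coefficients=m @ theta,
        vcov=m @ vcov @ m.T,
        spec=cb.lag_spec,
        reference_value=float(x_ref),
        at_value=float(x_star),
        center_day=center_day,
    )
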