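"""Location-level quasi-Poisson regression for the summer DLNM.

The design matrix combines the cross-basis block (and, for the time-varying
model, its day-of-season interaction twin) with the confounder model:
a natural cubic spline of day of season (4 df, equally spaced knots)
interacted with summer indicators, a long-term trend spline (about 1 df per
decade), day-of-week indicators, and optional humidity / diurnal temperature
range adjustments.

Fitting is delegated to statsmodels' Poisson GLM (IRLS, deviance-based
convergence) with the Pearson-statistic dispersion of the quasi-likelihood
approach: ``phi = X2 / (n - p)`` and ``vcov = phi * (X'WX)^-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from heatlag.crossbasis import CrossBasis, InteractionBasis
from heatlag.simulate import LocationSeries
from heatlag.splines import SplineSpec, eval_natural_cubic, percentile_knots

__all__ = ["FirstStageFit", "DesignInfo", "assemble_design", "fit_quasipoisson", "extract_blocks"]


@dataclass(frozen=True)
class DesignInfo:
    """Assembled design matrix, response and block layout."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    blocks: dict[str, slice]
    usable: np.ndarray  # mask over the original series rows


@dataclass(frozen=True)
class FirstStageFit:
    """Converged quasi-Poisson fit with its block layout.

    ``beta_main`` / ``beta_int`` are the cross-basis and interaction
    coefficient blocks; ``vcov`` is the full covariance (Pearson-scaled).
    """

    params: np.ndarray
    vcov: np.ndarray
    names: list[str]
    blocks: dict[str, slice]
    dispersion: float
    n_obs: int
    deviance: float
    location_id: str | None = None

    @property
    def beta_main(self) -> np.ndarray:
        return self.params[self.blocks["crossbasis"]]

    @property
    def beta_int(self) -> np.ndarray | None:
        if "interaction" not in self.blocks:
            return None
        return self.params[self.blocks["interaction"]]

    @property
    def has_interaction(self) -> bool:
        return "interaction" in self.blocks

    def to_dict(self) -> dict:
        """JSON-serialisable fit summary."""
        return {
            "location_id": self.location_id,
            "names": list(self.names),
            "params": self.params.tolist(),
            "vcov": self.vcov.tolist(),
            "dispersion": self.dispersion,
            "n_obs": self.n_obs,
            "deviance": self.deviance,
            "blocks": {k: [v.start, v.stop] for k, v in self.blocks.items()},
        }


def _equally_spaced_interior(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(lo + (hi - lo) * k / (n + 1) for k in range(1, n + 1))


def _seasonal_block(dos: np.ndarray, summers: np.ndarray, df: int) -> tuple[np.ndarray, list[str]]:
    lo, hi = 1.0, float(dos.max())
    spec = SplineSpec("natural_cubic", _equally_spaced_interior(lo, hi, df - 1), (lo, hi))
    basis = eval_natural_cubic(np.clip(dos, lo, hi), spec).values
    cols, names = [], []
    for s in np.unique(summers):
        block = basis * (summers == s)[:, None]
        cols.append(block)
        names += [f"seas{j + 1}:summer{s}" for j in range(df)]
    return np.column_stack(cols), names


def _trend_block(time_index: np.ndarray, n_years: int) -> tuple[np.ndarray, list[str]]:
    df = max(1, round(n_years / 10))
    lo, hi = float(time_index.min()), float(time_index.max())
    spec = SplineSpec("natural_cubic", _equally_spaced_interior(lo, hi, df - 1), (lo, hi))
    vals = eval_natural_cubic(time_index, spec).values
    return vals, [f"trend{j + 1}" for j in range(df)]


def _lag01_mean(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[1:] = 0.5 * (x[1:] + x[:-1])
    return out


def assemble_design(
    series: LocationSeries,
    cb: CrossBasis,
    ib: InteractionBasis | None = None,
    *,
    seasonal_df: int = 4,
    adjust_humidity: bool = False,
    adjust_dtr: bool = False,
) -> DesignInfo:
    """Assemble the quasi-Poisson design matrix for one location.

    Columns: intercept | cross-basis | interaction (if any) | day-of-season
    spline x summer indicators | long-term trend spline | 6 day-of-week
    indicators | optional humidity spline (3 df of the lag 0-1 mean) |
    optional diurnal temperature range (linear).  Rows are restricted to
    analysed days with a complete lag window.
    """
    data = series.data
    n = len(data)
    if cb.values.shape[0] != n:
        raise ValueError("cross-basis rows must align with the series")
    dos = data["day_of_season"].to_numpy(dtype=float)
    summers = data["summer"].to_numpy()
    usable = cb.usable & (dos >= 1) & np.isfinite(data["deaths"].to_numpy(dtype=float))

    pieces: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    blocks: dict[str, slice] = {"intercept": slice(0, 1)}

    def add(block: np.ndarray, block_names: list[str], key: str) -> None:
        start = sum(p.shape[1] for p in pieces)
        pieces.append(block)
        names.extend(block_names)
        blocks[key] = slice(start, start + block.shape[1])

    add(cb.values, [f"cb{j + 1}.{k + 1}" for j in range(cb.df_exposure) for k in range(cb.df_lag)], "crossbasis")
    if ib is not None:
        if ib.values.shape != cb.values.shape:
            raise ValueError("interaction block must match the cross-basis shape")
        add(ib.values, [f"int{j + 1}.{k + 1}" for j in range(cb.df_exposure) for k in range(cb.df_lag)], "interaction")

    seas, seas_names = _seasonal_block(dos, summers, seasonal_df)
    add(seas, seas_names, "seasonal")

    dates = np.asarray(data["date"])
    t_index = np.array([(d - dates[0]).days for d in dates], dtype=float)
    trend, trend_names = _trend_block(t_index, len(np.unique(summers)))
    add(trend, trend_names, "trend")

    dow = data["dow"].to_numpy()
    dow_block = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])
    add(dow_block, [f"dow{d}" for d in range(1, 7)], "dow")

    if adjust_humidity:
        if "humidity" not in data.columns:
            raise ValueError("humidity adjustment requested but series has no humidity column")
        h01 = _lag01_mean(data["humidity"].to_numpy(dtype=float))
        knots = percentile_knots(h01[usable], [33.3, 66.7])
        spec = SplineSpec(
            "natural_cubic", tuple(knots), (float(h01[usable].min()), float(h01[usable].max()))
        )
        add(eval_natural_cubic(h01, spec).values, [f"hum{j + 1}" for j in range(3)], "humidity")
    if adjust_dtr:
        if "dtr" not in data.columns:
            raise ValueError("dtr adjustment requested but series has no dtr column")
        add(data["dtr"].to_numpy(dtype=float)[:, None], ["dtr"], "dtr")

    X = np.column_stack(pieces)
    y = data["deaths"].to_numpy(dtype=float)

    Xu = X[usable]
    rank = np.linalg.matrix_rank(Xu)
    if rank < X.shape[1]:
        # locate the first block whose addition breaks full rank
        cum = 0
        for key, sl in blocks.items():
            cum = sl.stop
            sub = Xu[:, :cum]
            if np.linalg.matrix_rank(sub) < cum:
                raise ValueError(f"design matrix rank-deficient after adding block '{key}'")
        raise ValueError("design matrix rank-deficient")
    return DesignInfo(X=X[usable], y=y[usable], names=names, blocks=blocks, usable=usable)


def fit_quasipoisson(
    X,
    y,
    *,
    names: list[str] | None = None,
    blocks: dict[str, slice] | None = None,
    location_id: str | None = None,
    maxiter: int = 100,
    tol: float = 1e-9,
) -> FirstStageFit:
    """Fit a log-link quasi-Poisson GLM and return coefficients + covariance.

    Accepts either a :class:`DesignInfo` as ``X`` (with ``y=None``) or raw
    arrays.  Dispersion is the Pearson chi-square estimator; a warning is
    raised when it falls outside [0.5, 10].
    """
    if isinstance(X, DesignInfo):
        info = X
        X, y, names, blocks = info.X, info.y, info.names, info.blocks
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol, scale="X2")
    if not getattr(res, "converged", True):
        raise RuntimeError(f"IRLS did not converge in {maxiter} iterations")
    phi = float(res.scale)
    if phi < 0.5 or phi > 10:
        warnings.warn(f"unusual dispersion estimate phi={phi:.3g}", stacklevel=2)
    if blocks is None:
        blocks = {}
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return FirstStageFit(
        params=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        names=list(names),
        blocks=dict(blocks),
        dispersion=phi,
        n_obs=len(y),
        deviance=float(res.deviance),
        location_id=location_id,
    )


def extract_blocks(fit: FirstStageFit, which: str) -> tuple[np.ndarray, np.ndarray]:
    """Sub-vector and covariance of the requested cross-basis block(s).

    ``which`` is one of ``main``, ``interaction``, ``joint``; ``joint``
    returns main stacked over interaction (24 coefficients by default).
    """
    if which == "main":
        idx = np.arange(fit.blocks["crossbasis"].start, fit.blocks["crossbasis"].stop)
    elif which == "interaction":
        if "interaction" not in fit.blocks:
            raise ValueError("fit has no interaction block")
        idx = np.arange(fit.blocks["interaction"].start, fit.blocks["interaction"].stop)
    elif which == "joint":
        if "interaction" not in fit.blocks:
            raise ValueError("fit has no interaction block")
        idx = np.concatenate(
            [
                np.arange(fit.blocks["crossbasis"].start, fit.blocks["crossbasis"].stop),
                np.arange(fit.blocks["interaction"].start, fit.blocks["interaction"].stop),
            ]
        )
    else:
        raise ValueError(f"unknown block selector {which!r}")
    return fit.params[idx], fit.vcov[np.ix_(idx, idx)]
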