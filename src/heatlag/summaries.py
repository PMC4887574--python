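"""Reported quantities: minimum-mortality percentiles, recentred curves,
relative-risk tables and lag-response curves.

Curves are represented on a relative scale, along percentiles of the summer
temperature distribution: country-level curves use the average of the
location-specific percentile tables, location-level curves the location's
own.  The minimum-mortality percentile (MMP) is the argmin over percentiles
1-99 of the overall cumulative curve from the model without interaction; all
relative risks are reported versus the MMP with Wald-type 95% confidence
intervals, symmetric on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from heatlag.reduction import ReducedSet

__all__ = [
    "PercentileTable",
    "CurveSummary",
    "RRSummary",
    "percentile_table",
    "find_mmp",
    "recenter_curve",
    "rr_table",
    "lag_curve",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PercentileTable:
    """Percentile -> temperature mapping (percentiles 0..100)."""

    percentiles: np.ndarray
    temperatures: np.ndarray

    def temperature(self, pct) -> np.ndarray:
        return np.interp(np.asarray(pct, dtype=float), self.percentiles, self.temperatures)


def percentile_table(temps_or_list, percentiles=None) -> PercentileTable:
    """Empirical percentile table of one series, or the average table of many.

    Passing a list of temperature arrays averages the location-specific
    tables percentile-by-percentile (the country-level convention).
    """
    if percentiles is None:
        percentiles = np.arange(0, 101, dtype=float)
    percentiles = np.asarray(percentiles, dtype=float)
    if isinstance(temps_or_list, (list, tuple)):
        tables = np.array(
            [np.percentile(np.asarray(t, dtype=float), percentiles) for t in temps_or_list]
        )
        temps = tables.mean(axis=0)
    else:
        temps = np.percentile(np.asarray(temps_or_list, dtype=float), percentiles)
    return PercentileTable(percentiles=percentiles, temperatures=temps)


@dataclass(frozen=True)
class CurveSummary:
    """Percentile-gridded log-RR curve with pointwise variances."""

    percentiles: np.ndarray
    temperatures: np.ndarray
    logrr: np.ndarray
    variance: np.ndarray
    reference_percentile: float
    center_day: float | str
    country: str | None = None

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.logrr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.logrr - _Z95 * np.sqrt(self.variance))

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.logrr + _Z95 * np.sqrt(self.variance))

    def at(self, pct: float) -> tuple[float, float]:
        """log-RR and variance at a percentile (grid interpolation)."""
        return (
            float(np.interp(pct, self.percentiles, self.logrr)),
            float(np.interp(pct, self.percentiles, self.variance)),
        )


@dataclass(frozen=True)
class RRSummary:
    """One row of the per-country results table."""

    country: str
    period: str
    mmp: float
    rr90: float
    rr90_ci: tuple[float, float]
    rr99: float
    rr99_ci: tuple[float, float]
    wald_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.rr90_ci[0] <= self.rr90 <= self.rr90_ci[1]):
            raise ValueError("RR90 outside its confidence interval")
        if not (self.rr99_ci[0] <= self.rr99 <= self.rr99_ci[1]):
            raise ValueError("RR99 outside its confidence interval")


def find_mmp(
    reduced: ReducedSet,
    table: PercentileTable,
    *,
    grid: np.ndarray | None = None,
) -> float:
    """Minimum-mortality percentile of an overall cumulative curve.

    Argmin over the percentile grid (default 1..99, step 1); ties break
    toward the lower percentile.  Reference choice does not affect the
    argmin.
    """
    if reduced.kind != "overall_cumulative":
        raise ValueError("MMP is defined on overall cumulative sets")
    if grid is None:
        grid = np.arange(1.0, 100.0)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 1 or grid.max() > 99:
        raise ValueError("MMP search grid must stay within percentiles 1-99")
    vals, _ = reduced.curve(table.temperature(grid))
    return float(grid[int(np.argmin(vals))])


def recenter_curve(
    reduced: ReducedSet,
    table: PercentileTable,
    reference_percentile: float,
    *,
    grid: np.ndarray | None = None,
    country: str | None = None,
) -> CurveSummary:
    """Overall cumulative curve recentred on a reference percentile.

    The log-RR at the reference is exactly zero (with zero variance); all
    other points carry the variance of the contrast ``f(x) - f(x_ref)``.
    """
    if grid is None:
        grid = np.arange(1.0, 100.0)
    grid = np.asarray(grid, dtype=float)
    x_ref = float(table.temperature(reference_percentile))
    anchored = replace(reduced, reference_value=x_ref)
    temps = table.temperature(grid)
    logrr, var = anchored.curve(temps)
    return CurveSummary(
        percentiles=grid,
        temperatures=temps,
        logrr=logrr,
        variance=var,
        reference_percentile=float(reference_percentile),
        center_day=reduced.center_day,
        country=country,
    )


def _rr_ci(logrr: float, var: float) -> tuple[float, tuple[float, float]]:
    se = np.sqrt(max(var, 0.0))
    return float(np.exp(logrr)), (float(np.exp(logrr - _Z95 * se)), float(np.exp(logrr + _Z95 * se)))


def rr_table(
    early: ReducedSet,
    late: ReducedSet,
    whole: ReducedSet,
    mmp: float,
    table: PercentileTable,
    *,
    country: str = "pooled",
    wald_p: float | None = None,
) -> list[RRSummary]:
    """Relative risks at the 90th and 99th percentiles versus the MMP.

    One row per period (whole / early / late); the Wald p-value of the
    within-summer interaction is attached to every row of the country.
    """
    rows = []
    for period, rs in (("whole", whole), ("early", early), ("late", late)):
        cs = recenter_curve(rs, table, mmp, country=country)
        rr90, ci90 = _rr_ci(*cs.at(90.0))
        rr99, ci99 = _rr_ci(*cs.at(99.0))
        rows.append(
            RRSummary(
                country=country,
                period=period,
                mmp=mmp,
                rr90=rr90,
                rr90_ci=ci90,
                rr99=rr99,
                rr99_ci=ci99,
                wald_p=wald_p,
            )
        )
    return rows


def lag_curve(
    reduced: ReducedSet,
    *,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lag-response curve (log-RR and variance) on a fine lag grid.

    Default grid is 0..10 in steps of 0.25; sums for consistency checks use
    the integer lags.
    """
    if reduced.kind != "lag_at_value":
        raise ValueError("lag_curve requires a lag-at-value reduced set")
    if grid is None:
        grid = np.arange(0.0, 10.25, 0.25)
    grid = np.asarray(grid, dtype=float)
    val, var = reduced.curve(grid)
    return grid, val, var
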