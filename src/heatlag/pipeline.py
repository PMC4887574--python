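"""End-to-end two-stage analysis: simulate/read -> first stage -> reduce ->
pool -> summarise, with CSV/JSON outputs.

The entry point is :func:`run_full_analysis`, a deterministic (given the
seed) orchestration of the library modules.  Capabilities that a shell tool
would expose as subcommands are plain functions here: dataset generation and
I/O (:func:`write_dataset`, :func:`read_dataset`), per-location fitting
(:func:`fit_location`), pooling and summarising (inside
:func:`run_full_analysis`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import heatlag
from heatlag.crossbasis import build_crossbasis, build_interaction
from heatlag.firststage import assemble_design, extract_blocks, fit_quasipoisson
from heatlag.mvmeta import (
    MetaFit,
    blup,
    build_meta_design,
    fit_mvmeta_reml,
    predict_country,
    wald_test_interaction,
)
from heatlag.reduction import ReducedSet, predict_at_day, reduce_lag, reduce_overall
from heatlag.simulate import LocationSeries, SimulationConfig, TrueSurface, simulate_multicountry
from heatlag.splines import SplineSpec, log_spaced_lag_knots, percentile_knots
from heatlag.summaries import (
    PercentileTable,
    find_mmp,
    lag_curve,
    percentile_table,
    recenter_curve,
    rr_table,
)

__all__ = [
    "PipelineConfig",
    "LocationFit",
    "AnalysisResult",
    "exposure_spec_for",
    "default_lag_spec",
    "fit_location",
    "run_full_analysis",
    "read_location_csv",
    "write_location_csv",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger("heatlag")

_EXPOSURE_KNOT_RULES = {2: (), 3: (75.0,), 4: (50.0, 90.0)}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full analysis run.

    Either ``simulation`` (a :class:`SimulationConfig`) or ``manifest`` (path
    to a ``locations.csv`` written by :func:`write_dataset`) supplies the
    data.  ``exposure_df`` selects the exposure-response spline: 2 df (no
    knots), 3 df (knot at the location 75th percentile, the default) or 4 df
    (knots at the 50th and 90th percentiles).
    """

    simulation: SimulationConfig | None = None
    manifest: str | None = None
    exposure_df: int = 3
    lag_max: int = 10
    n_lag_knots: int = 2
    center_early: int | None = None
    center_late: int | None = None
    adjust_humidity: bool = False
    adjust_dtr: bool = False
    outdir: str | None = None
    seed: int | None = None
    impute_missing: bool = False
    max_excluded_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.exposure_df not in _EXPOSURE_KNOT_RULES:
            raise ValueError("exposure_df must be 2, 3 or 4")
        if (self.simulation is None) == (self.manifest is None):
            raise ValueError("exactly one of simulation or manifest must be given")

    def resolved_simulation(self) -> SimulationConfig | None:
        if self.simulation is None:
            return None
        if self.seed is not None and self.seed != self.simulation.seed:
            return dataclasses.replace(self.simulation, seed=self.seed)
        return self.simulation

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["surface_spec"] = dataclasses.asdict(self.simulation.surface_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            sim["surface_spec"] = TrueSurface(**sim["surface_spec"])
            sim["years"] = tuple(sim["years"])
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)


def exposure_spec_for(temps: np.ndarray, exposure_df: int) -> SplineSpec:
    """Quadratic B-spline exposure basis for one location's summer temperatures."""
    rule = _EXPOSURE_KNOT_RULES[exposure_df]
    knots = tuple(percentile_knots(temps, rule)) if rule else ()
    return SplineSpec(
        "quadratic_bspline", knots, (float(np.min(temps)), float(np.max(temps))), intercept=False
    )


def default_lag_spec(lag_max: int = 10, n_knots: int = 2) -> SplineSpec:
    """Natural cubic lag basis with intercept and log-spaced interior knots."""
    return SplineSpec(
        "natural_cubic",
        tuple(log_spaced_lag_knots(lag_max, n_knots)),
        (0.0, float(lag_max)),
        intercept=True,
    )


# ---------------------------------------------------------------------------
# file I/O

_CSV_COLUMNS = ["date", "day_of_season", "summer", "dow", "temp", "deaths"]


def write_location_csv(series: LocationSeries, path) -> None:
    """One CSV per location; burn-in rows keep an empty deaths field."""
    cols = _CSV_COLUMNS + [c for c in ("humidity", "dtr") if c in series.data.columns]
    out = series.data[cols].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)


def read_location_csv(
    path,
    *,
    location_id: str | None = None,
    country_id: str = "unknown",
    impute_missing: bool = False,
) -> LocationSeries:
    """Parse and validate a location CSV written by :func:`write_location_csv`.

    Calendar gaps within a summer are rejected unless they amount to at most
    5% of the summer's days and ``impute_missing`` is set, in which case
    temperatures are linearly interpolated and deaths set to the rounded
    summer mean; imputed rows are flagged in an ``imputed`` column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"malformed header in {path}: missing column(s) {missing_cols}")
    df["date"] = [pd.Timestamp(d).date() for d in df["date"]]
    df["imputed"] = False
    filled = []
    for summer, g in df.groupby("summer", sort=True):
        g = g.sort_values("date").reset_index(drop=True)
        dates = pd.to_datetime(g["date"])
        full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
        n_missing = len(full) - len(g)
        if n_missing:
            if not impute_missing or n_missing > 0.05 * len(full):
                raise ValueError(
                    f"summer {summer}: {n_missing} missing day(s); "
                    "set impute_missing to interpolate up to 5%"
                )
            g = g.set_index(dates).reindex(full)
            g["imputed"] = g["temp"].isna()
            g["temp"] = g["temp"].interpolate(method="linear")
            g["summer"] = summer
            g["dow"] = [d.weekday() for d in full]
            g["date"] = [d.date() for d in full]
            dos = g["day_of_season"].to_numpy(dtype=float)
            base = np.nanmin(dos) - np.flatnonzero(~np.isnan(dos)).min()
            g["day_of_season"] = (base + np.arange(len(full))).astype(int)
            mean_deaths = np.round(np.nanmean(g["deaths"].to_numpy(dtype=float)))
            analysed = g["day_of_season"].to_numpy() >= 1
            fill = g["deaths"].isna() & analysed
            g.loc[fill, "deaths"] = mean_deaths
            g = g.reset_index(drop=True)
            logger.info("summer %s: imputed %d missing day(s)", summer, int(n_missing))
        filled.append(g)
    df = pd.concat(filled, ignore_index=True)
    loc = location_id or Path(path).stem
    return LocationSeries(location_id=loc, country_id=country_id, data=df)


def write_dataset(series_list, truth, outdir) -> Path:
    """Write per-location CSVs, a locations.csv manifest and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series_list:
        write_location_csv(s, outdir / f"{s.location_id}.csv")
        rows.append(
            {
                "location_id": s.location_id,
                "country_id": s.country_id,
                "temp_mean": round(s.summer_temp_mean, 6),
                "temp_range": round(s.summer_temp_range, 6),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "locations.csv", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.as_dict(), indent=1))
    return outdir


def read_dataset(manifest_path, *, impute_missing: bool = False) -> list[LocationSeries]:
    """Read every location listed in a ``locations.csv`` manifest."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    out = []
    for _, row in manifest.iterrows():
        out.append(
            read_location_csv(
                base / f"{row['location_id']}.csv",
                location_id=row["location_id"],
                country_id=row["country_id"],
                impute_missing=impute_missing,
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-location first stage

@dataclass
class LocationFit:
    """All first-stage products of one location needed by the second stage."""

    series: LocationSeries
    exposure_spec: SplineSpec
    crossbasis: object
    whole_overall: ReducedSet
    early_overall: ReducedSet
    late_overall: ReducedSet
    interaction_overall: ReducedSet
    theta_early: np.ndarray
    vcov_early: np.ndarray
    theta_late: np.ndarray
    vcov_late: np.ndarray
    dispersion: float
    table: PercentileTable
    fit_summary: dict


def fit_location(
    series: LocationSeries,
    *,
    exposure_df: int = 3,
    lag_max: int = 10,
    n_lag_knots: int = 2,
    center_early: int | None = None,
    center_late: int | None = None,
    adjust_humidity: bool = False,
    adjust_dtr: bool = False,
) -> LocationFit:
    """First-stage products for one location.

    Fits both the time-varying model (cross-basis + interaction centred on
    the early-summer day) and the standard model without interaction, and
    reduces the coefficient blocks to overall-cumulative sets with the
    location median temperature as provisional reference.
    """
    data = series.data
    temps_analysis = series.temperature
    days = int(data["day_of_season"].max())
    d_early = center_early if center_early is not None else round(days / 8)
    d_late = center_late if center_late is not None else days - round(days / 8)

    espec = exposure_spec_for(temps_analysis, exposure_df)
    lspec = default_lag_spec(lag_max, n_lag_knots)
    cb = build_crossbasis(
        data["temp"].to_numpy(dtype=float),
        espec,
        lspec,
        lag_range=(0, lag_max),
        segments=data["summer"].to_numpy(),
    )
    ib = build_interaction(cb, data["day_of_season"].to_numpy(dtype=float), d_early)

    design_tv = assemble_design(
        series, cb, ib, adjust_humidity=adjust_humidity, adjust_dtr=adjust_dtr
    )
    fit_tv = fit_quasipoisson(design_tv, None, location_id=series.location_id)
    design_whole = assemble_design(
        series, cb, None, adjust_humidity=adjust_humidity, adjust_dtr=adjust_dtr
    )
    fit_whole = fit_quasipoisson(design_whole, None, location_id=series.location_id)

    x_med = float(np.median(temps_analysis))
    theta_j, vcov_j = extract_blocks(fit_tv, "joint")
    theta_e, vcov_e = predict_at_day(theta_j, vcov_j, d_early, d_early)
    theta_l, vcov_l = predict_at_day(theta_j, vcov_j, d_early, d_late)
    theta_w, vcov_w = extract_blocks(fit_whole, "main")
    theta_i, vcov_i = extract_blocks(fit_tv, "interaction")

    table = percentile_table(temps_analysis)
    return LocationFit(
        series=series,
        exposure_spec=espec,
        crossbasis=cb,
        whole_overall=reduce_overall(theta_w, vcov_w, cb, reference_value=x_med),
        early_overall=reduce_overall(theta_e, vcov_e, cb, reference_value=x_med, center_day=d_early),
        late_overall=reduce_overall(theta_l, vcov_l, cb, reference_value=x_med, center_day=d_late),
        interaction_overall=reduce_overall(theta_i, vcov_i, cb, center_day="interaction"),
        theta_early=theta_e,
        vcov_early=vcov_e,
        theta_late=theta_l,
        vcov_late=vcov_l,
        dispersion=fit_tv.dispersion,
        table=table,
        fit_summary=fit_tv.to_dict(),
    )


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class AnalysisResult:
    """Everything :func:`run_full_analysis` computes."""

    country_summary: pd.DataFrame
    curves: dict[tuple[str, str], pd.DataFrame]
    lag_curves: dict[tuple[str, str], pd.DataFrame]
    meta_fits: dict[str, MetaFit]
    location_fits: dict[str, LocationFit]
    location_mmp: dict[str, float]
    provenance: dict
    truth: object | None = None


def _country_exposure_spec(table: PercentileTable, exposure_df: int) -> SplineSpec:
    rule = _EXPOSURE_KNOT_RULES[exposure_df]
    knots = tuple(float(table.temperature(p)) for p in rule)
    lo, hi = float(table.temperature(0.0)), float(table.temperature(100.0))
    return SplineSpec("quadratic_bspline", knots, (lo, hi), intercept=False)


def _country_reduced(
    fit: MetaFit, country: str, cov_vals: dict[str, float], spec: SplineSpec, kind: str, **kw
) -> ReducedSet:
    coef, vcov = predict_country(fit, country, cov_vals)
    return ReducedSet(kind=kind, coefficients=coef, vcov=vcov, spec=spec, **kw)


def run_full_analysis(config: PipelineConfig):
    """Run simulate/read -> fit -> reduce -> pool -> summarise.

    Returns an :class:`AnalysisResult`; when ``config.outdir`` is set, also
    writes ``country_summary.csv``, percentile-gridded curves, lag curves,
    per-location fit summaries and a provenance JSON.
    """
    truth = None
    sim = config.resolved_simulation()
    if sim is not None:
        series_list, truth = simulate_multicountry(sim)
    else:
        series_list = read_dataset(config.manifest, impute_missing=config.impute_missing)
    series_list = sorted(series_list, key=lambda s: s.location_id)

    fits: dict[str, LocationFit] = {}
    excluded: dict[str, str] = {}
    for s in series_list:
        try:
            fits[s.location_id] = fit_location(
                s,
                exposure_df=config.exposure_df,
                lag_max=config.lag_max,
                n_lag_knots=config.n_lag_knots,
                center_early=config.center_early,
                center_late=config.center_late,
                adjust_humidity=config.adjust_humidity,
                adjust_dtr=config.adjust_dtr,
            )
        except Exception as exc:  # noqa: BLE001 - failing locations are excluded, not fatal
            logger.warning("location %s excluded: %s", s.location_id, exc)
            excluded[s.location_id] = str(exc)
    if len(excluded) > config.max_excluded_fraction * len(series_list):
        raise RuntimeError(
            f"{len(excluded)}/{len(series_list)} locations failed the first stage: {excluded}"
        )

    loc_ids = sorted(fits)
    countries = [fits[i].series.country_id for i in loc_ids]
    temp_means = np.array([fits[i].series.summer_temp_mean for i in loc_ids])
    temp_ranges = np.array([fits[i].series.summer_temp_range for i in loc_ids])
    X, cols, cov_means = build_meta_design(countries, temp_means, temp_ranges)

    def pool(sets: list[ReducedSet]) -> MetaFit:
        y = np.array([r.coefficients for r in sets])
        S = np.array([r.vcov for r in sets])
        return fit_mvmeta_reml(y, S, X, columns=cols, covariate_means=cov_means)

    meta_fits = {
        "whole": pool([fits[i].whole_overall for i in loc_ids]),
        "early": pool([fits[i].early_overall for i in loc_ids]),
        "late": pool([fits[i].late_overall for i in loc_ids]),
        "interaction": pool([fits[i].interaction_overall for i in loc_ids]),
    }

    country_levels = sorted(set(countries))
    country_tables = {
        c: percentile_table(
            [fits[i].series.temperature for i in loc_ids if fits[i].series.country_id == c]
        )
        for c in country_levels
    }
    country_covs = {
        c: {
            "temp_mean": float(
                np.mean([tm for tm, cc in zip(temp_means, countries) if cc == c])
            ),
            "temp_range": float(
                np.mean([tr for tr, cc in zip(temp_ranges, countries) if cc == c])
            ),
        }
        for c in country_levels
    }

    # location MMPs from BLUPs of the whole-summer model (pass 2 reference)
    blup_coef, _ = blup(meta_fits["whole"])
    location_mmp: dict[str, float] = {}
    for idx, loc in enumerate(loc_ids):
        f = fits[loc]
        anchored = dataclasses.replace(f.whole_overall, coefficients=blup_coef[idx])
        location_mmp[loc] = find_mmp(anchored, f.table)

    # pass-2 lag reduction: x* = location 99th pct, reference = location BLUP MMP
    lag_sets = {"early": [], "late": []}
    for loc in loc_ids:
        f = fits[loc]
        x_star = float(f.table.temperature(99.0))
        x_ref = float(f.table.temperature(location_mmp[loc]))
        lag_sets["early"].append(
            reduce_lag(f.theta_early, f.vcov_early, f.crossbasis, x_star, x_ref, center_day="early")
        )
        lag_sets["late"].append(
            reduce_lag(f.theta_late, f.vcov_late, f.crossbasis, x_star, x_ref, center_day="late")
        )
    meta_fits["lag_early"] = pool(lag_sets["early"])
    meta_fits["lag_late"] = pool(lag_sets["late"])

    lag_spec = default_lag_spec(config.lag_max, config.n_lag_knots)
    rows = []
    curves: dict[tuple[str, str], pd.DataFrame] = {}
    lag_curves: dict[tuple[str, str], pd.DataFrame] = {}
    for c in country_levels:
        spec_c = _country_exposure_spec(country_tables[c], config.exposure_df)
        sets = {
            period: _country_reduced(
                meta_fits[period], c, country_covs[c], spec_c, "overall_cumulative",
                center_day=period,
            )
            for period in ("whole", "early", "late")
        }
        mmp = find_mmp(sets["whole"], country_tables[c])
        b_int, v_int = predict_country(meta_fits["interaction"], c, country_covs[c])
        _, _, wald_p = wald_test_interaction(b_int, v_int)
        for row in rr_table(
            sets["early"], sets["late"], sets["whole"], mmp, country_tables[c],
            country=c, wald_p=wald_p,
        ):
            rows.append(
                {
                    "country": row.country,
                    "period": row.period,
                    "mmp": row.mmp,
                    "rr90": row.rr90,
                    "rr90_lo": row.rr90_ci[0],
                    "rr90_hi": row.rr90_ci[1],
                    "rr99": row.rr99,
                    "rr99_lo": row.rr99_ci[0],
                    "rr99_hi": row.rr99_ci[1],
                    "wald_p": row.wald_p,
                }
            )
        for period in ("whole", "early", "late"):
            cs = recenter_curve(sets[period], country_tables[c], mmp, country=c)
            curves[(c, period)] = pd.DataFrame(
                {
                    "percentile": cs.percentiles,
                    "temperature": cs.temperatures,
                    "logrr": cs.logrr,
                    "rr": cs.rr,
                    "rr_lo": cs.ci_low,
                    "rr_hi": cs.ci_high,
                }
            )
        for period in ("early", "late"):
            coef, vcov = predict_country(meta_fits[f"lag_{period}"], c, country_covs[c])
            rset = ReducedSet(
                kind="lag_at_value", coefficients=coef, vcov=vcov, spec=lag_spec,
                center_day=period,
            )
            grid, val, var = lag_curve(rset)
            se = np.sqrt(var)
            lag_curves[(c, period)] = pd.DataFrame(
                {
                    "lag": grid,
                    "logrr": val,
                    "rr": np.exp(val),
                    "rr_lo": np.exp(val - 1.959963984540054 * se),
                    "rr_hi": np.exp(val + 1.959963984540054 * se),
                }
            )

    country_summary = pd.DataFrame(rows)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "package_version": heatlag.__version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_locations": len(series_list),
        "excluded": excluded,
        "dispersion": {loc: fits[loc].dispersion for loc in loc_ids},
        "location_mmp": location_mmp,
    }

    result = AnalysisResult(
        country_summary=country_summary,
        curves=curves,
        lag_curves=lag_curves,
        meta_fits=meta_fits,
        location_fits=fits,
        location_mmp=location_mmp,
        provenance=provenance,
        truth=truth,
    )
    if config.outdir is not None:
        _write_results(result, config)
    return result


def _write_results(result: AnalysisResult, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    (out / "lag").mkdir(exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    result.country_summary.to_csv(out / "country_summary.csv", index=False, float_format="%.6g")
    for (c, period), df in result.curves.items():
        df.to_csv(out / "curves" / f"{c}_{period}.csv", index=False, float_format="%.6g")
    for (c, period), df in result.lag_curves.items():
        df.to_csv(out / "lag" / f"{c}_{period}.csv", index=False, float_format="%.6g")
    for loc, f in result.location_fits.items():
        (out / "fits" / f"{loc}.json").write_text(json.dumps(f.fit_summary))
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=1, default=str))
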