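"""Synthetic multi-location summer mortality series with a known
time-varying exposure-lag-response surface.

The generator emulates the structure of multi-country daily mortality/weather
series restricted to a 4-month summer window:

* temperature: a seasonal sinusoid peaking mid-summer plus AR(1) Gaussian
  noise, with 10 burn-in days before each summer so that 0-10 day lag windows
  are complete from the first analysed day;
* deaths: overdispersed counts whose log-rate combines a baseline, a mild
  within-summer seasonal cycle, a day-of-week cycle, and the lag-cumulated
  heat effect of a "true surface";
* the true surface is separable per anchor day: an exposure-response curve
  (quadratic around its minimum-mortality point) times a normalised
  exponential-decay lag distribution, and the day-``d`` surface is the exact
  linear interpolation between the early- and late-summer anchor surfaces --
  the same model class fitted downstream (linear day-of-season interaction).

Between-location heterogeneity enters through the log-RR scale parameters of
the surface and through location climates (mean summer temperature).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "TrueSurface",
    "SimulationConfig",
    "LocationEffects",
    "LocationSeries",
    "SimulationTruth",
    "TemperatureDistribution",
    "seasonal_mean_temperature",
    "simulate_temperature",
    "simulate_deaths",
    "simulate_multicountry",
    "true_cumulative_logrr",
]


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth exposure-lag-response surface, anchored early and late.

    ``logrr99_*`` is the lag-cumulated log relative risk of a day at the 99th
    summer temperature percentile versus the minimum-mortality percentile
    ``mmt_percentile_*``; ``lag_decay_*`` is the exponential decay rate of
    the lag distribution (small = risk spread over many lags).  The day-``d``
    surface is the linear interpolation (in ``d``) between the two anchor
    surfaces, so its cumulated log-RR at the 99th percentile interpolates
    ``logrr99_early`` and ``logrr99_late`` exactly.
    """

    mmt_percentile_early: float = 60.0
    mmt_percentile_late: float = 60.0
    logrr99_early: float = 0.35
    logrr99_late: float = 0.05
    lag_decay_early: float = 0.3
    lag_decay_late: float = 1.0
    lag_max: int = 10

    def __post_init__(self) -> None:
        for name in ("mmt_percentile_early", "mmt_percentile_late"):
            p = getattr(self, name)
            if not 0 < p < 100:
                raise ValueError(f"{name} must be in (0, 100), got {p}")

    def lag_weights(self, decay: float) -> np.ndarray:
        """Discretised exponential lag distribution, summing to one."""
        w = np.exp(-decay * np.arange(self.lag_max + 1))
        return w / w.sum()


@dataclass(frozen=True)
class LocationEffects:
    """Per-location realisation of climate and surface scale parameters."""

    temp_mean: float
    logrr99_early: float
    logrr99_late: float


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the default simulation.

    Defaults: 30 locations in 2 countries, 10 summers of 122 days, 20
    expected deaths/day, heat effect attenuating from log-RR 0.35 (early) to
    0.05 (late) at the 99th percentile, lag spread shrinking over the season,
    overdispersion 1.2.
    """

    n_locations: int = 30
    n_countries: int = 2
    years: tuple[int, ...] = tuple(range(2000, 2010))
    days_per_summer: int = 122
    baseline_rate: float = 20.0
    temp_mean: float = 22.0
    temp_amplitude: float = 4.0
    temp_sd: float = 2.5
    temp_ar1: float = 0.6
    surface_spec: TrueSurface = field(default_factory=TrueSurface)
    heterogeneity_sd: float = 0.05
    dispersion: float = 1.2
    seed: int = 20160502
    # auxiliary world parameters (see docs/methods.md)
    temp_mean_sd: float = 1.5
    seasonal_amplitude: float = 0.05
    dow_amplitude: float = 0.02
    burnin_days: int = 10
    with_humidity: bool = False
    with_dtr: bool = False

    def __post_init__(self) -> None:
        if self.days_per_summer < 30:
            raise ValueError("days_per_summer must be >= 30")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        if not 0 <= self.temp_ar1 < 1:
            raise ValueError("temp_ar1 must be in [0, 1)")
        if self.n_locations < self.n_countries:
            raise ValueError("need n_locations >= n_countries")
        for name in ("baseline_rate", "temp_mean", "temp_amplitude", "temp_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.burnin_days < self.surface_spec.lag_max:
            raise ValueError("burnin_days must cover the lag window")

    @property
    def early_day(self) -> int:
        """Midpoint of the first summer month (day 15 of a 122-day summer)."""
        return round(self.days_per_summer / 8)

    @property
    def late_day(self) -> int:
        """Midpoint of the last summer month (day 107 of a 122-day summer)."""
        return self.days_per_summer - round(self.days_per_summer / 8)


@dataclass(frozen=True)
class LocationSeries:
    """One location's daily summer series plus metadata.

    ``data`` holds one row per day, burn-in days included (``day_of_season
    <= 0``, ``deaths`` missing); analysed days have ``day_of_season`` in
    ``1..days_per_summer`` and integer non-negative deaths.
    """

    location_id: str
    country_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"date", "day_of_season", "summer", "dow", "temp", "deaths"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"LocationSeries missing columns: {sorted(missing)}")
        a = self.analysis
        d = a["deaths"].to_numpy(dtype=float)
        if np.any(~np.isfinite(d)) or np.any(d < 0) or np.any(d != np.round(d)):
            raise ValueError("analysed deaths must be non-negative integers")
        for _, g in self.data.groupby("summer"):
            dos = g["day_of_season"].to_numpy()
            if np.any(np.diff(dos) != 1):
                raise ValueError("day_of_season must be gapless within each summer")

    @property
    def analysis(self) -> pd.DataFrame:
        """Rows of analysed days (burn-in excluded)."""
        return self.data[self.data["day_of_season"] >= 1]

    @property
    def temperature(self) -> np.ndarray:
        return self.analysis["temp"].to_numpy()

    @property
    def deaths(self) -> np.ndarray:
        return self.analysis["deaths"].to_numpy().astype(int)

    @property
    def summer_temp_mean(self) -> float:
        return float(self.temperature.mean())

    @property
    def summer_temp_range(self) -> float:
        t = self.temperature
        return float(t.max() - t.min())

    @property
    def n_summers(self) -> int:
        return int(self.data["summer"].nunique())


@dataclass(frozen=True)
class SimulationTruth:
    """Every per-location parameter of a simulated dataset, for recovery tests."""

    config: SimulationConfig
    effects: dict[str, LocationEffects]
    countries: dict[str, str]

    def as_dict(self) -> dict:
        s = self.config.surface_spec
        return {
            "surface": {
                "mmt_percentile_early": s.mmt_percentile_early,
                "mmt_percentile_late": s.mmt_percentile_late,
                "logrr99_early": s.logrr99_early,
                "logrr99_late": s.logrr99_late,
                "lag_decay_early": s.lag_decay_early,
                "lag_decay_late": s.lag_decay_late,
                "lag_max": s.lag_max,
            },
            "seed": self.config.seed,
            "dispersion": self.config.dispersion,
            "locations": {
                loc: {
                    "country_id": self.countries[loc],
                    "temp_mean": e.temp_mean,
                    "logrr99_early": e.logrr99_early,
                    "logrr99_late": e.logrr99_late,
                }
                for loc, e in self.effects.items()
            },
        }


def seasonal_mean_temperature(cfg: SimulationConfig, effects: LocationEffects, days) -> np.ndarray:
    """Deterministic seasonal temperature mean: sinusoid peaking mid-summer."""
    d = np.asarray(days, dtype=float)
    return effects.temp_mean + cfg.temp_amplitude * np.sin(np.pi * (d - 0.5) / cfg.days_per_summer)


class TemperatureDistribution:
    """Marginal summer temperature distribution implied by the weather model.

    The marginal over analysed days is an equal mixture of normals
    ``N(mu_d, sigma^2)`` with ``sigma`` the stationary AR(1) noise SD; the
    percentile and quantile functions below are its exact CDF (averaged
    normal CDFs) and a grid-interpolated inverse.
    """

    def __init__(self, cfg: SimulationConfig, effects: LocationEffects):
        self.mus = seasonal_mean_temperature(cfg, effects, np.arange(1, cfg.days_per_summer + 1))
        self.sigma = cfg.temp_sd / np.sqrt(1.0 - cfg.temp_ar1**2) if cfg.temp_sd > 0 else 0.0
        pad = 8 * max(self.sigma, 1e-6)
        self._grid = np.linspace(self.mus.min() - pad, self.mus.max() + pad, 4001)
        self._cdf = self._cdf_at(self._grid)

    def _cdf_at(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(len(x))
        step = max(1, int(2e6 / max(len(self.mus), 1)))  # bound the work matrix
        for i in range(0, len(x), step):
            xi = x[i : i + step, None]
            if self.sigma == 0:
                out[i : i + step] = (xi >= self.mus[None, :]).mean(axis=1)
            else:
                out[i : i + step] = ndtr((xi - self.mus[None, :]) / self.sigma).mean(axis=1)
        return out

    def percentile(self, temp) -> np.ndarray:
        """Temperature -> percentile (0-100)."""
        return 100.0 * self._cdf_at(np.atleast_1d(np.asarray(temp, dtype=float)))

    def temperature(self, pct) -> np.ndarray:
        """Percentile (0-100) -> temperature."""
        p = np.atleast_1d(np.asarray(pct, dtype=float)) / 100.0
        return np.interp(p, self._cdf, self._grid)


def _day_weight(cfg: SimulationConfig, day) -> np.ndarray:
    """Interpolation weight of the late-summer anchor on a given day."""
    d = np.asarray(day, dtype=float)
    return (d - cfg.early_day) / (cfg.late_day - cfg.early_day)


def true_cumulative_logrr(
    surface: TrueSurface,
    temp_percentile,
    day_of_season,
    *,
    early_day: float = 15,
    late_day: float = 107,
    quantile_fn=None,
) -> np.ndarray:
    """Ground-truth lag-cumulated log-RR at a percentile on a given day.

    Each anchor curve is quadratic around its minimum-mortality percentile
    and equals ``logrr99_*`` at the 99th percentile; the day-``d`` value is
    their linear interpolation with weight ``(d - early_day) / (late_day -
    early_day)``.  With ``quantile_fn`` (percentile -> temperature) the
    quadratic is taken on the temperature scale (the generator's convention);
    without it, on the percentile scale.  Both agree at the anchor points
    (the MMT, where the value is 0, and the 99th percentile).
    """
    p = np.asarray(temp_percentile, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("temp_percentile must be in (0, 100)")
    if quantile_fn is None:
        coord = lambda q: np.asarray(q, dtype=float)  # noqa: E731
    else:
        coord = quantile_fn
    x = coord(p)

    def anchor(pct_mmt: float, logrr99: float) -> np.ndarray:
        xm, x99 = coord(pct_mmt), coord(99.0)
        return logrr99 * ((x - xm) / (x99 - xm)) ** 2

    w = (np.asarray(day_of_season, dtype=float) - early_day) / (late_day - early_day)
    g_early = anchor(surface.mmt_percentile_early, surface.logrr99_early)
    g_late = anchor(surface.mmt_percentile_late, surface.logrr99_late)
    return (1.0 - w) * g_early + w * g_late


def simulate_temperature(
    cfg: SimulationConfig, location_effects: LocationEffects, rng: np.random.Generator
) -> np.ndarray:
    """Per-summer temperature series, burn-in days included.

    Returns an ``(n_summers, burnin_days + days_per_summer)`` array:
    seasonal sinusoid plus stationary AR(1) noise, deterministic given the
    generator state.
    """
    if not np.isfinite(location_effects.temp_mean):
        raise ValueError("temp_mean must be finite")
    n_days = cfg.burnin_days + cfg.days_per_summer
    days = np.arange(1 - cfg.burnin_days, cfg.days_per_summer + 1)
    mu = seasonal_mean_temperature(cfg, location_effects, days)
    out = np.empty((len(cfg.years), n_days))
    stat_sd = cfg.temp_sd / np.sqrt(1.0 - cfg.temp_ar1**2) if cfg.temp_sd > 0 else 0.0
    for s in range(len(cfg.years)):
        eps = rng.normal(0.0, cfg.temp_sd, size=n_days)
        noise = np.empty(n_days)
        noise[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
        for t in range(1, n_days):
            noise[t] = cfg.temp_ar1 * noise[t - 1] + eps[t]
        out[s] = mu + noise
    return out


def _surface_log_linear_predictor(
    temps: np.ndarray,
    cfg: SimulationConfig,
    surface: TrueSurface,
    effects: LocationEffects,
    dist: TemperatureDistribution,
) -> np.ndarray:
    """Lag-cumulated heat log-RR for every analysed day of every summer."""
    lag_max = surface.lag_max
    w_early = surface.lag_weights(surface.lag_decay_early)
    w_late = surface.lag_weights(surface.lag_decay_late)
    q = dist.temperature

    def anchor_curve(x, pct_mmt, logrr99):
        xm, x99 = q(pct_mmt)[0], q(99.0)[0]
        return logrr99 * ((x - xm) / (x99 - xm)) ** 2

    days = np.arange(1, cfg.days_per_summer + 1)
    wd = _day_weight(cfg, days)
    out = np.empty((temps.shape[0], cfg.days_per_summer))
    for s in range(temps.shape[0]):
        x = temps[s]
        ge = anchor_curve(x, surface.mmt_percentile_early, effects.logrr99_early)
        gl = anchor_curve(x, surface.mmt_percentile_late, effects.logrr99_late)
        cum_e = np.zeros(cfg.days_per_summer)
        cum_l = np.zeros(cfg.days_per_summer)
        base = cfg.burnin_days
        for lag in range(lag_max + 1):
            sl = slice(base - lag, base - lag + cfg.days_per_summer)
            cum_e += w_early[lag] * ge[sl]
            cum_l += w_late[lag] * gl[sl]
        out[s] = (1.0 - wd) * cum_e + wd * cum_l
    return out


def _dow_log_factor(cfg: SimulationConfig, dow: np.ndarray) -> np.ndarray:
    return cfg.dow_amplitude * np.sin(2 * np.pi * dow / 7.0)


def _seasonal_log_factor(cfg: SimulationConfig, day: np.ndarray) -> np.ndarray:
    return cfg.seasonal_amplitude * np.sin(2 * np.pi * day / cfg.days_per_summer)


def simulate_deaths(
    temps: np.ndarray,
    cfg: SimulationConfig,
    surface: TrueSurface,
    effects: LocationEffects,
    rng: np.random.Generator,
    *,
    dow: np.ndarray | None = None,
) -> np.ndarray:
    """Draw daily death counts for every analysed day.

    The mean is ``baseline_rate * seasonal factor * day-of-week factor *
    exp(lag-cumulated heat log-RR)``; overdispersion ``phi > 1`` is
    implemented as a negative binomial with variance ``phi * mean``.

    Parameters
    ----------
    temps : (n_summers, burnin + days) array from :func:`simulate_temperature`.
    dow : optional (n_summers, days) integer day-of-week array (0 = Monday).
    """
    if temps.ndim != 2 or temps.shape[1] < cfg.surface_spec.lag_max + cfg.days_per_summer:
        raise ValueError("temps must include >= lag_max burn-in days per summer")
    dist = TemperatureDistribution(cfg, effects)
    eta = _surface_log_linear_predictor(temps, cfg, surface, effects, dist)
    days = np.arange(1, cfg.days_per_summer + 1)
    eta = eta + _seasonal_log_factor(cfg, days)[None, :]
    if dow is not None:
        eta = eta + _dow_log_factor(cfg, np.asarray(dow))
    log_mu = np.log(cfg.baseline_rate) + eta
    if np.any(log_mu > 50):
        raise ValueError("death-rate overflow: log mean exceeds 50; check surface/baseline")
    mu = np.exp(log_mu)
    if cfg.dispersion == 1.0:
        return rng.poisson(mu)
    r = mu / (cfg.dispersion - 1.0)
    return rng.negative_binomial(r, 1.0 / cfg.dispersion)


def _summer_dates(year: int, n_days: int, burnin: int) -> tuple[np.ndarray, np.ndarray]:
    """Calendar dates and day-of-week for one summer (start June 1)."""
    start = dt.date(year, 6, 1) - dt.timedelta(days=burnin)
    dates = np.array([start + dt.timedelta(days=i) for i in range(burnin + n_days)])
    dows = np.array([d.weekday() for d in dates])
    return dates, dows


def _location_frame(
    cfg: SimulationConfig,
    temps: np.ndarray,
    deaths: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    frames = []
    for s, year in enumerate(cfg.years):
        dates, dows = _summer_dates(year, cfg.days_per_summer, cfg.burnin_days)
        dos = np.arange(1 - cfg.burnin_days, cfg.days_per_summer + 1)
        death_col = np.full(len(dos), np.nan)
        death_col[cfg.burnin_days:] = deaths[s]
        frame = pd.DataFrame(
            {
                "date": dates,
                "day_of_season": dos,
                "summer": year,
                "dow": dows,
                "temp": temps[s],
                "deaths": death_col,
            }
        )
        if cfg.with_humidity:
            frame["humidity"] = np.clip(rng.normal(70.0, 8.0, len(dos)), 5.0, 100.0)
        if cfg.with_dtr:
            frame["dtr"] = np.abs(rng.normal(8.0, 2.0, len(dos)))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_multicountry(cfg: SimulationConfig) -> tuple[list[LocationSeries], SimulationTruth]:
    """Generate the full multi-location dataset plus its truth record.

    Locations are assigned to countries in contiguous blocks; each draws its
    own climate mean and surface scale parameters (SD ``heterogeneity_sd``).
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    surface = cfg.surface_spec
    series_list: list[LocationSeries] = []
    effects_map: dict[str, LocationEffects] = {}
    countries: dict[str, str] = {}
    for i in range(cfg.n_locations):
        loc_id = f"loc{i + 1:03d}"
        country = f"country{i * cfg.n_countries // cfg.n_locations + 1}"
        eff = LocationEffects(
            temp_mean=float(rng.normal(cfg.temp_mean, cfg.temp_mean_sd)),
            logrr99_early=float(rng.normal(surface.logrr99_early, cfg.heterogeneity_sd)),
            logrr99_late=float(rng.normal(surface.logrr99_late, cfg.heterogeneity_sd)),
        )
        temps = simulate_temperature(cfg, eff, rng)
        dows = np.array(
            [_summer_dates(y, cfg.days_per_summer, cfg.burnin_days)[1][cfg.burnin_days:] for y in cfg.years]
        )
        deaths = simulate_deaths(temps, cfg, surface, eff, rng, dow=dows)
        frame = _location_frame(cfg, temps, deaths, rng)
        series_list.append(LocationSeries(location_id=loc_id, country_id=country, data=frame))
        effects_map[loc_id] = eff
        countries[loc_id] = country
    truth = SimulationTruth(config=cfg, effects=effects_map, countries=countries)
    return series_list, truth
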