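"""Synthetic-data generator: determinism, weather model, count model, truth oracle."""

import numpy as np
import pandas as pd
import pytest

import heatlag as hl
from heatlag.simulate import (
    LocationEffects,
    SimulationConfig,
    TemperatureDistribution,
    TrueSurface,
    seasonal_mean_temperature,
    simulate_deaths,
    simulate_multicountry,
    simulate_temperature,
    true_cumulative_logrr,
)


class TestTemperature:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_locations=2, n_countries=1, years=(2000, 2001))
        a, _ = simulate_multicountry(cfg)
        b, _ = simulate_multicountry(cfg)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.data, sb.data)

    def test_degenerate_parameters_give_constant_series(self):
        cfg = SimulationConfig(temp_amplitude=0.0, temp_sd=0.0, years=(2000,))
        eff = LocationEffects(temp_mean=21.0, logrr99_early=0, logrr99_late=0)
        t = simulate_temperature(cfg, eff, np.random.default_rng(0))
        assert np.all(t == 21.0)

    def test_ar1_autocorrelation_recovered(self):
        cfg = SimulationConfig(
            years=(2000,), days_per_summer=10_000, temp_ar1=0.7, temp_amplitude=2.0
        )
        eff = LocationEffects(temp_mean=20.0, logrr99_early=0, logrr99_late=0)
        t = simulate_temperature(cfg, eff, np.random.default_rng(99))[0]
        days = np.arange(1 - cfg.burnin_days, cfg.days_per_summer + 1)
        noise = t - seasonal_mean_temperature(cfg, eff, days)
        acf1 = np.corrcoef(noise[:-1], noise[1:])[0, 1]
        assert abs(acf1 - 0.7) < 0.03

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(temp_mean=np.nan)


class TestTrueSurface:
    surface = TrueSurface()

    def test_zero_at_interpolated_mmt(self):
        for day in (15, 61, 107):
            assert true_cumulative_logrr(self.surface, 60.0, day) == pytest.approx(0.0)

    def test_anchor_values_exact(self):
        assert true_cumulative_logrr(self.surface, 99.0, 15) == pytest.approx(0.35)
        assert true_cumulative_logrr(self.surface, 99.0, 107) == pytest.approx(0.05)

    def test_midpoint_day_interpolates(self):
        got = true_cumulative_logrr(self.surface, 99.0, 61.0)
        assert got == pytest.approx((0.35 + 0.05) / 2)

    def test_continuous_in_both_arguments(self):
        p = np.linspace(1, 99, 197)
        v1 = true_cumulative_logrr(self.surface, p, 40.0)
        assert np.abs(np.diff(v1)).max() < 0.02
        d = np.linspace(1, 122, 122)
        v2 = true_cumulative_logrr(self.surface, 95.0, d)
        assert np.abs(np.diff(v2)).max() < 0.01

    def test_percentile_bounds_enforced(self):
        with pytest.raises(ValueError):
            true_cumulative_logrr(self.surface, 0.0, 15)

    def test_lag_weights_normalised(self):
        w = self.surface.lag_weights(0.3)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w) < 0)


class TestDeaths:
    def _flat_cfg(self, **kw):
        surface = TrueSurface(logrr99_early=0.0, logrr99_late=0.0)
        return SimulationConfig(
            years=(2000,),
            days_per_summer=50_000,
            surface_spec=surface,
            dispersion=1.0,
            seasonal_amplitude=0.0,
            dow_amplitude=0.0,
            **kw,
        )

    def test_null_surface_mean_matches_baseline(self):
        cfg = self._flat_cfg(baseline_rate=20.0)
        eff = LocationEffects(temp_mean=22.0, logrr99_early=0.0, logrr99_late=0.0)
        rng = np.random.default_rng(5)
        temps = simulate_temperature(cfg, eff, rng)
        deaths = simulate_deaths(temps, cfg, cfg.surface_spec, eff, rng)
        se = np.sqrt(20.0 / deaths.size)
        assert abs(deaths.mean() - 20.0) < 3 * se

    def test_deaths_are_nonnegative_integers(self):
        cfg = SimulationConfig(years=(2000,), days_per_summer=200, dispersion=1.7)
        eff = LocationEffects(temp_mean=22.0, logrr99_early=0.4, logrr99_late=0.1)
        rng = np.random.default_rng(6)
        temps = simulate_temperature(cfg, eff, rng)
        deaths = simulate_deaths(temps, cfg, cfg.surface_spec, eff, rng)
        assert deaths.dtype.kind in "iu" and np.all(deaths >= 0)

    def test_doubling_baseline_doubles_expectation(self):
        means = []
        for baseline in (15.0, 30.0):
            cfg = self._flat_cfg(baseline_rate=baseline)
            eff = LocationEffects(temp_mean=22.0, logrr99_early=0.0, logrr99_late=0.0)
            rng = np.random.default_rng(7)
            temps = simulate_temperature(cfg, eff, rng)
            means.append(simulate_deaths(temps, cfg, cfg.surface_spec, eff, rng).mean())
        se = np.sqrt(2 * 30.0 / 50_000)
        assert abs(means[1] - 2 * means[0]) < 3 * se

    def test_overdispersion_inflates_variance(self):
        out = {}
        for phi in (1.0, 2.0):
            cfg = self._flat_cfg(baseline_rate=20.0)
            cfg = hl.SimulationConfig(**{**cfg.__dict__, "dispersion": phi})
            eff = LocationEffects(temp_mean=22.0, logrr99_early=0.0, logrr99_late=0.0)
            rng = np.random.default_rng(8)
            temps = simulate_temperature(cfg, eff, rng)
            d = simulate_deaths(temps, cfg, cfg.surface_spec, eff, rng)
            out[phi] = d.var() / d.mean()
        assert out[1.0] == pytest.approx(1.0, abs=0.05)
        assert out[2.0] == pytest.approx(2.0, abs=0.1)

    def test_overflow_rejected(self):
        cfg = SimulationConfig(years=(2000,), days_per_summer=40, baseline_rate=1e20)
        eff = LocationEffects(temp_mean=22.0, logrr99_early=30.0, logrr99_late=30.0)
        rng = np.random.default_rng(9)
        temps = simulate_temperature(cfg, eff, rng)
        with pytest.raises(ValueError, match="overflow"):
            simulate_deaths(temps, cfg, cfg.surface_spec, eff, rng)


class TestMulticountry:
    def test_no_heterogeneity_shares_parameters(self):
        cfg = SimulationConfig(
            n_locations=4, n_countries=2, years=(2000,), days_per_summer=40,
            heterogeneity_sd=0.0, temp_mean_sd=0.0, baseline_rate=5.0,
        )
        _, truth = simulate_multicountry(cfg)
        effs = list(truth.effects.values())
        assert len(effs) == 4
        assert all(e.logrr99_early == effs[0].logrr99_early for e in effs)

    def test_heterogeneity_sd_recovered_across_locations(self):
        cfg = SimulationConfig(
            n_locations=200, n_countries=2, years=(2000,), days_per_summer=30,
            baseline_rate=5.0, heterogeneity_sd=0.1, seed=77,
        )
        _, truth = simulate_multicountry(cfg)
        sd = np.std([e.logrr99_early for e in truth.effects.values()], ddof=1)
        assert abs(sd - 0.1) < 0.015

    def test_output_count_and_country_split(self):
        cfg = SimulationConfig(
            n_locations=6, n_countries=3, years=(2000,), days_per_summer=40, baseline_rate=5.0
        )
        series, truth = simulate_multicountry(cfg)
        assert len(series) == 6
        assert len({s.country_id for s in series}) == 3

    def test_percentile_map_is_consistent(self):
        cfg = SimulationConfig(years=(2000,))
        eff = LocationEffects(temp_mean=22.0, logrr99_early=0, logrr99_late=0)
        dist = TemperatureDistribution(cfg, eff)
        for p in (1.0, 25.0, 60.0, 99.0):
            assert dist.percentile(dist.temperature(p))[0] == pytest.approx(p, abs=0.05)

    def test_series_validation(self):
        cfg = SimulationConfig(n_locations=1, n_countries=1, years=(2000,), days_per_summer=40)
        series, _ = simulate_multicountry(cfg)
        bad = series[0].data.copy()
        bad.loc[bad.index[-1], "deaths"] = -1
        with pytest.raises(ValueError, match="non-negative"):
            hl.LocationSeries("x", "c", bad)
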