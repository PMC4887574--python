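"""Shared fixtures: small simulated locations and fitted first stages."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import heatlag as hl

warnings.filterwarnings("ignore", message="unusual dispersion")


@pytest.fixture(scope="session")
def small_cfg() -> hl.SimulationConfig:
    """Six summers of one well-populated location; quick to fit."""
    return hl.SimulationConfig(
        n_locations=1,
        n_countries=1,
        years=tuple(range(2000, 2006)),
        baseline_rate=30.0,
        heterogeneity_sd=0.0,
        dispersion=1.0,
        seed=424242,
    )


@pytest.fixture(scope="session")
def small_series(small_cfg) -> hl.LocationSeries:
    series, _ = hl.simulate_multicountry(small_cfg)
    return series[0]


@pytest.fixture(scope="session")
def small_fit(small_series):
    """Fitted first stage (time-varying + whole) for the small location."""
    return hl.fit_location(small_series)


@pytest.fixture(scope="session")
def small_crossbasis(small_series):
    espec = hl.exposure_spec_for(small_series.temperature, 3)
    lspec = hl.default_lag_spec()
    return hl.build_crossbasis(
        small_series.data["temp"].to_numpy(),
        espec,
        lspec,
        segments=small_series.data["summer"].to_numpy(),
    )
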