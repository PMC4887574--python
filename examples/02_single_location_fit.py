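"""Fit the time-varying DLNM to one location and read off early/late risk.

The first stage regresses daily deaths on the 12-column cross-basis
(quadratic exposure spline x natural cubic lag spline, lags 0-10) plus its
day-of-season interaction and the confounder model, then reduces the
coefficients to the overall cumulative exposure-response curve for the
early- and late-summer anchor days.
"""

import numpy as np

import heatlag as hl

cfg = hl.SimulationConfig(
    n_locations=1, n_countries=1, years=tuple(range(1998, 2008)),
    baseline_rate=40.0, heterogeneity_sd=0.0, seed=7,
)
series, truth = hl.simulate_multicountry(cfg)
loc = series[0]

fit = hl.fit_location(loc)
print(f"location {loc.location_id}: dispersion phi = {fit.dispersion:.3f}")

table = fit.table
x99 = float(table.temperature(99.0))
x60 = float(table.temperature(60.0))  # the true minimum-mortality percentile
for name, reduced in (("early", fit.early_overall), ("late", fit.late_overall)):
    val, var = reduced.curve([x99])
    ref, _ = reduced.curve([x60])
    logrr = val[0] - ref[0]
    se = np.sqrt(var[0])
    print(
        f"{name:>5} summer: RR at 99th vs 60th percentile = "
        f"{np.exp(logrr):.3f} (log-RR {logrr:+.3f} +- {se:.3f})"
    )
print(
    "\nTruth is RR exp(0.35)=1.419 early and exp(0.05)=1.051 late; a single "
    "location recovers these within its sampling error."
)
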