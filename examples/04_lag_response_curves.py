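"""Country-pooled lag-response curves at the 99th percentile, early vs late.

The lag-response curve slices the exposure-lag-response surface at the 99th
temperature percentile (versus the location minimum-mortality temperatures)
and shows how the extra risk of one hot day is distributed over the
following 10 days.  Early-summer risk persists over more lags than
late-summer risk -- the mechanism behind the within-summer attenuation.
"""

import heatlag as hl

res = hl.run_full_analysis(hl.PipelineConfig(simulation=hl.SimulationConfig()))

country = res.country_summary["country"].iloc[0]
print(f"pooled lag-response at the 99th percentile, {country}:")
print(f"{'lag':>4} {'early RR':>9} {'late RR':>9}")
early = res.lag_curves[(country, "early")]
late = res.lag_curves[(country, "late")]
for lag in range(11):
    e = early[early.lag == lag]["rr"].iloc[0]
    l = late[late.lag == lag]["rr"].iloc[0]
    print(f"{lag:>4} {e:>9.3f} {l:>9.3f}")
print(
    "\nThe early-summer curve shows clearly elevated risk over the first "
    "3-4 lags (truth: exponential decay at rate 0.3/day from RR~1.10 at "
    "lag 0), while the late-summer curve stays essentially flat at 1; the "
    "whole early/late contrast in cumulated risk comes from this "
    "larger-and-longer early lag structure."
)
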