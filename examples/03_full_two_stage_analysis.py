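"""The complete two-stage analysis on the default simulated world.

Thirty locations in two countries are fitted with time-varying DLNMs, the
reduced coefficient sets are pooled by REML multivariate meta-regression with
country indicators and climate meta-predictors, and the country summaries
mirror a heat-mortality results table: minimum-mortality percentile (MMP),
relative risks at the 90th/99th temperature percentiles for the whole
summer and for the early/late anchor days, and the Wald p-value of the
within-summer interaction.
"""

import heatlag as hl

cfg = hl.PipelineConfig(
    simulation=hl.SimulationConfig(),  # 30 locations, 2 countries, 10 summers
    outdir="scratch/example_results",
)
res = hl.run_full_analysis(cfg)

print(res.country_summary.round(3).to_string(index=False))
print(
    "\nReading the table: in both countries the RR at the 99th percentile "
    "versus the MMP drops from early to late summer (truth: 1.419 -> 1.051), "
    "and the small Wald p-values reject the hypothesis of a constant "
    "exposure-response across the season."
)
print(f"full CSV outputs in {cfg.outdir}/")
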