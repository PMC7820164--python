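"""The full pipeline: paired historical vs contemporary scenario runs.

Each scenario generates a stand, burns it with the surrogate fire,
classifies mortality, and runs all six pattern statistics with global
envelopes plus the group analysis.  The comparison table condenses the
contrast into r-averaged z scores per statistic.

Takes a couple of minutes (two scenarios, 99 null simulations each).
"""

from firestand import (
    AnalysisConfig,
    PlotWindow,
    ScenarioConfig,
    compare_scenarios,
    run_scenario,
)

reports = {}
for era in ("historical", "contemporary"):
    cfg = ScenarioConfig(
        label=era,
        preset_era=era,
        window=PlotWindow(0, 200, 0, 100),      # 2 ha
        analysis=AnalysisConfig(n_sim=99),
        master_seed=11,
        out_dir=f"scratch/{era}",
    )
    reports[era] = run_scenario(cfg)
    print(f"{era}: {reports[era].prefire.n} trees, "
          f"{100 * (1 - reports[era].survivor_fraction):.0f}% killed")

comp = compare_scenarios(reports["historical"], reports["contemporary"])
print("\nper-statistic r-averaged z (a=historical, b=contemporary):")
print(comp["statistics"].to_string(index=False))
print("\ngroup-size comparison:")
print(comp["groups"].to_string(index=False))

# Expected contrast: the historical stand is more strongly aggregated
# before fire (larger g_all z), keeps an aggregated survivor pattern
# (g_alive z > 0), and retains multi-tree groups; the contemporary stand
# suffers near-total mortality leaving a sparse, unaggregated remnant.
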