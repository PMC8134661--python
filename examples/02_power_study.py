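"""Power of the combined test vs MANOVA and univariate Bonferroni.

The covariate trait's cohort has 5,000 individuals; the focal trait's
cohort is fully nested at 3,000. MANOVA can only use the 3,000-person
overlap, while the combined test uses both full cohorts — the source of
its advantage. Replicates are reduced here so the script runs in seconds;
rates carry the printed Monte-Carlo SEs.
"""

from btob import ScenarioConfig, power_frame, power_table, scenario_grid

base = ScenarioConfig(h2_1=0.005, h2_2=0.0, rho=0.6, n1=5000, n2=3000,
                      n_overlap=3000, reps=200, seed=42)
grid = scenario_grid(base, "h2_2", [0.0, 0.002, 0.005])
estimates = power_table(grid, ["btob", "manova", "univariate"], alpha=5e-8)

df = power_frame(estimates)
print(df[["method", "h2_2", "rate", "mc_se"]].to_string(index=False))
print("\nrate = fraction of replicates rejecting at alpha = 5e-8.")
print("btob >= manova expected at every h2_2 under partial overlap;")
print("the dip of btob between h2_2 = 0 and small h2_2 is real: the adjusted")
print("effect crosses zero as the focal trait's signal starts to cancel the bias.")
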