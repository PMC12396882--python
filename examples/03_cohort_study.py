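"""Run the full simulated cohort study and its statistical battery.

Twelve synthetic temporal-bone specimens are measured under TL-S, TL-R
(maximal patent retraction, independent re-scan) and TL-C (collapse
refitted inside the TL-S scan).  Contrasts against TL-S use a one-tailed
paired t-test (retraction can only open the corridor); TL-C vs TL-R is
two-tailed.  Percent increases are per-specimen changes relative to the
stationary sinus.
"""

from presigmoid import CohortConfig, analyze_cohort, simulate_study

table = simulate_study(CohortConfig(n_specimens=12, seed=1))
report = analyze_cohort(table)

print(table.groupby("procedure")[["sf_total", "ea_iac", "ea_bulb", "aa"]]
      .mean().round(1))
print()
print(report.summary())
print()
sig = report.correlations.query("p_two_tailed < 0.05")
print("significant correlations (p2 < 0.05):")
for _, row in sig.iterrows():
    print(f"  {row.x} vs {row.y}: r = {row.r:+.2f} (p2 = {row.p_two_tailed:.3f})")
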