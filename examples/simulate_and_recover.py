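"""Generate a synthetic cohort and recover the configured responses.

Simulates 8 participants at 2.4 g for the three rotation-axis positions,
runs the full cleaning/resampling/epoching pipeline, and compares the
recovered final-run-minute heart-rate delta per position against the
generator's configured values (50 / 24 / 8 bpm for P1 / P2 / P3).  The
recovered means should track the configured ones within sampling noise
(between-participant SD 15.5 / 11.6 / 7.8 bpm).
"""

import pandas as pd

from sahc import SimConfig, generate_trial, process_runs
from sahc.stats import final_run_delta_table

config = SimConfig(n_participants=8, channels=("HR", "CC", "cTSI"), g_levels=(2.4,), seed=7)
trial = generate_trial(config)
print(f"simulated {len(trial.runs)} runs ({config.n_participants} participants x 3 positions)")

epoch_table, _, rejected = process_runs(trial.runs, classify=False)
if rejected:
    print(f"channels rejected at the 95 % validity gate: {rejected}")

wide = final_run_delta_table(epoch_table)
recovered = wide.groupby("position")[["HR", "CC", "cTSI"]].mean()
configured = pd.DataFrame(
    {ch: {p: config.effects[ch][p][0] for p in ("P1", "P2", "P3")} for ch in ("HR", "CC", "cTSI")}
)
print("\nfinal-run-minute deltas by position (recovered vs configured):")
print(pd.concat({"recovered": recovered, "configured": configured}, axis=1).round(2))
print(
    "\nHR and CC rise (and cTSI falls) most with the axis above the head"
    "\n(P1, steepest g-gradient) and least with the axis at the heart (P3)."
)
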