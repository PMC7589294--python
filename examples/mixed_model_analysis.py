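"""Mixed-model inference on simulated epoch deltas.

Simulates a small cohort across all positions and g-levels, computes the
2 min epoch deltas, and fits the random-intercept linear mixed model
(heart-rate delta ~ time x position x foot g, random intercept per
participant).  Each effect is tested by a likelihood-ratio test against
the model without it; the per-epoch position contrast at 2.4 g is then
localized with one-way ANOVA + Tukey HSD.
"""

from sahc import SimConfig, generate_trial, process_runs
from sahc.stats import (
    add_position_code,
    epoch_anova_tukey,
    final_run_delta_table,
    lmm_effect_test,
)

config = SimConfig(n_participants=8, channels=("HR",), seed=3)
trial = generate_trial(config)
epoch_table, _, _ = process_runs(trial.runs, classify=False)
table = add_position_code(epoch_table.dropna(subset=["delta"]))
hr = table[table["channel"] == "HR"].rename(columns={"t_start": "time"})

print("likelihood-ratio tests (random-intercept LMM, ML fit):")
for effect in ("time", "position_code", "g_foot"):
    full, reduced, test = lmm_effect_test(hr, effect)
    print(
        f"  {effect:14s} chi2({test.df}) = {test.statistic:8.1f}   p = {test.pvalue:.3g}"
    )

wide = final_run_delta_table(table)
at_24 = wide[wide["g_foot"] == 2.4]
groups = {p: grp["HR"].to_numpy() for p, grp in at_24.groupby("position")}
res = epoch_anova_tukey(groups)
print(f"\nfinal-run-minute HR delta by position at 2.4 g: F = {res.f_statistic:.1f}, p = {res.pvalue:.3g}")
print(res.tukey.to_string(index=False))
print(
    "\nThe position effect reflects the g-gradient: the same foot-level g"
    "\nloads the carotid baroreceptors very differently depending on where"
    "\nthe rotation axis sits."
)
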