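"""Simulate the default 6-subject cohort and reproduce the regression +
repeated-measures ANOVA analysis.

Prints per-cell mean slopes/intercepts and the two ANOVA tables: the
uncertainty effect on slopes should be strongly significant, the force
effect should not be, and the intercept pattern should mirror between
the 'easy left' and 'easy right' blocks.
"""

import riskmotor as rm

config = rm.default_config()
trials = rm.simulate_cohort(config.subjects, config.design,
                            master_seed=config.seed, costs=config.costs)
print(f"simulated {len(trials)} trials "
      f"({len(config.subjects)} subjects x 3 blocks x "
      f"{config.design.trials_per_block} trials)\n")

regression = rm.regression_table(trials, burn_in=config.design.burn_in)
print("Across-subject cell means (deviation = target - response):")
print(rm.summarize_cells(regression).to_string(index=False,
      float_format=lambda v: f"{v:8.3f}"))

for response in ("slope", "intercept"):
    table = rm.run_rm_anova(regression, response)
    print(f"\nRepeated-measures ANOVA on {response}s:")
    print(table[["effect", "df", "df_error", "F", "p"]].to_string(
        index=False, float_format=lambda v: f"{v:10.4g}"))
print("\nSlopes rise FULL -> BLUR -> NONE in every force block (uncertainty"
      "\neffect), intercepts deviate towards the cheap side only under"
      "\nuncertainty (force x uncertainty interaction).")
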