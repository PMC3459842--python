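"""Small simulate-then-fit recovery study.

Runs 10 replicates of simulating a risk-seeking subject (600 trials) and
fitting it back, then prints per-parameter bias and RMSE.  Larger runs
(50+ replicates) tighten these numbers; see scripts/acceptance.py.
"""

import riskmotor as rm

constants = rm.DesignConstants(sigma_p=2.0, Q=1e4,
                               costs=rm.default_costs(c1=0.5, c0=2.0))
subject = rm.SubjectSpec(
    "r1",
    rm.ModelParams(sigma_p=2.0, Q=1e4, theta=0.5, sigma_m=0.2, halfwidth=1.0),
    sigma_blur=1.0,
)
report, estimates = rm.recover_parameters(
    [subject], rm.DesignSpec(trials_per_block=200), constants,
    options=rm.FitOptions(seed=3), n_replicates=10, seed=2024,
)
print(report.to_string(index=False, float_format=lambda v: f"{v:10.4f}"))
print("\nBias ~ 0 and small RMSE mean the maximum-likelihood machinery can"
      "\nrecover the risk attitude and noise levels from behaviour alone.")
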