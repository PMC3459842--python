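# Default study conditions for riskmotor's synthetic cohorts.
#
# Positions in cm (positive = rightward, origin = target-distribution
# centre), costs in abstract cost units, theta in 1/cost units.  These
# values define a plausible instance of the interception task; see
# docs/methods.md for the rationale behind each choice.
seed: 20120927
output_dir: riskmotor_out
design:
  trials_per_block: 200
  feedback_weights: [2, 1, 1]   # relative frequencies FULL : BLUR : NONE
  block_order: [F0, FL, FR]
  burn_in: 0                    # synthetic responders have no learning phase
model:
  sigma_p: 2.0                  # prior s.d. of target position (cm)
  Q: 10000.0                    # hit-cost weight; large => constant bias ~ 0
  halfwidth: 1.0                # target half-width (cm)
  sigma_o_full: 0.0             # FULL condition modelled as noiseless
costs:
  c0: 2.0                       # cost offset (keeps effort positive; no behavioural effect)
  c1: 0.5                       # |cost slope| per cm; +c1 in FL, -c1 in FR
subjects:                       # six risk-seeking responders (theta > 0)
  - {subject_id: s01, theta: 0.50, sigma_m: 0.25, sigma_blur: 2.0}
  - {subject_id: s02, theta: 0.65, sigma_m: 0.35, sigma_blur: 1.8}
  - {subject_id: s03, theta: 0.80, sigma_m: 0.30, sigma_blur: 2.2}
  - {subject_id: s04, theta: 0.80, sigma_m: 0.28, sigma_blur: 2.0}
  - {subject_id: s05, theta: 0.95, sigma_m: 0.32, sigma_blur: 1.9}
  - {subject_id: s06, theta: 1.10, sigma_m: 0.27, sigma_blur: 2.1}
analysis:
  axis_flip: false
  gg_correction: false
fitting:
  n_starts: 5
  theta_bounds: [-2.0, 2.0]
  sigma_blur_bounds: [0.05, 20.0]
  sigma_m_bounds: [0.0001, 10.0]
  k0_bounds: [-5.0, 5.0]
  breakdown_margin: 0.05
  seed: 7
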