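# Methods

This note documents the models implemented in `riskmotor`, the default
study conditions, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Generative model of a trial

All positions are lateral coordinates in cm, positive rightward, origin
at the centre of the target distribution.  Per trial:

1. target x ~ N(0, σ_p²);
2. cue o ~ N(x, σ_o²), where σ_o is set by the feedback condition:
   FULL → σ_o = 0 (configurable small positive `sigma_o_full`), BLUR →
   σ_o = σ_blur, NONE → σ_o = ∞ (no cue is generated; recording one is
   treated as an input error, not silently ignored);
3. the responder forms the Gaussian posterior (x̂, σ̂²) with
   x̂ = wo, w = σ_p²/(σ_p²+σ_o²), σ̂² = wσ_o²;
4. response r = x̂ − c₁/(2Q) − (θ/2)c₁σ̂² + ε, ε ~ N(0, σ_m²);
5. hit ⇔ |r − x| ≤ halfwidth.

The response rule is the exact minimiser of the exponential-utility
stress S(r) = −(2/θ)·log E[exp(−(θ/2)Q(x−r)²)] + c(r); expanding the
Gaussian integral gives the closed form in `riskmotor.model`.  The
transform requires 1 + θQσ̂² > 0; for θ < 0 (risk aversion) this fails
once pessimism outweighs the evidence ("breakdown"), and with a large Q
it fails almost immediately, so in practice only θ ≥ 0 is explorable
under the default conditions — a property of the model, not of the
implementation.

Sign conventions.  θ > 0 is the optimistic attitude that produces a bias
*towards* the cheap side; c₁ > 0 ("easy left", block FL) means cost
grows to the right; the analysed deviation is d = x − r, which makes the
no-feedback condition the identity line (slope 1).  With the opposite
axis orientation all intercepts change sign only; `regression_table`
exposes an `axis_flip` flag and records the convention in its metadata,
and all shipped checks assert sign-symmetric/magnitude claims only.

The derived regression line of d on x is E[d|x] = slope·x + intercept
with slope = σ_o²/(σ_p²+σ_o²) (force-independent) and intercept =
c₁/(2Q) + (θ/2)c₁σ̂².  The hit probability is closed-form because
r − x ~ N(−intercept, σ̂² + σ_m²): the shrinkage and cue-noise
contributions to Var(r − x) collapse exactly to the posterior variance.

## Default study conditions

The experiment they emulate used placeholder-free magnitudes that are
not recoverable, so the defaults in `src/riskmotor/defaults.yaml` are
the package's own choice of a realistic instance, fixed once:

| parameter | default | why |
|---|---|---|
| σ_p | 2.0 cm | typical lateral spread of target priors in reaching set-ups |
| σ_blur | ≈2 cm (per subject 1.8–2.2) | puts the BLUR slope near 0.5, midway between FULL (0) and NONE (1) |
| σ_m | 0.25–0.35 cm | motor noise small relative to the prior spread |
| halfwidth | 1.0 cm | makes FULL hits near-certain and NONE hits ~35% |
| Q | 10⁴ | large hit weight ⇒ constant bias c₁/(2Q) = 2.5×10⁻⁵·c₁ cm ≈ 0 |
| c₁ | ±0.5 cost/cm (FL/FR), 0 (F0) | NONE-condition bias (θ/2)c₁σ_p² ≈ 0.8θ cm, well resolved above σ_m |
| c₀ | 2.0 | keeps effort positive over the workspace; no behavioural effect |
| design | 3 blocks (F0, FL, FR) × 200 trials, feedback 2:1:1 | 600 analysed trials/subject |
| subjects | 6, θ ∈ [0.5, 1.1] | small heterogeneous risk-seeking cohort |
| burn_in | 0 | no learning dynamics are simulated; real data should exclude early trials per block |

The BLUR display is abstracted to a single scalar cue with noise
σ_blur.  An optional `blur_mode="cloud"` draws the cue as the mean of
`cloud_size` (default 5) samples of s.d. σ_blur, i.e. effective noise
σ_blur/√5, covering the interpretation that subjects average a dot
cloud.  Movement kinematics, the physical viscous-force ramp, return
movements and auditory feedback are not modelled; the force field enters
only through the scalar cost c(r), whose slope absorbs the unknown
physical conversion constant.

Seeding: one master seed per cohort; per-subject design and simulation
seeds are spawned with `numpy.random.SeedSequence` in subject order
(31-bit children), making cohorts bit-reproducible and subjects
independent.

## Regression and ANOVA

Each subject × force × feedback cell is fit by OLS of d on x
(scipy's `linregress`, ≥3 trials and nonzero target variance required).
The slopes (or intercepts) then enter a classical balanced two-way
repeated-measures ANOVA in which each within-subject effect is tested
against its subject-by-effect interaction mean square (df 2, 2 and 4
against 2(S−1), 2(S−1), 4(S−1)).  The sum-of-squares decomposition is
computed directly (and conserves total SS to 1e−9 relative); the F and p
values are cross-checked in the test suite against statsmodels'
`AnovaRM`.  No sphericity correction is applied by default, matching the
plain RM-ANOVA reported for this paradigm; a Greenhouse–Geisser option
computes ε from the orthonormal-contrast covariance (Kronecker contrasts
for the interaction) and is off by default.  A degenerate all-constant
table returns F = 0, p = 1.

Note that with mirrored costs (c₁ and −c₁) the uncertainty modulation of
the intercept cancels in the uncertainty *main effect* and appears as
the force × uncertainty interaction; the slope carries a pure
uncertainty main effect.

## Maximum-likelihood fitting

Marginalising the unobserved cue, r | x ~ N(wx + k, wσ̂² + σ_m²) with
k = −c₁(k₀ + (θ/2)σ̂²).  The per-subject free parameters are θ, σ_blur,
σ_m and the nuisance constant k₀ (standing in for 1/(2Q); Q is not
separately identifiable from behaviour and is fixed only in simulation).
σ_p and the cost slopes are design constants known to the analyst.
Identifiability requires ≥2 feedback conditions and ≥1 block with
c₁ ≠ 0; violations raise an explicit error.

Optimisation: L-BFGS-B on the bounded box θ ∈ [θ_lo, 2],
σ_blur ∈ [0.05, 20] cm, σ_m ∈ [10⁻⁴, 10] cm, k₀ ∈ [−5, 5] cm, where
θ_lo keeps 1 + θQσ_p² > 0.05 away from the breakdown boundary (with the
default Q = 10⁴ this pins θ_lo ≈ −2.4×10⁻⁵).  One method-of-moments
start (σ_m from FULL residuals, σ_blur from the BLUR response slope, θ
from the mean NONE-block bias) plus four seeded uniform restarts; the
best optimum is reported with a convergence flag, never silently.  The
recovery harness repeats simulate→fit and reports per-parameter bias,
RMSE and relative RMSE; k₀'s relative RMSE is dominated by its
near-zero truth and is reported for completeness only.  Interval
estimates (and hence coverage) are not produced.

## Problem sizes and runtimes

The shipped checks use the default cohort (6 × 600 analysed trials),
100 replicate cohorts for the ANOVA detection rates, 50 replicate fits
(600 trials each) for recovery, a ~1100-point grid for the
closed-form-vs-minimisation comparison (tolerance 10⁻⁶ cm; quadrature
agreement to 10⁻⁸ relative), and 10⁶ Monte-Carlo samples for the
hit-probability comparison.  These sizes were chosen so the full suite
and the acceptance script each complete in well under a minute on one
CPU while leaving Monte-Carlo error far below the tolerances tested.

## What passing tests show — and what they do not

The synthetic generator realises exactly the stationary model above, so
the analysis pipeline is validated against a matched truth: regressions
converge to the predicted lines, the ANOVA detects the designed pattern,
and the MLE recovers generating parameters.  Real data differ in ways
deliberately not simulated: trial-by-trial learning of the prior (hence
the burn-in option), kinematic/temporal structure, possibly non-Gaussian
motor noise, sequential effects, and subjects whose cue use is not
exactly Bayesian.  Passing tests therefore certify the correctness of
the formulas and machinery, not the adequacy of the model for any
particular data set.

## Known limitations

- Static one-step decisions only; no dynamic (multi-step LQG/Kalman)
  risk-sensitive control.
- Risk aversion (θ < 0) is effectively outside the explorable region
  whenever Qσ̂² is large, by the breakdown bound.
- The ANOVA requires a complete balanced 3×3 table per subject; missing
  cells are an error rather than being imputed.
- Fitting assumes σ_p and c₁ known; misspecifying them biases θ.
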