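"""Single-trial Bayesian estimation and risk-sensitive response models.

The task being modelled is a target-interception reach: on each trial a
target appears at a lateral position ``x`` drawn from a zero-mean Gaussian
prior with standard deviation ``sigma_p``; the subject receives visual
feedback ``o`` about the target corrupted by Gaussian noise whose standard
deviation ``sigma_o`` depends on the feedback condition (clear display,
blurred cloud, or no feedback at all), and indicates a lateral response
``r`` halfway into the movement.  Missing the target incurs a quadratic
cost ``Q*(x - r)**2`` and the response position itself carries a linear
effort cost ``c(r) = c0 + c1*r`` induced by a viscous force field.

Combining prior and cue gives the Gaussian posterior belief

    x | o  ~  Normal(x_hat, s2),
    x_hat = sigma_p**2 * o / (sigma_p**2 + sigma_o**2),
    s2    = sigma_p**2 * sigma_o**2 / (sigma_p**2 + sigma_o**2).

A *risk-neutral* responder minimises posterior expected cost and answers
``x_hat - c1/(2Q)`` — a bias that is independent of the uncertainty.  A
*risk-sensitive* responder instead minimises the exponential-utility
("stress") transform of the trial cost,

    S(r) = -(2/theta) * log E[ exp(-(theta/2) * Q*(x - r)**2) ] + c(r)
         = (1/theta) * log(1 + theta*Q*s2)
           + Q*(x_hat - r)**2 / (1 + theta*Q*s2) + c0 + c1*r,

whose unique minimiser is

    r* = x_hat - (c1 / (2Q)) * (1 + theta*Q*s2)
       = x_hat - c1/(2Q) - (theta/2) * c1 * s2.

For ``theta > 0`` (the optimistic, risk-seeking attitude used throughout
this package) the response is pushed towards the cheap side of the
workspace by an amount *proportional to the posterior variance*: the bias
vanishes under full feedback and is largest with no feedback.  That
interaction between effort cost and estimation uncertainty is the model's
signature and what the downstream regression pipeline measures.  The
transform is only defined while ``1 + theta*Q*s2 > 0``; crossing that
bound (possible only for ``theta < 0``) raises :class:`RiskBreakdownError`.

Axis convention: positive = rightward, origin at the centre of the target
distribution.  All positions are in cm, costs in abstract cost units,
``theta`` in 1/cost units.

Functions accept scalars or NumPy arrays for the observation/posterior
mean and broadcast accordingly; condition-level parameters are scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import (
    InconsistentInputError,
    InvalidParameterError,
    RiskBreakdownError,
)

__all__ = [
    "FEEDBACK_LABELS",
    "FORCE_LABELS",
    "FeedbackCondition",
    "CostFunction",
    "ModelParams",
    "PosteriorBelief",
    "posterior_update",
    "expected_cost",
    "risk_neutral_response",
    "stress_value",
    "risk_sensitive_response",
    "predicted_slope_intercept",
    "hit_probability",
]

FEEDBACK_LABELS = ("FULL", "BLUR", "NONE")
FORCE_LABELS = ("F0", "FL", "FR")


@dataclass(frozen=True)
class FeedbackCondition:
    """A feedback condition: a label and its observation noise (cm).

    FULL shows the target clearly (sigma_o == 0 by default; a small
    positive value is allowed as a configuration choice), BLUR shows a
    noisy cue (0 < sigma_o < inf), NONE shows nothing (sigma_o == inf).
    """

    label: str
    sigma_o: float

    def __post_init__(self) -> None:
        if self.label not in FEEDBACK_LABELS:
            raise InvalidParameterError(
                f"feedback label must be one of {FEEDBACK_LABELS}, got {self.label!r}"
            )
        s = float(self.sigma_o)
        if s < 0 or math.isnan(s):
            raise InvalidParameterError(f"sigma_o must be >= 0, got {s}")
        if self.label == "NONE" and not math.isinf(s):
            raise InvalidParameterError("NONE condition requires sigma_o = +inf")
        if self.label == "BLUR" and not (0.0 < s < math.inf):
            raise InvalidParameterError("BLUR condition requires 0 < sigma_o < inf")
        if self.label == "FULL" and math.isinf(s):
            raise InvalidParameterError("FULL condition requires finite sigma_o")

    @classmethod
    def full(cls, sigma_o: float = 0.0) -> "FeedbackCondition":
        return cls("FULL", sigma_o)

    @classmethod
    def blur(cls, sigma_o: float) -> "FeedbackCondition":
        return cls("BLUR", sigma_o)

    @classmethod
    def none(cls) -> "FeedbackCondition":
        return cls("NONE", math.inf)


@dataclass(frozen=True)
class CostFunction:
    """Linear response cost ``c(r) = c0 + c1*r`` for one force condition.

    ``c1 > 0`` means responses to the right are more effortful ("easy
    left", label FL); ``c1 < 0`` is the mirrored "easy right" (FR); the
    no-force block F0 has ``c0 = c1 = 0``.  The linear function stands in
    for the scalar effort induced by the experimental viscous force; its
    slope absorbs the (unmodelled) physical conversion constant.
    """

    c0: float
    c1: float
    label: str = "F0"

    def __post_init__(self) -> None:
        if self.label not in FORCE_LABELS:
            raise InvalidParameterError(
                f"force label must be one of {FORCE_LABELS}, got {self.label!r}"
            )
        if not (math.isfinite(self.c0) and math.isfinite(self.c1)):
            raise InvalidParameterError("cost coefficients must be finite")
        if self.label == "F0" and (self.c0 != 0.0 or self.c1 != 0.0):
            raise InvalidParameterError("F0 condition requires c0 = c1 = 0")

    def __call__(self, r):
        return self.c0 + self.c1 * np.asarray(r, dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Generative and decision parameters shared across trials.

    sigma_p    prior s.d. of the lateral target position (cm), > 0
    Q          target-hit cost weight (cost units / cm**2), > 0
    theta      risk-sensitivity (1 / cost units); 0 = risk-neutral,
               > 0 = optimistic/risk-seeking (biases towards cheap
               responses under uncertainty), < 0 = risk-averse
    sigma_m    motor noise s.d. added to the response (cm), >= 0
    halfwidth  target half-width used for the hit criterion (cm), > 0
    """

    sigma_p: float
    Q: float
    theta: float = 0.0
    sigma_m: float = 0.0
    halfwidth: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_p > 0 and math.isfinite(self.sigma_p)):
            raise InvalidParameterError(f"sigma_p must be > 0, got {self.sigma_p}")
        if not (self.Q > 0 and math.isfinite(self.Q)):
            raise InvalidParameterError(f"Q must be > 0, got {self.Q}")
        if self.sigma_m < 0 or not math.isfinite(self.sigma_m):
            raise InvalidParameterError(f"sigma_m must be >= 0, got {self.sigma_m}")
        if not (self.halfwidth > 0):
            raise InvalidParameterError(f"halfwidth must be > 0, got {self.halfwidth}")
        if not math.isfinite(self.theta):
            raise InvalidParameterError("theta must be finite")


@dataclass(frozen=True)
class PosteriorBelief:
    """Gaussian belief over the target position: mean x_hat and variance.

    ``mean`` may be an array (one entry per trial); ``variance`` is the
    scalar posterior variance shared by trials of one feedback condition.
    """

    mean: object  # float or ndarray
    variance: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.variance) < 0):
            raise InvalidParameterError("posterior variance must be >= 0")


def _posterior_moments(sigma_p: float, sigma_o: float) -> tuple[float, float]:
    """Return (shrinkage weight w, posterior variance s2) for one condition.

    w = sigma_p**2/(sigma_p**2 + sigma_o**2) is the weight on the cue;
    s2 = w * sigma_o**2 = (1 - w) * sigma_p**2.
    """
    if math.isinf(sigma_o):
        return 0.0, sigma_p**2
    vp, vo = sigma_p**2, sigma_o**2
    w = vp / (vp + vo)
    return w, w * vo


def posterior_update(observation, sigma_p: float, sigma_o: float) -> PosteriorBelief:
    """Combine the Gaussian prior with a noisy cue into a posterior belief.

    Parameters
    ----------
    observation : float, ndarray or None
        Observed cue position(s) (cm).  Must be ``None`` exactly when
        ``sigma_o`` is infinite (no feedback).
    sigma_p, sigma_o : float
        Prior and observation noise standard deviations (cm).

    Returns
    -------
    PosteriorBelief
        mean = sigma_p**2 * o / (sigma_p**2 + sigma_o**2) and
        variance = sigma_p**2 * sigma_o**2 / (sigma_p**2 + sigma_o**2);
        the prior (0, sigma_p**2) when there is no feedback, and the exact
        observation (o, 0) when the cue is noiseless.
    """
    if not (sigma_p > 0 and math.isfinite(sigma_p)):
        raise InvalidParameterError(f"sigma_p must be positive and finite, got {sigma_p}")
    if sigma_o < 0 or math.isnan(sigma_o):
        raise InvalidParameterError(f"sigma_o must be >= 0, got {sigma_o}")
    if math.isinf(sigma_o):
        if observation is not None:
            raise InconsistentInputError(
                "an observation was recorded although sigma_o is infinite"
            )
        return PosteriorBelief(0.0, sigma_p**2)
    if observation is None:
        raise InconsistentInputError("observation missing but sigma_o is finite")
    obs = np.asarray(observation, dtype=float)
    if obs.ndim == 0:
        obs = float(obs)
    w, s2 = _posterior_moments(sigma_p, sigma_o)
    return PosteriorBelief(w * obs, s2)


def expected_cost(r, belief: PosteriorBelief, Q: float, cost: CostFunction):
    """Posterior expected trial cost E[Q*(x - r)**2] + c(r).

    Equals Q*((mean - r)**2 + variance) + c0 + c1*r; the variance term is
    irreducible and does not affect the minimiser.
    """
    r = np.asarray(r, dtype=float)
    out = Q * ((np.asarray(belief.mean) - r) ** 2 + belief.variance) + cost(r)
    return float(out) if out.ndim == 0 else out


def risk_neutral_response(belief: PosteriorBelief, Q: float, cost: CostFunction):
    """Minimiser of the expected cost: posterior mean shifted by c1/(2Q).

    Independent of the posterior variance — a risk-neutral responder's
    cost bias does not interact with uncertainty.
    """
    if Q <= 0:
        raise InvalidParameterError(f"Q must be > 0, got {Q}")
    out = np.asarray(belief.mean, dtype=float) - cost.c1 / (2.0 * Q)
    return float(out) if out.ndim == 0 else out


def _breakdown_factor(theta: float, Q: float, variance: float) -> float:
    d = 1.0 + theta * Q * variance
    if d <= 0:
        raise RiskBreakdownError(
            f"1 + theta*Q*variance = {d:.6g} <= 0: exponential-utility "
            "integral diverges (risk-averse breakdown)"
        )
    return d


def stress_value(r, belief: PosteriorBelief, Q: float, theta: float, cost: CostFunction):
    """Risk-sensitive stress of response r under the posterior belief.

    Closed form of -(2/theta)*log E[exp(-(theta/2)*Q*(x-r)**2)] + c(r):

        (1/theta)*log(1 + theta*Q*s2) + Q*(mean - r)**2/(1 + theta*Q*s2)
        + c0 + c1*r

    with the continuous extension to the expected cost at theta = 0.
    Raises :class:`RiskBreakdownError` when 1 + theta*Q*s2 <= 0.
    """
    if theta == 0.0:
        return expected_cost(r, belief, Q, cost)
    d = _breakdown_factor(theta, Q, belief.variance)
    r = np.asarray(r, dtype=float)
    out = (
        math.log(d) / theta
        + Q * (np.asarray(belief.mean) - r) ** 2 / d
        + cost(r)
    )
    return float(out) if out.ndim == 0 else out


def risk_sensitive_response(
    belief: PosteriorBelief, Q: float, theta: float, cost: CostFunction
):
    """Unique minimiser of :func:`stress_value` in r.

        r* = mean - (c1/(2Q)) * (1 + theta*Q*variance)
           = mean - c1/(2Q) - (theta/2)*c1*variance

    theta > 0 shifts the response towards the low-cost side by an amount
    growing with the posterior variance; with zero variance or theta = 0
    it coincides with the risk-neutral response.
    """
    if Q <= 0:
        raise InvalidParameterError(f"Q must be > 0, got {Q}")
    d = _breakdown_factor(theta, Q, belief.variance)
    out = np.asarray(belief.mean, dtype=float) - (cost.c1 / (2.0 * Q)) * d
    return float(out) if out.ndim == 0 else out


def _cost_bias(theta: float, Q: float, c1: float, variance: float) -> float:
    """Uncertainty-modulated cost bias b = c1/(2Q) + (theta/2)*c1*variance."""
    _breakdown_factor(theta, Q, variance)
    return c1 / (2.0 * Q) + 0.5 * theta * c1 * variance


def predicted_slope_intercept(
    params: ModelParams, feedback: FeedbackCondition, cost: CostFunction
) -> tuple[float, float]:
    """Predicted regression line of lateral deviation d = x - r on x.

    Averaging the generative model over cue noise gives
    E[d | x] = slope * x + intercept with

        slope     = sigma_o**2 / (sigma_p**2 + sigma_o**2)   in [0, 1]
        intercept = c1/(2Q) + (theta/2)*c1*s2(feedback)      (cm)

    The slope rises from 0 (full feedback) to 1 (no feedback: the subject
    aims at the prior mean so the deviation tracks the target), and is
    independent of the force condition; the intercept is the cost bias,
    proportional to the posterior variance for theta != 0.
    """
    w, s2 = _posterior_moments(params.sigma_p, feedback.sigma_o)
    slope = 1.0 - w
    intercept = _cost_bias(params.theta, params.Q, cost.c1, s2)
    return slope, intercept


def hit_probability(
    params: ModelParams, feedback: FeedbackCondition, cost: CostFunction
) -> float:
    """Probability of hitting the target under the full generative model.

    With x ~ prior, o ~ likelihood, r = risk-sensitive response + motor
    noise, the error r - x is Gaussian with mean -(cost bias) and variance
    s2 + sigma_m**2 (the shrinkage and cue-noise contributions collapse to
    the posterior variance s2).  Returns P(|r - x| <= halfwidth).
    """
    if params.halfwidth <= 0:
        raise InvalidParameterError("halfwidth must be > 0")
    _, s2 = _posterior_moments(params.sigma_p, feedback.sigma_o)
    mu = -_cost_bias(params.theta, params.Q, cost.c1, s2)
    var = s2 + params.sigma_m**2
    h = params.halfwidth
    if var == 0.0:
        return 1.0 if abs(mu) <= h else 0.0
    sd = math.sqrt(var)
    return float(norm.cdf((h - mu) / sd) - norm.cdf((-h - mu) / sd))
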