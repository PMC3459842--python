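"""Synthetic experiment designs and cohorts of risk-sensitive responders.

Emulates the structure of the interception study: three sequential force
blocks (no force, "easy left", "easy right"), trial-wise feedback
conditions drawn with relative frequencies (2, 1, 1) for (FULL, BLUR,
NONE), lateral targets from a zero-mean Gaussian, and per-trial responses
from the risk-sensitive decision model plus motor noise.  No learning
dynamics or kinematics are simulated; behaviour is stationary within a
block, so the burn-in filter of the analysis stage defaults to zero for
synthetic cohorts.

Seeding scheme: a cohort takes one master seed; per-subject simulation
seeds are derived with ``numpy.random.SeedSequence(master_seed).spawn``,
in subject-list order, so cohorts are bit-reproducible and subjects are
statistically independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InconsistentInputError, InvalidParameterError
from .model import (
    FEEDBACK_LABELS,
    FORCE_LABELS,
    CostFunction,
    ModelParams,
    posterior_update,
    risk_sensitive_response,
)

__all__ = [
    "TRIAL_COLUMNS",
    "DesignSpec",
    "SubjectSpec",
    "TrialRecord",
    "make_design",
    "simulate_subject",
    "simulate_cohort",
    "default_costs",
]

#: Column order of every trial table produced or consumed by this package.
TRIAL_COLUMNS = (
    "subject_id",
    "block_index",
    "trial_index",
    "force_label",
    "feedback_label",
    "target_x",
    "observation_x",
    "response_x",
    "hit",
)


@dataclass(frozen=True)
class TrialRecord:
    """One trial; ``observation_x`` is None exactly on NONE trials."""

    subject_id: str
    block_index: int
    trial_index: int
    force_label: str
    feedback_label: str
    target_x: float
    observation_x: float | None
    response_x: float
    hit: bool


@dataclass(frozen=True)
class DesignSpec:
    """Experiment design: block structure and feedback randomisation.

    feedback_weights are the relative frequencies of (FULL, BLUR, NONE);
    burn_in is the number of leading trials per block excluded later at
    analysis time (they are still simulated).
    """

    trials_per_block: int = 200
    feedback_weights: tuple[int, int, int] = (2, 1, 1)
    block_order: tuple[str, str, str] = FORCE_LABELS
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block <= self.burn_in:
            raise InvalidParameterError(
                "trials_per_block must exceed burn_in "
                f"({self.trials_per_block} <= {self.burn_in})"
            )
        if self.burn_in < 0:
            raise InvalidParameterError("burn_in must be >= 0")
        w = tuple(self.feedback_weights)
        if len(w) != 3 or any(x < 0 for x in w) or sum(w) == 0:
            raise InvalidParameterError(
                f"feedback_weights must be 3 nonnegative ints, not all zero: {w}"
            )
        if sorted(self.block_order) != sorted(FORCE_LABELS):
            raise InvalidParameterError(
                f"block_order must be a permutation of {FORCE_LABELS}"
            )


@dataclass(frozen=True)
class SubjectSpec:
    """A synthetic subject: decision parameters plus their cue noise.

    ``sigma_blur`` is the effective scalar cue noise in the BLUR condition
    when ``blur_mode == "scalar"`` (default).  With ``blur_mode ==
    "cloud"`` the displayed five-sample Gaussian cloud is emulated: the
    cue is the mean of ``cloud_size`` draws with s.d. ``sigma_blur``, so
    the effective observation noise is ``sigma_blur / sqrt(cloud_size)``.
    """

    subject_id: str
    params: ModelParams
    sigma_blur: float
    blur_mode: str = "scalar"
    cloud_size: int = 5

    def __post_init__(self) -> None:
        if not (self.sigma_blur > 0 and np.isfinite(self.sigma_blur)):
            raise InvalidParameterError("sigma_blur must be positive and finite")
        if self.blur_mode not in ("scalar", "cloud"):
            raise InvalidParameterError("blur_mode must be 'scalar' or 'cloud'")
        if self.cloud_size < 1:
            raise InvalidParameterError("cloud_size must be >= 1")

    def effective_sigma_o(self, feedback_label: str, sigma_o_full: float = 0.0) -> float:
        if feedback_label == "FULL":
            return sigma_o_full
        if feedback_label == "BLUR":
            if self.blur_mode == "cloud":
                return self.sigma_blur / np.sqrt(self.cloud_size)
            return self.sigma_blur
        if feedback_label == "NONE":
            return np.inf
        raise InvalidParameterError(f"unknown feedback label {feedback_label!r}")


def default_costs(c1: float = 0.5, c0: float = 2.0) -> dict[str, CostFunction]:
    """Cost functions per force block: F0 free, FL 'easy left' (+c1),
    FR 'easy right' (-c1)."""
    return {
        "F0": CostFunction(0.0, 0.0, "F0"),
        "FL": CostFunction(c0, abs(c1), "FL"),
        "FR": CostFunction(c0, -abs(c1), "FR"),
    }


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Lay out the trial sequence of one session.

    Blocks follow ``spec.block_order``; within each block, feedback
    labels are drawn i.i.d. with probabilities proportional to
    ``feedback_weights``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.feedback_weights, dtype=float)
    p = p / p.sum()
    n = spec.trials_per_block
    frames = []
    for bi, force in enumerate(spec.block_order, start=1):
        labels = rng.choice(FEEDBACK_LABELS, size=n, p=p)
        frames.append(
            pd.DataFrame(
                {
                    "block_index": bi,
                    "trial_index": np.arange(1, n + 1),
                    "force_label": force,
                    "feedback_label": labels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_subject(
    subject: SubjectSpec,
    design: pd.DataFrame,
    costs: Mapping[str, CostFunction] | None = None,
    seed: int = 0,
    sigma_o_full: float = 0.0,
) -> pd.DataFrame:
    """Simulate one subject's responses over a laid-out design.

    Per trial: target ~ N(0, sigma_p**2); cue ~ N(target, sigma_o**2) for
    the trial's feedback condition (absent on NONE trials); response =
    risk-sensitive response to the posterior belief + N(0, sigma_m**2)
    motor noise; hit = |response - target| <= halfwidth.

    The random stream draws, in order, all targets, all cue-noise
    deviates, and all motor-noise deviates (cue noise is drawn for every
    trial and discarded on NONE trials so the stream layout is
    independent of the feedback sequence).
    """
    costs = default_costs() if costs is None else costs
    params = subject.params
    n = len(design)
    rng = np.random.default_rng(seed)
    target = rng.normal(0.0, params.sigma_p, size=n)
    cue_z = rng.standard_normal(n)
    motor = rng.normal(0.0, params.sigma_m, size=n) if params.sigma_m > 0 else np.zeros(n)

    observation = np.full(n, np.nan)
    response = np.empty(n)
    for force in design["force_label"].unique():
        cost = costs[force]
        for fb in design.loc[design["force_label"] == force, "feedback_label"].unique():
            mask = (
                (design["force_label"] == force).to_numpy()
                & (design["feedback_label"] == fb).to_numpy()
            )
            sigma_o = subject.effective_sigma_o(fb, sigma_o_full)
            if np.isinf(sigma_o):
                belief = posterior_update(None, params.sigma_p, sigma_o)
            else:
                obs = target[mask] + sigma_o * cue_z[mask]
                observation[mask] = obs
                belief = posterior_update(obs, params.sigma_p, sigma_o)
            response[mask] = (
                risk_sensitive_response(belief, params.Q, params.theta, cost)
                + motor[mask]
            )

    out = design.copy()
    out.insert(0, "subject_id", subject.subject_id)
    out["target_x"] = target
    out["observation_x"] = observation
    out["response_x"] = response
    out["hit"] = np.abs(response - target) <= params.halfwidth
    return out[list(TRIAL_COLUMNS)]


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def simulate_cohort(
    subjects: Sequence[SubjectSpec],
    design_spec: DesignSpec,
    master_seed: int,
    costs: Mapping[str, CostFunction] | None = None,
    sigma_o_full: float = 0.0,
) -> pd.DataFrame:
    """Simulate a cohort; each subject gets their own randomised design
    and response stream, both derived deterministically from the master
    seed (see module docstring).  Subject order is as given."""
    if len(subjects) < 1:
        raise InvalidParameterError("need at least one subject")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise InconsistentInputError(f"duplicate subject_id in cohort: {ids}")
    seeds = _spawn_seeds(master_seed, 2 * len(subjects))
    frames = []
    for i, subject in enumerate(subjects):
        design = make_design(dataclasses.replace(design_spec, seed=seeds[2 * i]))
        frames.append(
            simulate_subject(
                subject, design, costs=costs, seed=seeds[2 * i + 1],
                sigma_o_full=sigma_o_full,
            )
        )
    return pd.concat(frames, ignore_index=True)
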