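"""Maximum-likelihood estimation of decision parameters from trial tables.

Marginalising the unobserved cue, the response on a trial with target x is
Gaussian:

    r | x ~ Normal(w*x + k,  w*s2 + sigma_m**2),
    w  = sigma_p**2 / (sigma_p**2 + sigma_o**2)   (cue weight),
    s2 = w * sigma_o**2                            (posterior variance),
    k  = -c1*k0 - (theta/2)*c1*s2                  (cost bias, sign-flipped),

where k0 plays the role of the constant trade-off 1/(2Q) and is treated
as a free nuisance offset per unit c1 (Q itself is not separately
identifiable and is fixed only in simulation).  The free parameters per
subject are (theta, sigma_blur, sigma_m, k0); sigma_p and the cost slopes
c1 per block are design constants known to the experimenter.

Optimisation is bounded L-BFGS-B with a method-of-moments start plus
seeded random multi-starts; the theta lower bound keeps
1 + theta*Q*s2 > breakdown_margin away from the exponential-utility
divergence.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import linregress

from .errors import (
    IdentifiabilityError,
    InvalidParameterError,
    RiskBreakdownError,
)
from .model import CostFunction, _posterior_moments
from .simulate import DesignSpec, SubjectSpec, _spawn_seeds, simulate_cohort

__all__ = [
    "DesignConstants",
    "CandidateParams",
    "FitOptions",
    "FitResult",
    "trial_loglik",
    "table_loglik",
    "fit_subject_mle",
    "recover_parameters",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class DesignConstants:
    """Quantities fixed by the experimental design, not estimated."""

    sigma_p: float
    Q: float
    costs: Mapping[str, CostFunction]
    sigma_o_full: float = 0.0


@dataclass(frozen=True)
class CandidateParams:
    """Free parameters of the per-subject likelihood."""

    theta: float
    sigma_blur: float
    sigma_m: float
    k0: float = 0.0


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 5
    theta_bounds: tuple[float, float] = (-2.0, 2.0)
    sigma_blur_bounds: tuple[float, float] = (0.05, 20.0)
    sigma_m_bounds: tuple[float, float] = (1e-4, 10.0)
    k0_bounds: tuple[float, float] = (-5.0, 5.0)
    breakdown_margin: float = 0.05
    seed: int = 0
    maxiter: int = 500


@dataclass(frozen=True)
class FitResult:
    subject_id: str
    theta_hat: float
    sigma_blur_hat: float
    sigma_m_hat: float
    k0_hat: float
    loglik: float
    converged: bool
    n_trials: int


def _condition_moments(
    feedback_label: str, params: CandidateParams, constants: DesignConstants
) -> tuple[float, float]:
    """(w, s2) for a feedback condition under candidate parameters."""
    if feedback_label == "FULL":
        sigma_o = constants.sigma_o_full
    elif feedback_label == "BLUR":
        sigma_o = params.sigma_blur
    elif feedback_label == "NONE":
        sigma_o = math.inf
    else:
        raise InvalidParameterError(f"unknown feedback label {feedback_label!r}")
    return _posterior_moments(constants.sigma_p, sigma_o)


def _check_breakdown(theta: float, Q: float, s2: float) -> None:
    if 1.0 + theta * Q * s2 <= 0.0:
        raise RiskBreakdownError(
            f"1 + theta*Q*s2 = {1.0 + theta * Q * s2:.6g} <= 0"
        )


def trial_loglik(
    trial, params: CandidateParams, constants: DesignConstants
) -> float:
    """Log density of one trial's response given its target.

    ``trial`` is any mapping with keys feedback_label, force_label,
    target_x, response_x (a TrialRecord dataclass also works).  The
    density is Normal(w*x + k, w*s2 + sigma_m**2) as derived in the
    module docstring; a zero-variance (degenerate) condition returns
    -inf unless the response matches the predicted mean exactly.
    """
    if dataclasses.is_dataclass(trial):
        trial = dataclasses.asdict(trial)
    w, s2 = _condition_moments(trial["feedback_label"], params, constants)
    _check_breakdown(params.theta, constants.Q, s2)
    c1 = constants.costs[trial["force_label"]].c1
    mean = w * float(trial["target_x"]) - c1 * (params.k0 + 0.5 * params.theta * s2)
    var = w * s2 + params.sigma_m**2
    r = float(trial["response_x"])
    if var == 0.0:
        return math.inf if r == mean else -math.inf
    return -0.5 * (_LOG2PI + math.log(var) + (r - mean) ** 2 / var)


def _group_trials(trials: pd.DataFrame) -> list[tuple[str, str, np.ndarray, np.ndarray]]:
    groups = []
    for (fb, force), g in trials.groupby(["feedback_label", "force_label"], sort=True):
        groups.append(
            (fb, force, g["target_x"].to_numpy(float), g["response_x"].to_numpy(float))
        )
    return groups


def table_loglik(
    trials: pd.DataFrame, params: CandidateParams, constants: DesignConstants
) -> float:
    """Summed log-likelihood of a trial table (vectorised per condition)."""
    total = 0.0
    for fb, force, x, r in _group_trials(trials):
        w, s2 = _condition_moments(fb, params, constants)
        _check_breakdown(params.theta, constants.Q, s2)
        c1 = constants.costs[force].c1
        mean = w * x - c1 * (params.k0 + 0.5 * params.theta * s2)
        var = w * s2 + params.sigma_m**2
        if var == 0.0:
            return math.inf if np.all(r == mean) else -math.inf
        total += float(
            -0.5 * np.sum(_LOG2PI + math.log(var) + (r - mean) ** 2 / var)
        )
    return total


def _moment_start(
    trials: pd.DataFrame, constants: DesignConstants, bounds: list[tuple[float, float]]
) -> np.ndarray:
    """Method-of-moments initial point (clipped into the bounds)."""
    theta0, sb0, sm0, k00 = 0.1, constants.sigma_p, 0.3, 0.0
    full = trials[trials["feedback_label"] == "FULL"]
    if len(full) >= 3:
        sm0 = float(np.std(full["response_x"] - full["target_x"])) or sm0
    blur = trials[trials["feedback_label"] == "BLUR"]
    if len(blur) >= 3 and np.var(blur["target_x"].to_numpy()) > 0:
        w0 = linregress(blur["target_x"], blur["response_x"]).slope
        w0 = float(np.clip(w0, 0.02, 0.98))
        sb0 = constants.sigma_p * math.sqrt((1.0 - w0) / w0)
    none = trials[trials["feedback_label"] == "NONE"]
    ests = []
    for force, g in none.groupby("force_label"):
        c1 = constants.costs[force].c1
        if c1 != 0.0 and len(g) >= 3:
            ests.append(-2.0 * float(g["response_x"].mean()) / (c1 * constants.sigma_p**2))
    if ests:
        theta0 = float(np.mean(ests))
    x0 = np.array([theta0, sb0, sm0, k00])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x0, lo, hi)


def fit_subject_mle(
    trials: pd.DataFrame,
    constants: DesignConstants,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximum-likelihood fit of (theta, sigma_blur, sigma_m, k0) for one
    subject's trials.

    Requires trials spanning at least two feedback conditions and at
    least one block with a nonzero cost slope (otherwise theta and k0 are
    not identifiable).  Deterministic given ``options.seed``.
    """
    ids = trials["subject_id"].unique()
    if len(ids) != 1:
        raise InvalidParameterError(f"expected one subject, got {sorted(ids)}")
    fbs = set(trials["feedback_label"].unique())
    if len(fbs) < 2:
        raise IdentifiabilityError(
            f"trials span only feedback condition(s) {sorted(fbs)}; "
            "need >= 2 to separate cue weight from bias"
        )
    c1s = {constants.costs[f].c1 for f in trials["force_label"].unique()}
    if all(c == 0.0 for c in c1s):
        raise IdentifiabilityError(
            "no block with nonzero cost slope: theta and k0 are not identifiable"
        )

    theta_lo = max(
        options.theta_bounds[0],
        (options.breakdown_margin - 1.0) / (constants.Q * constants.sigma_p**2),
    )
    bounds = [
        (theta_lo, options.theta_bounds[1]),
        options.sigma_blur_bounds,
        options.sigma_m_bounds,
        options.k0_bounds,
    ]
    groups = _group_trials(trials)

    def neg_ll(vec: np.ndarray) -> float:
        theta, sb, sm, k0 = vec
        total = 0.0
        for fb, force, x, r in groups:
            w, s2 = _condition_moments(
                fb, CandidateParams(theta, sb, sm, k0), constants
            )
            c1 = constants.costs[force].c1
            mean = w * x - c1 * (k0 + 0.5 * theta * s2)
            var = w * s2 + sm**2
            total += 0.5 * np.sum(_LOG2PI + math.log(var) + (r - mean) ** 2 / var)
        return total

    rng = np.random.default_rng(options.seed)
    starts = [_moment_start(trials, constants, bounds)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # random starts stay well inside the box to avoid flat boundary regions
    for _ in range(max(0, options.n_starts - 1)):
        u = rng.uniform(0.05, 0.95, size=4)
        starts.append(lo + u * (np.minimum(hi, np.array([2.0, 10.0, 3.0, 2.0])) - lo))

    best = None
    for x0 in starts:
        res = minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta, sb, sm, k0 = best.x
    return FitResult(
        subject_id=str(ids[0]),
        theta_hat=float(theta),
        sigma_blur_hat=float(sb),
        sigma_m_hat=float(sm),
        k0_hat=float(k0),
        loglik=float(-best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_trials=len(trials),
    )


_PARAM_NAMES = ("theta", "sigma_blur", "sigma_m", "k0")


def recover_parameters(
    subjects: Sequence[SubjectSpec],
    design_spec: DesignSpec,
    constants: DesignConstants,
    options: FitOptions = FitOptions(),
    n_replicates: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-then-fit validation loop.

    Repeatedly simulates the given cohort, fits every subject, and
    compares estimates with the generating truth.  Returns ``(report,
    estimates)``: the report has one row per parameter with mean truth,
    bias, RMSE and relative RMSE (NaN when the mean truth is 0); the
    estimates table has one row per replicate x subject x parameter and
    records per-replicate failures (converged=False, NaN estimate) rather
    than aborting.
    """
    if n_replicates < 2:
        raise InvalidParameterError(
            "n_replicates must be >= 2 to report dispersion"
        )
    truth = {
        s.subject_id: {
            "theta": s.params.theta,
            "sigma_blur": s.effective_sigma_o("BLUR"),
            "sigma_m": s.params.sigma_m,
            "k0": 1.0 / (2.0 * constants.Q),
        }
        for s in subjects
    }
    seeds = _spawn_seeds(seed, n_replicates)
    rows = []
    for rep in range(n_replicates):
        trials = simulate_cohort(
            subjects, design_spec, master_seed=seeds[rep],
            costs=constants.costs, sigma_o_full=constants.sigma_o_full,
        )
        for sid, sub_trials in trials.groupby("subject_id", sort=False):
            opts = dataclasses.replace(options, seed=(options.seed + 1000 * rep) % 2**31)
            try:
                fit = fit_subject_mle(sub_trials, constants, opts)
                est = {
                    "theta": fit.theta_hat,
                    "sigma_blur": fit.sigma_blur_hat,
                    "sigma_m": fit.sigma_m_hat,
                    "k0": fit.k0_hat,
                }
                converged = fit.converged
            except (RiskBreakdownError, IdentifiabilityError):  # per-replicate failure
                est = {p: np.nan for p in _PARAM_NAMES}
                converged = False
            for p in _PARAM_NAMES:
                rows.append(
                    {
                        "replicate": rep,
                        "subject_id": sid,
                        "parameter": p,
                        "truth": truth[sid][p],
                        "estimate": est[p],
                        "converged": converged,
                    }
                )
    estimates = pd.DataFrame(rows)
    report_rows = []
    for p in _PARAM_NAMES:
        sub = estimates[(estimates["parameter"] == p) & estimates["converged"]]
        err = sub["estimate"] - sub["truth"]
        truth_mean = float(estimates.loc[estimates["parameter"] == p, "truth"].mean())
        rmse = float(np.sqrt(np.mean(err**2))) if len(sub) else np.nan
        report_rows.append(
            {
                "parameter": p,
                "truth_mean": truth_mean,
                "bias": float(err.mean()) if len(sub) else np.nan,
                "rmse": rmse,
                "rel_rmse": rmse / abs(truth_mean) if truth_mean != 0.0 else np.nan,
                "n_fits": int(len(sub)),
                "n_failed": int(
                    (~estimates.loc[estimates["parameter"] == p, "converged"]).sum()
                ),
            }
        )
    return pd.DataFrame(report_rows), estimates
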