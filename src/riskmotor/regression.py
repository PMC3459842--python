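"""Per-condition regression of lateral deviation and repeated-measures ANOVA.

The analysis mirrors the study's: for every subject x force x feedback
cell, ordinary least squares of the lateral deviation d = target - response
on the true target position; the fitted slopes and intercepts then enter a
classical two-way repeated-measures ANOVA with force and uncertainty as
within-subject factors, each effect tested against its subject-by-effect
interaction mean square.  No sphericity correction is applied by default;
a Greenhouse-Geisser option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import f as f_dist
from scipy.stats import linregress

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    UnbalancedDesignError,
)
from .model import FEEDBACK_LABELS, FORCE_LABELS

__all__ = [
    "RegressionResult",
    "fit_condition_regression",
    "regression_table",
    "run_rm_anova",
    "summarize_cells",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS line of deviation on target for one subject x force x feedback."""

    subject_id: str
    force_label: str
    feedback_label: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_trials: int


def fit_condition_regression(trials: pd.DataFrame) -> RegressionResult:
    """OLS of d = target_x - response_x on target_x for one cell.

    Requires >= 3 trials with finite target and response and nonzero
    target variance (burn-in is assumed to have been applied already).
    """
    t = trials.dropna(subset=["target_x", "response_x"])
    n = len(t)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 trials for a regression, got {n}")
    for col in ("subject_id", "force_label", "feedback_label"):
        if t[col].nunique() != 1:
            raise DegenerateDesignError(
                f"fit_condition_regression expects a single {col}, "
                f"got {sorted(t[col].unique())}"
            )
    x = t["target_x"].to_numpy(dtype=float)
    d = x - t["response_x"].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise DegenerateDesignError("target position has zero variance")
    res = linregress(x, d)
    return RegressionResult(
        subject_id=t["subject_id"].iloc[0],
        force_label=t["force_label"].iloc[0],
        feedback_label=t["feedback_label"].iloc[0],
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n_trials=n,
    )


def regression_table(
    trials: pd.DataFrame, burn_in: int = 0, axis_flip: bool = False
) -> pd.DataFrame:
    """Fit every subject x force x feedback cell after burn-in filtering.

    ``axis_flip`` mirrors the lateral axis (x -> -x, r -> -r) before
    regressing, which negates intercepts and leaves slopes unchanged; the
    chosen convention is recorded in the table's ``attrs``.
    """
    t = trials[trials["trial_index"] > burn_in].copy()
    if axis_flip:
        for col in ("target_x", "observation_x", "response_x"):
            t[col] = -t[col]
    rows = []
    for _, cell in t.groupby(["subject_id", "force_label", "feedback_label"], sort=True):
        rows.append(fit_condition_regression(cell).__dict__)
    out = pd.DataFrame(rows)
    out.attrs["deviation"] = "target_x - response_x"
    out.attrs["axis_flip"] = axis_flip
    out.attrs["burn_in"] = burn_in
    return out


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject-by-contrast scores.

    ``scores`` has one row per subject and one column per orthonormal
    contrast of the effect; epsilon = tr(S)^2 / (d * tr(S @ S)) with S the
    covariance of the scores, clipped to [1/d, 1].
    """
    d = scores.shape[1]
    S = np.cov(scores, rowvar=False)
    S = np.atleast_2d(S)
    eps = np.trace(S) ** 2 / (d * np.trace(S @ S))
    return float(np.clip(eps, 1.0 / d, 1.0))


def run_rm_anova(
    results: pd.DataFrame,
    response_name: str,
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on per-cell slopes or intercepts.

    Parameters
    ----------
    results : DataFrame
        Regression table with one row per subject x force x feedback cell
        (complete and balanced; no imputation is attempted).
    response_name : {"slope", "intercept"}
        Which coefficient to analyse.
    gg_correction : bool
        If True, add Greenhouse-Geisser adjusted columns (eps, p_gg).

    Returns
    -------
    DataFrame with rows for the force and uncertainty main effects and
    their interaction; columns ss, df, ms, ss_error, df_error, ms_error,
    F, p.  ``attrs`` carries ss_total and ss_subject so that the full
    sum-of-squares decomposition is available.
    """
    if response_name not in ("slope", "intercept"):
        raise ValueError("response_name must be 'slope' or 'intercept'")
    pivot = results.pivot_table(
        index="subject_id",
        columns=["force_label", "feedback_label"],
        values=response_name,
        aggfunc="count",
    )
    full_cols = pd.MultiIndex.from_product([FORCE_LABELS, FEEDBACK_LABELS])
    if (
        pivot.shape[1] != 9
        or pivot.isna().any().any()
        or (pivot != 1).any().any()
        or not set(map(tuple, pivot.columns)) == set(map(tuple, full_cols))
    ):
        raise UnbalancedDesignError(
            "need exactly one value per subject for every force x feedback cell"
        )
    wide = results.pivot(
        index="subject_id", columns=["force_label", "feedback_label"],
        values=response_name,
    ).reindex(columns=full_cols)
    S = wide.shape[0]
    if S < 2:
        raise UnbalancedDesignError("repeated-measures ANOVA needs >= 2 subjects")
    y = wide.to_numpy(dtype=float).reshape(S, 3, 3)  # subject x force x feedback

    gm = y.mean()
    ys = y.mean(axis=(1, 2))
    ya = y.mean(axis=(0, 2))
    yb = y.mean(axis=(0, 1))
    yab = y.mean(axis=0)
    ysa = y.mean(axis=2)
    ysb = y.mean(axis=1)

    ss_s = 9.0 * np.sum((ys - gm) ** 2)
    ss_a = 3.0 * S * np.sum((ya - gm) ** 2)
    ss_b = 3.0 * S * np.sum((yb - gm) ** 2)
    ss_ab = S * np.sum((yab - ya[:, None] - yb[None, :] + gm) ** 2)
    ss_as = 3.0 * np.sum((ysa - ys[:, None] - ya[None, :] + gm) ** 2)
    ss_bs = 3.0 * np.sum((ysb - ys[:, None] - yb[None, :] + gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_abs = max(ss_tot - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs), 0.0)

    effects = {
        "force": (ss_a, 2, ss_as, 2 * (S - 1)),
        "uncertainty": (ss_b, 2, ss_bs, 2 * (S - 1)),
        "force:uncertainty": (ss_ab, 4, ss_abs, 4 * (S - 1)),
    }

    C = helmert(3, full=False)  # 2 x 3 orthonormal contrasts
    contrast_scores = {
        "force": ysa @ C.T,
        "uncertainty": ysb @ C.T,
        "force:uncertainty": y.reshape(S, 9) @ np.kron(C, C).T,
    }

    rows = []
    for name, (ss, df, ss_e, df_e) in effects.items():
        ms, ms_e = ss / df, ss_e / df_e
        if ss <= 0.0 or (ss_tot > 0 and ss / ss_tot < 1e-14):
            F, p = 0.0, 1.0
        elif ms_e == 0.0:
            F, p = np.inf, 0.0
        else:
            F = ms / ms_e
            p = float(f_dist.sf(F, df, df_e))
        row = {
            "effect": name, "ss": ss, "df": df, "ms": ms,
            "ss_error": ss_e, "df_error": df_e, "ms_error": ms_e,
            "F": F, "p": p,
        }
        if gg_correction:
            eps = _gg_epsilon(contrast_scores[name])
            row["eps"] = eps
            row["p_gg"] = (
                p if not np.isfinite(F) or F == 0.0
                else float(f_dist.sf(F, eps * df, eps * df_e))
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["response_name"] = response_name
    out.attrs["ss_total"] = float(ss_tot)
    out.attrs["ss_subject"] = float(ss_s)
    out.attrs["df_subject"] = S - 1
    out.attrs["n_subjects"] = S
    return out


def summarize_cells(results: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean and dispersion of slope/intercept per cell.

    Dispersion is the population s.d. (ddof=0), so a single-subject table
    reports zero spread rather than NaN.
    """
    if len(results) == 0:
        raise InsufficientDataError("empty regression table")

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "slope_mean": g["slope"].mean(),
                "slope_sd": g["slope"].std(ddof=0),
                "intercept_mean": g["intercept"].mean(),
                "intercept_sd": g["intercept"].std(ddof=0),
                "n_subjects": g["subject_id"].nunique(),
            }
        )

    out = (
        results.groupby(["force_label", "feedback_label"], sort=True)[
            ["slope", "intercept", "subject_id"]
        ]
        .apply(_agg)
        .reset_index()
    )
    out["n_subjects"] = out["n_subjects"].astype(int)
    return out
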