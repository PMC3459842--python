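import numpy as np
import pytest

import riskmotor as rm


@pytest.fixture(scope="session")
def default_cfg():
    return rm.default_config()


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    """The package's default 6-subject cohort at its default seed."""
    return rm.simulate_cohort(
        default_cfg.subjects,
        default_cfg.design,
        master_seed=default_cfg.seed,
        costs=default_cfg.costs,
    )


@pytest.fixture(scope="session")
def default_regression(default_cfg, default_cohort):
    return rm.regression_table(default_cohort, burn_in=default_cfg.design.burn_in)


@pytest.fixture()
def small_config_dict():
    """A small, fast pipeline configuration as a raw mapping."""
    return {
        "seed": 20240601,
        "output_dir": "out",
        "design": {"trials_per_block": 60, "feedback_weights": [2, 1, 1],
                   "block_order": ["F0", "FL", "FR"], "burn_in": 0},
        "model": {"sigma_p": 2.0, "Q": 10000.0, "halfwidth": 1.0,
                  "sigma_o_full": 0.0},
        "costs": {"c0": 2.0, "c1": 0.5},
        "subjects": [
            {"subject_id": "a", "theta": 0.6, "sigma_m": 0.3, "sigma_blur": 2.0},
            {"subject_id": "b", "theta": 0.9, "sigma_m": 0.25, "sigma_blur": 1.8},
            {"subject_id": "c", "theta": 0.7, "sigma_m": 0.35, "sigma_blur": 2.2},
        ],
        "analysis": {"axis_flip": False, "gg_correction": False},
        "fitting": {"n_starts": 3, "seed": 11},
    }


def balanced_cell_table(values):
    """Build a complete subject x force x feedback regression-style table
    from an array of shape (S, 3, 3) (force x feedback order as in
    riskmotor.model); slope and intercept both carry the values."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    rows = []
    for s in range(values.shape[0]):
        for i, force in enumerate(rm.model.FORCE_LABELS):
            for j, fb in enumerate(rm.model.FEEDBACK_LABELS):
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "force_label": force,
                        "feedback_label": fb,
                        "slope": values[s, i, j],
                        "intercept": values[s, i, j],
                        "slope_se": 0.0,
                        "intercept_se": 0.0,
                        "n_trials": 10,
                    }
                )
    return pd.DataFrame(rows)
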