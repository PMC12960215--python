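"""Shared fixtures.

The expensive objects - the 5,000-user study cohort, its feature matrix and
the per-horizon models - are session-scoped and shared between the unit and
acceptance tests so the whole suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bpdropout import (
    GeneratorConfig,
    build_daily_series,
    featurize_cohort,
    generate_cohort,
    label_cohort,
    split_cohorts,
)
from bpdropout.labeling import DailySeries
from bpdropout.training import horizon_sweep

STUDY_SEED = 7
STUDY_HORIZONS = (28, 56, 84)
SWEEP_TRAIN_USERS = 1200  # user-grouped subsample of the training cohort
SWEEP_TRIALS = 4


def make_series(
    days, cutoff, user_id="u", sbp=None, dbp=75.0, pulse=70.0
) -> DailySeries:
    """Build a DailySeries from measured day indices (one reading per day
    unless ``days`` contains repeats)."""
    days = list(days)
    uniq, counts = np.unique(np.asarray(days, dtype=np.int64), return_counts=True)
    if sbp is None:
        sbp = [120.0 + (d % 7) for d in days]
    readings = pd.DataFrame(
        {
            "day": np.asarray(days, dtype=np.int64),
            "sbp": np.asarray(sbp, dtype=float),
            "dbp": np.full(len(days), dbp, dtype=float),
            "pulse": np.full(len(days), pulse, dtype=float),
        }
    ).sort_values("day", kind="stable").reset_index(drop=True)
    return DailySeries(
        user_id=user_id, days=uniq, counts=counts, cutoff_day=cutoff, readings=readings
    )


@pytest.fixture()
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def study_cohort():
    cfg = GeneratorConfig(n_users=5000, seed=STUDY_SEED)
    users, meas, truth = generate_cohort(cfg)
    return cfg, users, meas, truth


@pytest.fixture(scope="session")
def study_series(study_cohort):
    _, _, meas, _ = study_cohort
    return build_daily_series(meas)


@pytest.fixture(scope="session")
def study_windows(study_series):
    return label_cohort(study_series, horizons=STUDY_HORIZONS)


@pytest.fixture(scope="session")
def study_features(study_cohort, study_series, study_windows):
    _, users, _, _ = study_cohort
    return featurize_cohort(study_series, study_windows, users)


@pytest.fixture(scope="session")
def study_split(study_cohort):
    _, users, _, _ = study_cohort
    return split_cohorts(users, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_sweep(study_features, study_windows, study_split):
    """Per-horizon GBT and logistic models, tuned with the desk-scale budget
    on a 1,200-user subsample of the training cohort."""
    rng = np.random.default_rng(STUDY_SEED)
    train_sub = set(
        rng.choice(
            np.asarray(study_split.train_user_ids),
            size=SWEEP_TRAIN_USERS,
            replace=False,
        )
    )
    sub_split = type(study_split)(
        train_user_ids=tuple(sorted(train_sub)),
        test1_user_ids=study_split.test1_user_ids,
        test2_user_ids=study_split.test2_user_ids,
        seed=study_split.seed,
    )
    return horizon_sweep(
        study_features,
        study_windows,
        sub_split,
        horizons=STUDY_HORIZONS,
        model_types=("gbt", "logistic"),
        budget_trials=SWEEP_TRIALS,
        seed=STUDY_SEED,
    )


@pytest.fixture(scope="session")
def study_eval_x56(study_features, study_windows, study_split):
    """Test-2 evaluation rows at the interpretation horizon X = 56."""
    from bpdropout.training import assemble_matrix

    mat = assemble_matrix(study_features, study_windows, 56)
    return mat[mat["user_id"].isin(set(study_split.test2_user_ids))].reset_index(
        drop=True
    )


@pytest.fixture(scope="session")
def study_attr_x56(study_sweep, study_eval_x56):
    """Attribution reports for both model families on the X=56 Test-2 rows."""
    from bpdropout import compute_attributions
    from bpdropout.features import FEATURE_NAMES

    return {
        mt: compute_attributions(
            study_sweep.models[(56, mt)], study_eval_x56[FEATURE_NAMES]
        )
        for mt in ("gbt", "logistic")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-user cohort for invariant suites that do not need the full one."""
    cfg = GeneratorConfig(n_users=2000, seed=11, calendar_span_days=260)
    users, meas, truth = generate_cohort(cfg)
    return cfg, users, meas, truth
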