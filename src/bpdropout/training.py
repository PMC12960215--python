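"""Dropout classifiers per prediction horizon.

Two model families are trained on the per-window feature matrix to predict
the inactive state X days after the window end:

* ``gbt`` - a LightGBM gradient-boosted tree ensemble (handles NaN-coded
  missing values natively);
* ``logistic`` - L2-regularised logistic regression behind median imputation
  and standardisation.

Evaluation is leakage-safe throughout: users are split (never windows), the
fivefold cross-validation used for hyperparameter search is grouped by user,
and the held-out cohorts mirror the two-regime validation design - Test 1 is
every regime-A user, Test 2 an equally sized random sample of regime-B users,
with the remaining regime-B users forming the training set.

Hyperparameters are tuned by maximising mean CV AUC over a fixed documented
search space with a seeded log-uniform random sampler.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import CV_FOLDS, HORIZON_GRID, ConfigError, DataError
from .features import FEATURE_NAMES

MODEL_TYPES = ("gbt", "logistic")


class UndefinedAUC(ValueError):
    """AUC requested on single-class labels."""


@dataclass(frozen=True)
class SplitPlan:
    """User-level train / Test-1 / Test-2 assignment."""

    train_user_ids: tuple[str, ...]
    test1_user_ids: tuple[str, ...]
    test2_user_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        a, b, c = (
            set(self.train_user_ids),
            set(self.test1_user_ids),
            set(self.test2_user_ids),
        )
        if a & b or a & c or b & c:
            raise ValueError("split sets must be pairwise disjoint")
        if len(self.test1_user_ids) != len(self.test2_user_ids):
            raise ValueError("|test2| must equal |test1|")


def split_cohorts(users: pd.DataFrame, seed: int) -> SplitPlan:
    """All regime-A users -> Test 1; an equal-size seeded random sample of
    regime-B users -> Test 2; remaining regime-B users -> train."""
    a_users = users.loc[users["regime"] == "A", "user_id"].astype(str).tolist()
    b_users = users.loc[users["regime"] == "B", "user_id"].astype(str).tolist()
    if not a_users or not b_users:
        raise DataError("both regimes must be present to build the split")
    if len(b_users) < len(a_users):
        raise DataError(
            f"cannot match sizes: {len(b_users)} regime-B < {len(a_users)} regime-A"
        )
    rng = np.random.default_rng(seed)
    b_sorted = sorted(b_users)
    test2 = sorted(rng.choice(b_sorted, size=len(a_users), replace=False).tolist())
    train = sorted(set(b_sorted) - set(test2))
    return SplitPlan(tuple(train), tuple(sorted(a_users)), tuple(test2), seed)


# ---------------------------------------------------------------------------
# AUC


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC via the rank statistic with tie averaging (equals trapezoidal
    integration of the ROC curve)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUC("labels contain a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalResult:
    auc: float
    n: int
    roc_points: np.ndarray = field(repr=False)  # columns FPR, TPR


def _scores(model, X: pd.DataFrame) -> np.ndarray:
    if isinstance(model, Pipeline):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def evaluate_auc(model, features: pd.DataFrame, labels: np.ndarray) -> EvalResult:
    """Held-out AUC plus exported ROC points for one fitted model."""
    scores = _scores(model, features)
    auc = rank_auc(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    return EvalResult(auc=auc, n=len(labels), roc_points=np.column_stack([fpr, tpr]))


# ---------------------------------------------------------------------------
# grouped CV and tuning


def group_folds(
    groups: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded user-grouped folds: shuffle unique users, deal them round-robin."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    fold_of = {u: i % n_folds for i, u in enumerate(perm)}
    assign = np.array([fold_of[g] for g in groups])
    folds = []
    for k in range(n_folds):
        val = np.nonzero(assign == k)[0]
        train = np.nonzero(assign != k)[0]
        folds.append((train, val))
    return folds


def _sample_gbt_params(rng: np.random.Generator) -> dict[str, Any]:
    return {
        "num_leaves": int(np.exp(rng.uniform(np.log(15), np.log(255)))),
        "learning_rate": float(np.exp(rng.uniform(np.log(0.01), np.log(0.3)))),
        "min_child_samples": int(rng.integers(5, 101)),
        "feature_fraction": float(rng.uniform(0.5, 1.0)),
        "bagging_fraction": float(rng.uniform(0.5, 1.0)),
        "bagging_freq": 1,
    }


def _gbt(params: dict[str, Any], n_estimators: int, seed: int) -> lgb.LGBMClassifier:
    return lgb.LGBMClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        force_row_wise=True,
        **params,
    )


def _logistic(c: float) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=c, max_iter=2000, solver="lbfgs")),
        ]
    )


@dataclass
class TrainedModel:
    model_type: str
    model: Any
    best_params: dict[str, Any]
    cv_auc_mean: float
    cv_auc_sd: float
    trials: list[dict[str, Any]]
    n_train: int


def tune_and_train(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    model_type: str,
    n_folds: int = CV_FOLDS,
    budget_trials: int = 50,
    seed: int = 0,
) -> TrainedModel:
    """Seeded random search over the documented space, scored by mean
    user-grouped CV AUC; the returned model is refit on all rows with the
    best configuration.

    GBT trials run up to 1000 trees with early stopping (30 rounds) on the
    fold validation AUC; the refit uses the mean stopped iteration.
    """
    if budget_trials < 1:
        raise ConfigError("budget_trials must be >= 1")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DataError("training labels contain a single class")
    if model_type not in MODEL_TYPES:
        raise ConfigError(f"unknown model type {model_type!r}")

    folds = group_folds(np.asarray(groups), n_folds, seed)
    rng = np.random.default_rng(seed)
    trials: list[dict[str, Any]] = []
    best: dict[str, Any] | None = None

    for t in range(budget_trials):
        if model_type == "gbt":
            params = _sample_gbt_params(rng)
            fold_aucs, best_iters = [], []
            for tr, va in folds:
                clf = _gbt(params, n_estimators=1000, seed=seed)
                clf.fit(
                    features.iloc[tr],
                    labels[tr],
                    eval_set=[(features.iloc[va], labels[va])],
                    eval_metric="auc",
                    callbacks=[lgb.early_stopping(30, verbose=False)],
                )
                fold_aucs.append(
                    rank_auc(labels[va], clf.predict_proba(features.iloc[va])[:, 1])
                )
                best_iters.append(clf.best_iteration_ or 1000)
            record = {
                "trial": t,
                "params": {**params, "n_estimators": int(np.mean(best_iters))},
                "cv_auc_mean": float(np.mean(fold_aucs)),
                "cv_auc_sd": float(np.std(fold_aucs, ddof=1)),
            }
        else:
            c = float(np.exp(rng.uniform(np.log(1e-4), np.log(1e2))))
            fold_aucs = []
            for tr, va in folds:
                clf = _logistic(c)
                clf.fit(features.iloc[tr], labels[tr])
                fold_aucs.append(
                    rank_auc(labels[va], clf.decision_function(features.iloc[va]))
                )
            record = {
                "trial": t,
                "params": {"C": c},
                "cv_auc_mean": float(np.mean(fold_aucs)),
                "cv_auc_sd": float(np.std(fold_aucs, ddof=1)),
            }
        trials.append(record)
        if best is None or record["cv_auc_mean"] > best["cv_auc_mean"]:
            best = record

    assert best is not None
    if model_type == "gbt":
        params = dict(best["params"])
        n_est = max(int(params.pop("n_estimators")), 10)
        final = _gbt(params, n_estimators=n_est, seed=seed)
        final.fit(features, labels)
    else:
        final = _logistic(best["params"]["C"])
        final.fit(features, labels)
    return TrainedModel(
        model_type=model_type,
        model=final,
        best_params=best["params"],
        cv_auc_mean=best["cv_auc_mean"],
        cv_auc_sd=best["cv_auc_sd"],
        trials=trials,
        n_train=len(labels),
    )


# ---------------------------------------------------------------------------
# dataset assembly and the horizon sweep


def assemble_matrix(
    features: pd.DataFrame, windows: pd.DataFrame, X: int
) -> pd.DataFrame:
    """Join features with the horizon-X label, keeping rows where the label
    is defined.  Returns user_id, start_day, label, and feature columns."""
    if X not in HORIZON_GRID:
        raise ConfigError(f"horizon {X} off the grid")
    merged = features.merge(
        windows[["user_id", "start_day", f"y_{X}", f"defined_{X}"]],
        on=["user_id", "start_day"],
        validate="one_to_one",
    )
    merged = merged[merged[f"defined_{X}"]].copy()
    merged["label"] = merged[f"y_{X}"].astype(int)
    return merged.drop(columns=[f"y_{X}", f"defined_{X}"])


@dataclass
class ModelReport:
    """Per (horizon, model family) training and evaluation record."""

    entries: dict[tuple[int, str], dict[str, Any]] = field(default_factory=dict)
    models: dict[tuple[int, str], Any] = field(default_factory=dict, repr=False)

    def to_jsonable(self) -> dict[str, Any]:
        out = {}
        for (X, mt), e in self.entries.items():
            rec = {k: v for k, v in e.items() if k != "roc_test2"}
            out[f"{mt}_{X}"] = rec
        return out


def horizon_sweep(
    features: pd.DataFrame,
    windows: pd.DataFrame,
    split: SplitPlan,
    horizons: tuple[int, ...] = HORIZON_GRID,
    model_types: tuple[str, ...] = MODEL_TYPES,
    n_folds: int = CV_FOLDS,
    budget_trials: int = 50,
    seed: int = 0,
) -> ModelReport:
    """Independent model per (horizon, family): tune on the training users,
    evaluate on Test 1 and Test 2.  Rows with undefined labels at a horizon
    are excluded for that horizon only."""
    if not horizons:
        raise ConfigError("empty horizon grid")
    train_set = set(split.train_user_ids)
    t1_set = set(split.test1_user_ids)
    t2_set = set(split.test2_user_ids)
    report = ModelReport()
    for X in horizons:
        mat = assemble_matrix(features, windows, X)
        tr = mat[mat["user_id"].isin(train_set)]
        t1 = mat[mat["user_id"].isin(t1_set)]
        t2 = mat[mat["user_id"].isin(t2_set)]
        for mt in model_types:
            fitted = tune_and_train(
                tr[FEATURE_NAMES],
                tr["label"].to_numpy(),
                tr["user_id"].to_numpy(),
                mt,
                n_folds=n_folds,
                budget_trials=budget_trials,
                seed=seed,
            )
            e1 = evaluate_auc(fitted.model, t1[FEATURE_NAMES], t1["label"].to_numpy())
            e2 = evaluate_auc(fitted.model, t2[FEATURE_NAMES], t2["label"].to_numpy())
            report.entries[(X, mt)] = {
                "horizon": X,
                "model_type": mt,
                "cv_auc_mean": fitted.cv_auc_mean,
                "cv_auc_sd": fitted.cv_auc_sd,
                "auc_test1": e1.auc,
                "auc_test2": e2.auc,
                "n_train": fitted.n_train,
                "n_test1": e1.n,
                "n_test2": e2.n,
                "best_params": fitted.best_params,
                "roc_test2": e2.roc_points,
            }
            report.models[(X, mt)] = fitted.model
    return report
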