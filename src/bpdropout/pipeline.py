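"""End-to-end runner: simulate -> label -> featurize -> train -> explain ->
describe.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-executed in isolation and deterministic
stages reproduce their files byte-identically.  A ``manifest.json`` records
the configuration hash, seeds, per-stage row counts and output paths.

Tabular interchange: Parquet for intermediates (windows, features,
attributions), CSV for human-facing outputs.
"""

from __future__ import annotations

import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import descriptive as desc_mod
from .config import DataError, PipelineConfig
from .features import FEATURE_NAMES, featurize_cohort
from .labeling import (
    build_daily_series,
    day_index,
    detect_gaps,
    label_cohort,
    read_windows,
    write_windows,
)
from .simulate import export_truth, generate_cohort
from .training import assemble_matrix, horizon_sweep, split_cohorts

logger = logging.getLogger(__name__)

STAGES = ("simulate", "label", "featurize", "train", "explain", "describe")

MEASUREMENT_COLUMNS = ["user_id", "date", "sbp", "dbp", "pulse"]
USER_COLUMNS = ["user_id", "birth_ym", "sex", "regime"]


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read per-reading records; rows with unparseable dates or non-positive
    vitals are rejected and logged with their line numbers."""
    df = pd.read_csv(path, dtype={"user_id": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"measurements file missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    vitals = df[["sbp", "dbp", "pulse"]].apply(pd.to_numeric, errors="coerce")
    ok = dates.notna() & (vitals > 0).all(axis=1)
    if (~ok).any():
        # +2: header line plus 1-based numbering
        lines = (df.index[~ok] + 2).tolist()
        logger.warning(
            "rejected %d malformed measurement rows (lines %s)",
            len(lines),
            lines[:20],
        )
    out = df.loc[ok, MEASUREMENT_COLUMNS].copy()
    out["date"] = dates[ok].dt.strftime("%Y-%m-%d")
    out[["sbp", "dbp", "pulse"]] = vitals[ok]
    return out.reset_index(drop=True)


def read_users(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(USER_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"users file missing columns: {sorted(missing)}")
    return df[USER_COLUMNS]


def _series_from_files(out: Path):
    meas = read_measurements(out / "measurements.csv")
    if meas.empty:
        raise DataError("no valid measurement rows")
    return build_daily_series(meas)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    stages: tuple[str, ...] | None = None,
) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stages = STAGES if stages is None else tuple(stages)
    for s in stages:
        if s not in STAGES:
            raise DataError(f"unknown stage {s!r}")

    manifest_path = out / "manifest.json"
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seeds": {
            "generator": config.generator.seed,
            "training": config.training.seed,
        },
        "stages": {},
        "outputs": {},
    }
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
            manifest["stages"].update(prev.get("stages", {}))
            manifest["outputs"].update(prev.get("outputs", {}))
        except json.JSONDecodeError:
            pass

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        for f in files:
            if not f.exists() or f.stat().st_size == 0:
                raise DataError(f"stage {stage} declared missing/empty output {f}")
        manifest["stages"][stage] = counts
        manifest["outputs"][stage] = sorted(str(f.relative_to(out)) for f in files)
        logger.info("stage %s done: %s", stage, counts)

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            if stage == "simulate":
                users, meas, truth = generate_cohort(config.generator)
                users.to_csv(out / "users.csv", index=False)
                meas.to_csv(out / "measurements.csv", index=False)
                export_truth(truth, out / "truth.csv")
                record(
                    stage,
                    {"users": len(users), "measurements": len(meas)},
                    [out / "users.csv", out / "measurements.csv", out / "truth.csv"],
                )
            elif stage == "label":
                series = _series_from_files(out)
                windows = label_cohort(
                    series,
                    horizons=config.labeling.horizons,
                    keep_empty_windows=config.labeling.keep_empty_windows,
                )
                write_windows(windows, out / "windows.parquet")
                record(stage, {"windows": len(windows)}, [out / "windows.parquet"])
            elif stage == "featurize":
                series = _series_from_files(out)
                windows = read_windows(out / "windows.parquet")
                users = read_users(out / "users.csv")
                feats = featurize_cohort(series, windows, users)
                feats.to_parquet(out / "features.parquet", index=False)
                record(stage, {"rows": len(feats)}, [out / "features.parquet"])
            elif stage == "train":
                users = read_users(out / "users.csv")
                windows = read_windows(out / "windows.parquet")
                feats = pd.read_parquet(out / "features.parquet")
                split = split_cohorts(users, config.training.seed)
                report = horizon_sweep(
                    feats,
                    windows,
                    split,
                    horizons=config.training.horizons,
                    model_types=config.training.model_types,
                    n_folds=config.training.n_folds,
                    budget_trials=config.training.budget_trials,
                    seed=config.training.seed,
                )
                files = []
                (out / "models").mkdir(exist_ok=True)
                for (X, mt), entry in report.entries.items():
                    roc = pd.DataFrame(entry["roc_test2"], columns=["fpr", "tpr"])
                    roc_path = out / f"roc_{mt}_{X}.csv"
                    roc.to_csv(roc_path, index=False)
                    files.append(roc_path)
                    model_path = out / "models" / f"{mt}_{X}.pkl"
                    with open(model_path, "wb") as fh:
                        pickle.dump(report.models[(X, mt)], fh)
                rep_path = out / "model_report.json"
                rep_path.write_text(
                    json.dumps(report.to_jsonable(), indent=2, sort_keys=True)
                )
                split_path = out / "split.json"
                split_path.write_text(
                    json.dumps(
                        {
                            "train": list(split.train_user_ids),
                            "test1": list(split.test1_user_ids),
                            "test2": list(split.test2_user_ids),
                            "seed": split.seed,
                        },
                        indent=0,
                    )
                )
                record(
                    stage,
                    {"models": len(report.entries)},
                    files + [rep_path, split_path],
                )
            elif stage == "explain":
                X = config.explain_horizon
                with open(out / "models" / f"gbt_{X}.pkl", "rb") as fh:
                    model = pickle.load(fh)
                windows = read_windows(out / "windows.parquet")
                feats = pd.read_parquet(out / "features.parquet")
                split = json.loads((out / "split.json").read_text())
                mat = assemble_matrix(feats, windows, X)
                mat = mat[mat["user_id"].isin(set(split["test2"]))]
                report = attr_mod.compute_attributions(model, mat[FEATURE_NAMES])
                report.values.to_parquet(out / "shap_matrix.parquet", index=False)
                ranking = attr_mod.rank_features(report)
                pd.DataFrame(
                    {
                        "rank": np.arange(1, len(ranking) + 1),
                        "feature": ranking,
                        "mean_abs_attribution": [
                            float(report.values[f].abs().mean()) for f in ranking
                        ],
                    }
                ).to_csv(out / "ranking.csv", index=False)
                files = [out / "shap_matrix.parquet", out / "ranking.csv"]
                for feature in ("sbp_max", "age_years"):
                    prof = attr_mod.dependence_profile(report, feature, n_bins=20)
                    pd.DataFrame(
                        {
                            "bin_left": prof.edges[:-1],
                            "bin_right": prof.edges[1:],
                            "mean_attribution": prof.bin_mean,
                            "count": prof.bin_count,
                        }
                    ).to_csv(out / f"dependence_{feature}.csv", index=False)
                    files.append(out / f"dependence_{feature}.csv")
                record(stage, {"rows": len(report.values)}, files)
            elif stage == "describe":
                series = _series_from_files(out)
                users = read_users(out / "users.csv")
                gaps = [g for s in series.values() for g in detect_gaps(s)]
                desc_mod.non_resumption_curve(gaps).to_csv(
                    out / "fig1c.csv", index=False
                )
                desc_mod.dropout_rate_by_age(users, series).to_csv(
                    out / "fig5a.csv", index=False
                )
                events = desc_mod.dropout_event_table(series)
                sex_of = users.set_index("user_id")["sex"]
                curves = desc_mod.cumulative_incidence(
                    events["time"].to_numpy(),
                    events["event"].to_numpy(),
                    sex_of.loc[events["user_id"]].to_numpy(),
                )
                files = [out / "fig1c.csv", out / "fig5a.csv"]
                for lab, curve in curves.items():
                    p = out / f"fig5b_{lab}.csv"
                    pd.DataFrame(
                        {"time": curve.times, "cumulative_incidence": curve.values}
                    ).to_csv(p, index=False)
                    files.append(p)
                # regime comparison, standardized by age decade x sex
                origin_ages = _ages_at_first(users, series)
                ev = events.merge(users, on="user_id").merge(
                    origin_ages, on="user_id"
                )
                a = ev[ev["regime"] == "A"]
                b = ev[ev["regime"] == "B"]
                if not a.empty and not b.empty:
                    ca, cb = desc_mod.standardized_incidence_comparison(
                        a[["time", "event", "age_years", "sex"]],
                        b[["time", "event", "age_years", "sex"]],
                        time_grid=np.arange(0, 181, 5, dtype=float),
                    )
                    pd.DataFrame(
                        {
                            "time": ca.times,
                            "adjusted_incidence_A": ca.values,
                            "adjusted_incidence_B": cb.values,
                        }
                    ).to_csv(out / "fig5c.csv", index=False)
                    files.append(out / "fig5c.csv")
                desc_mod.monthly_dropout_rate(series).to_csv(
                    out / "fig5d.csv", index=False
                )
                files.append(out / "fig5d.csv")
                # week-delta comparison at the explain horizon
                windows = read_windows(out / "windows.parquet")
                feats = pd.read_parquet(out / "features.parquet")
                mat = assemble_matrix(feats, windows, config.explain_horizon)
                tests = [
                    desc_mod.compare_week_delta_by_outcome(
                        mat, mat["label"].to_numpy(), scope
                    )
                    for scope in ("all", "weekday", "weekend")
                ]
                pd.DataFrame([t.__dict__ for t in tests]).to_csv(
                    out / "week_delta_tests.csv", index=False
                )
                files.append(out / "week_delta_tests.csv")
                record(stage, {"gap_episodes": len(gaps)}, files)
    except Exception:
        logger.exception("pipeline aborted during stage %r", stage)
        manifest["aborted_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _ages_at_first(users: pd.DataFrame, series_map) -> pd.DataFrame:
    from .config import CALENDAR_ORIGIN

    origin = pd.Timestamp(CALENDAR_ORIGIN)
    rows = []
    prof = users.set_index("user_id")["birth_ym"].to_dict()
    for uid, s in series_map.items():
        if not s.days.size:
            continue
        d = origin + pd.Timedelta(days=s.first_day)
        by, bm = (int(p) for p in str(prof[uid]).split("-"))
        rows.append({"user_id": uid, "age_years": d.year - by - (d.month < bm)})
    return pd.DataFrame(rows)


__all__ = [
    "STAGES",
    "read_measurements",
    "read_users",
    "run_pipeline",
    "day_index",
]
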