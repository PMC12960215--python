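"""Additive per-prediction feature attributions and their summaries.

For the gradient-boosted models, attributions are exact path-dependent tree
attributions in log-odds units, computed by the ensemble itself
(``pred_contrib``); for the logistic model they are the closed-form linear
attributions ``w_j * (z_j - mean z_j)`` on the imputed, standardised inputs.
In both cases local accuracy holds: per row, base value plus the attribution
sum equals the model margin.

Summaries mirror the standard interpretation workflow: a global ranking by
mean absolute attribution, binned dependence profiles of attribution against
feature value, and a U-shape detector that compares mean attribution in the
two extreme bands of a numeric feature against a middle band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from .config import ConfigError
from .features import FEATURE_NAMES


class UndefinedProfile(ValueError):
    """A requested band or profile has no supporting data."""


@dataclass
class ShapReport:
    """Attribution matrix plus the inputs needed for dependence profiles."""

    values: pd.DataFrame = field(repr=False)  # rows x features, log-odds units
    base_value: float
    margins: np.ndarray = field(repr=False)
    feature_values: pd.DataFrame = field(repr=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def compute_attributions(model, features: pd.DataFrame) -> ShapReport:
    """Per-row additive attributions for a fitted model from model_training.

    ``base_value + sum(attributions) == margin`` holds row-wise to numerical
    precision; deterministic.
    """
    names = list(features.columns)
    if isinstance(model, Pipeline):
        clf = model.named_steps["clf"]
        if len(names) != model.named_steps["impute"].n_features_in_:
            raise ConfigError("feature schema mismatch with fitted pipeline")
        z = model.named_steps["scale"].transform(
            model.named_steps["impute"].transform(features)
        )
        w = clf.coef_.ravel()
        margins = clf.intercept_[0] + z @ w
        z_mean = z.mean(axis=0)
        base = float(clf.intercept_[0] + z_mean @ w)
        values = (z - z_mean) * w
    else:
        booster_names = model.booster_.feature_name()
        expected = [c.replace(" ", "_") for c in names]
        if booster_names != expected:
            raise ConfigError("feature schema mismatch with fitted booster")
        contrib = model.predict(features, pred_contrib=True)
        values = contrib[:, :-1]
        base = float(contrib[0, -1])
        margins = contrib.sum(axis=1)
    return ShapReport(
        values=pd.DataFrame(values, columns=names),
        base_value=base,
        margins=np.asarray(margins, dtype=float),
        feature_values=features.reset_index(drop=True),
    )


def rank_features(report: ShapReport, top_k: int | None = None) -> list[str]:
    """Features in descending mean |attribution|; ties broken by catalogue
    order."""
    if top_k is not None and top_k < 1:
        raise ConfigError("top_k must be >= 1")
    means = report.values.abs().mean(axis=0)
    order_key = {n: i for i, n in enumerate(FEATURE_NAMES)}
    ranked = sorted(
        report.feature_names,
        key=lambda n: (-means[n], order_key.get(n, len(order_key))),
    )
    return ranked if top_k is None else ranked[:top_k]


@dataclass
class DependenceProfile:
    feature: str
    edges: np.ndarray  # len n_bins + 1, strictly increasing
    bin_mean: np.ndarray  # mean attribution per bin
    bin_count: np.ndarray
    color_by: str | None = None
    color_mean: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def dependence_profile(
    report: ShapReport,
    feature: str,
    n_bins: int = 20,
    color_by: str | None = None,
    bin_edges: np.ndarray | None = None,
) -> DependenceProfile:
    """Binned mean attribution against feature value.

    Equal-count (quantile) bins by default; pass ``bin_edges`` for explicit
    value bands.  Rows with a missing feature value are dropped; an
    all-missing feature raises :class:`UndefinedProfile`.
    """
    if feature not in report.feature_names:
        raise ConfigError(f"{feature!r} not in the feature catalogue")
    x = report.feature_values[feature].to_numpy(dtype=float)
    attr = report.values[feature].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    if not ok.any():
        raise UndefinedProfile(f"feature {feature!r} is missing on every row")
    x, attr = x[ok], attr[ok]
    if bin_edges is None:
        qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        if edges.size < 2:
            edges = np.array([x.min() - 0.5, x.max() + 0.5])
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ConfigError("bin_edges must be strictly increasing")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    nb = edges.size - 1
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=attr, minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    color_mean = None
    if color_by is not None:
        c = report.feature_values[color_by].to_numpy(dtype=float)[ok]
        csums = np.bincount(idx, weights=np.nan_to_num(c), minlength=nb)
        cvalid = np.bincount(idx, weights=(~np.isnan(c)).astype(float), minlength=nb)
        color_mean = np.where(cvalid > 0, csums / np.maximum(cvalid, 1), np.nan)
    return DependenceProfile(
        feature=feature,
        edges=edges,
        bin_mean=means,
        bin_count=counts,
        color_by=color_by,
        color_mean=color_mean,
    )


@dataclass(frozen=True)
class UShapeResult:
    is_ushape: bool
    low_margin: float  # mean attr below low_edge minus mid-band mean
    high_margin: float  # mean attr above high_edge minus mid-band mean


def detect_ushape(
    profile: DependenceProfile,
    low_edge: float,
    mid_band: tuple[float, float],
    high_edge: float,
    margin: float = 0.0,
) -> UShapeResult:
    """U-shape test on a dependence profile.

    True iff the count-weighted mean attribution of bins centred below
    ``low_edge`` AND of bins centred above ``high_edge`` both exceed the
    mid-band mean by more than ``margin``.  Raises
    :class:`UndefinedProfile` when any band holds no data.
    """
    centers = profile.centers
    ok = profile.bin_count > 0

    def band_mean(mask: np.ndarray) -> float:
        mask = mask & ok
        if not mask.any():
            raise UndefinedProfile("empty band in U-shape test")
        w = profile.bin_count[mask]
        return float(np.average(profile.bin_mean[mask], weights=w))

    low = band_mean(centers < low_edge)
    mid = band_mean((centers >= mid_band[0]) & (centers <= mid_band[1]))
    high = band_mean(centers > high_edge)
    return UShapeResult(
        is_ushape=(low - mid > margin) and (high - mid > margin),
        low_margin=low - mid,
        high_margin=high - mid,
    )
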