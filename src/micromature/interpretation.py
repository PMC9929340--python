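"""Model interpretation: scaled feature importance and accumulated local effects.

Accumulated local effects (ALE) summarize how a fitted model's prediction
changes across the distribution of one feature, free of the extrapolation
bias of partial-dependence plots.  The feature axis is cut into
equal-count (quantile) intervals; within each interval the local effect is
the prediction difference when every sample in the interval has the feature
set to the interval's upper versus lower bound; local effects are
accumulated cumulatively and centered about the sample-weighted average
effect.  Each increment also carries a 95% confidence interval,
mean ± 1.96·sd/√n, where sd is the standard deviation of the per-sample
prediction changes in that interval and n its sample count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ALEResult", "ImportanceRanking", "scaled_importance", "ale", "plot_ale"]


@dataclass
class ImportanceRanking:
    """Features ordered by importance, scaled so the top feature is 1."""

    table: pd.DataFrame  # columns: feature, importance, scaled_importance, rank


def scaled_importance(model, top_k: int = 20) -> pd.DataFrame:
    """Top-``top_k`` features by importance, scaled relative to the first.

    ``model`` is a :class:`micromature.maturity.SelectedModel` or a fitted
    XGBoost sklearn estimator.  Returns an empty frame (with a warning) for
    an ensemble with no splits.
    """
    booster = getattr(model, "model", model)
    if hasattr(booster, "get_booster"):
        booster = booster.get_booster()
    raw = booster.get_score(importance_type="gain")
    cols = ["feature", "importance", "scaled_importance", "rank"]
    if not raw:
        warnings.warn("model has no splits; empty importance ranking")
        return pd.DataFrame(columns=cols)
    ser = pd.Series(raw, dtype=float).sort_values(ascending=False).head(top_k)
    out = pd.DataFrame(
        {
            "feature": ser.index,
            "importance": ser.to_numpy(),
            "scaled_importance": ser.to_numpy() / ser.iloc[0],
            "rank": np.arange(1, len(ser) + 1),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class ALEResult:
    """Centered ALE curve for one feature.

    ``grid`` holds the K+1 interval breakpoints (feature values at
    percentile cuts); ``effect`` the centered accumulated effect at each
    breakpoint (outcome units, right-edge convention).  The per-increment
    arrays (length K) carry the mean local change, its 95% CI and the
    interval sample count.
    """

    feature_id: str
    grid: np.ndarray
    effect: np.ndarray
    delta_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_increment: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = len(self.grid) - 1
        return pd.DataFrame(
            {
                "feature": self.feature_id,
                "breakpoint_value": self.grid,
                "effect": self.effect,
                "delta_mean": np.concatenate([[np.nan], self.delta_mean]),
                "ci_low": np.concatenate([[np.nan], self.ci_low]),
                "ci_high": np.concatenate([[np.nan], self.ci_high]),
                "n": np.concatenate([[0], self.n_per_increment]).astype(int),
            }
        )


def _predict_fn(model):
    if hasattr(model, "predict") and hasattr(model, "retained_features"):
        return lambda X: model.model.predict(X[model.retained_features])
    if hasattr(model, "predict"):
        return model.predict
    return model  # plain callable


def ale(model, data: pd.DataFrame, feature_id: str, n_intervals: int = 10) -> ALEResult:
    """Accumulated local effects of ``feature_id`` on the model prediction.

    Intervals are quantile-based (equal sample counts); tied breakpoints —
    ubiquitous at zero abundance in microbiome tables — are merged into a
    single interval.  A constant feature yields an all-zero effect with a
    warning.
    """
    if feature_id not in data.columns:
        raise KeyError(f"feature {feature_id!r} not in data")
    predict = _predict_fn(model)
    x = data[feature_id].to_numpy(dtype=float)
    quantiles = np.quantile(x, np.linspace(0, 1, n_intervals + 1))
    grid = np.unique(quantiles)
    if len(grid) < 2:
        warnings.warn(f"feature {feature_id!r} is constant; zero ALE")
        return ALEResult(
            feature_id=str(feature_id),
            grid=np.array([grid[0], grid[0]]),
            effect=np.zeros(2),
            delta_mean=np.zeros(1),
            ci_low=np.zeros(1),
            ci_high=np.zeros(1),
            n_per_increment=np.array([len(x)]),
        )
    k = len(grid) - 1
    # Interval index per sample: interval j covers (grid[j], grid[j+1]],
    # with the lowest values assigned to interval 0.
    idx = np.clip(np.searchsorted(grid, x, side="left") - 1, 0, k - 1)

    delta_mean = np.zeros(k)
    delta_sd = np.zeros(k)
    n_per = np.zeros(k, dtype=int)
    for j in range(k):
        members = np.flatnonzero(idx == j)
        n_per[j] = len(members)
        if len(members) == 0:
            continue
        lo = data.iloc[members].copy()
        hi = lo.copy()
        lo[feature_id] = grid[j]
        hi[feature_id] = grid[j + 1]
        change = np.asarray(predict(hi), dtype=float) - np.asarray(predict(lo), dtype=float)
        delta_mean[j] = change.mean()
        delta_sd[j] = change.std(ddof=1) if len(change) > 1 else 0.0

    accumulated = np.concatenate([[0.0], np.cumsum(delta_mean)])
    # Center about the sample-weighted average effect, interpolating the
    # accumulated curve at interval midpoints (standard ALE centering).
    midpoints = 0.5 * (accumulated[:-1] + accumulated[1:])
    center = float(np.sum(n_per * midpoints) / np.sum(n_per))
    effect = accumulated - center

    half = 1.96 * delta_sd / np.sqrt(np.maximum(n_per, 1))
    return ALEResult(
        feature_id=str(feature_id),
        grid=grid,
        effect=effect,
        delta_mean=delta_mean,
        ci_low=delta_mean - half,
        ci_high=delta_mean + half,
        n_per_increment=n_per,
    )


def plot_ale(result: ALEResult, ax=None, rug: pd.Series | None = None):
    """Plot a centered ALE curve with increment-wise CIs (and an optional
    rug of observed feature values)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.grid, result.effect, marker="o", lw=1.5, color="tab:blue")
    # CI band around each increment's endpoint effect
    ax.fill_between(result.grid[1:], result.effect[1:] - (result.delta_mean - result.ci_low),
                    result.effect[1:] + (result.ci_high - result.delta_mean),
                    alpha=0.2, color="tab:blue")
    if rug is not None:
        ax.plot(rug, np.full(len(rug), ax.get_ylim()[0]), "|", color="k", alpha=0.3)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(result.feature_id)
    ax.set_ylabel("accumulated local effect")
    return ax
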