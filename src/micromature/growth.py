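"""Growth prediction: attained LAZ/WHZ and growth velocity from the microbiome.

Models are fitted per age category, stratified by maternal HIV status, with
either microbiome features alone or microbiome plus epidemiological
covariates, reusing the 3-stage selection from :mod:`micromature.maturity`
with an identity response transform.  Growth velocity is the change in
LAZ/WHZ per day between a study visit and the child's subsequent visit,
attached to the earlier visit (predicting future growth from the current
microbiome).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import AGE_CATEGORIES, FeatureTable, epi_covariate_columns
from .interpretation import scaled_importance
from .maturity import SearchConfig, SelectedModel, three_stage_select

__all__ = [
    "GrowthTask",
    "GrowthModelResult",
    "compute_growth_velocity",
    "fit_growth_model",
    "run_growth_grid",
    "performance_frame",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("LAZ", "WHZ", "LAZ_velocity", "WHZ_velocity")
STRATA = ("HIV_negative_mothers", "HIV_positive_mothers", "all")
FEATURE_SETS = ("microbiome_only", "microbiome_plus_epi")

_STRATUM_EXPOSURE = {
    "HIV_negative_mothers": ("CHU",),
    "HIV_positive_mothers": ("CHEU",),
    "all": ("CHU", "CHEU"),
}


@dataclass(frozen=True)
class GrowthTask:
    outcome: str
    age_category: int
    hiv_stratum: str = "all"
    feature_set: str = "microbiome_only"
    feature_kind: str = "species"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.age_category not in AGE_CATEGORIES:
            raise ValueError(f"unknown age category {self.age_category!r}")
        if self.hiv_stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.hiv_stratum!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.feature_kind not in ("species", "pathway"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")

    def label(self) -> str:
        return (
            f"{self.outcome}_cat{self.age_category}_{self.hiv_stratum}"
            f"_{self.feature_set}_{self.feature_kind}"
        )


@dataclass
class GrowthModelResult:
    task: GrowthTask
    status: str                      # "ok" | "skipped: <reason>"
    n: int = 0
    model: SelectedModel | None = None
    pseudo_r2: float = float("nan")
    mae: float = float("nan")
    top_features: pd.DataFrame | None = None


def compute_growth_velocity(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample LAZ/WHZ velocity (Z-score units per day) to the child's
    next visit; missing for each child's final visit.

    Raises on non-increasing ages or duplicate visits within a child.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    out = pd.DataFrame(index=meta.index, columns=["laz_velocity", "whz_velocity"], dtype=float)
    for child, sub in meta.groupby("child_id"):
        if sub["visit"].duplicated().any():
            raise ValueError(f"duplicate visit for child {child!r}")
        sub = sub.sort_values("age_days")
        ages = sub["age_days"].to_numpy(dtype=float)
        if (np.diff(ages) <= 0).any():
            raise ValueError(f"non-increasing ages within child {child!r}")
        for col, vcol in (("laz", "laz_velocity"), ("whz", "whz_velocity")):
            z = sub[col].to_numpy(dtype=float)
            vel = (z[1:] - z[:-1]) / np.diff(ages)
            out.loc[sub.index[:-1], vcol] = vel
    return out


def _outcome_values(task: GrowthTask, meta: pd.DataFrame) -> pd.Series:
    if task.outcome == "LAZ":
        return meta["laz"]
    if task.outcome == "WHZ":
        return meta["whz"]
    vel = compute_growth_velocity(meta)
    return vel["laz_velocity" if task.outcome == "LAZ_velocity" else "whz_velocity"]


def _one_hot_epi(meta: pd.DataFrame) -> pd.DataFrame:
    cols = epi_covariate_columns(meta)
    base = meta[cols] if cols else pd.DataFrame(index=meta.index)
    extra = {}
    if "ebf_3m" in meta.columns:
        extra["epi_ebf_3m"] = meta["ebf_3m"].astype(float)
    if "delivery_csection" in meta.columns:
        extra["epi_delivery_csection"] = meta["delivery_csection"].astype(float)
    if "arm" in meta.columns:
        for lv in ("WASH", "IYCF", "WASH_IYCF"):  # SOC reference
            extra[f"epi_arm_{lv}"] = (meta["arm"] == lv).astype(float)
    return pd.concat([base, pd.DataFrame(extra, index=meta.index)], axis=1)


def fit_growth_model(
    task: GrowthTask,
    tables: dict[str, FeatureTable],
    metadata: pd.DataFrame,
    config: SearchConfig,
    min_n: int = 15,
    top_k: int = 20,
) -> GrowthModelResult:
    """Fit one cell of the growth task grid.

    One sample per child (the earliest in the category) is used; cells with
    fewer than ``min_n`` usable samples are skipped with an "unstable
    stratum" status rather than fitted.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    table = tables[task.feature_kind]
    outcome_all = _outcome_values(task, meta)

    sub = meta[meta["age_category"] == task.age_category]
    sub = sub[sub["hiv_exposure"].isin(_STRATUM_EXPOSURE[task.hiv_stratum])]
    sub = sub.loc[sub.index.intersection(table.data.index)]
    sub = sub.sort_values("age_days")
    sub = sub[~sub["child_id"].duplicated(keep="first")]
    y = outcome_all.loc[sub.index]
    n_missing = int(y.isna().sum())
    if n_missing:
        logger.info("%s: dropped %d samples with missing outcome", task.label(), n_missing)
    sub = sub.loc[y.notna()]
    y = y.loc[sub.index].astype(float)

    needed = max(min_n, config.stage1_folds)
    if len(sub) < needed:
        return GrowthModelResult(
            task, status=f"skipped: unstable stratum (n={len(sub)} < {needed})", n=len(sub)
        )

    X = table.data.loc[sub.index]
    groups = {"microbiome": list(X.columns)}
    if task.feature_set == "microbiome_plus_epi":
        epi = _one_hot_epi(sub)
        epi = epi.loc[:, epi.notna().all()]
        X = pd.concat([X, epi], axis=1)
        groups["epidemiological"] = list(epi.columns)

    model = three_stage_select(X, y.to_numpy(), config, feature_groups=groups)
    top = scaled_importance(model, top_k=top_k)
    return GrowthModelResult(
        task,
        status="ok",
        n=len(sub),
        model=model,
        pseudo_r2=model.metrics["pseudo_r2"],
        mae=model.metrics["mae"],
        top_features=top,
    )


def run_growth_grid(
    tables: dict[str, FeatureTable],
    metadata: pd.DataFrame,
    config: SearchConfig,
    outcomes=OUTCOMES,
    age_categories=AGE_CATEGORIES,
    strata=STRATA,
    feature_sets=FEATURE_SETS,
    feature_kinds=("species", "pathway"),
    min_n: int = 15,
) -> list[GrowthModelResult]:
    """Iterate the task grid; every cell gets a result with an explicit
    status (fitted or skipped), independent of iteration order."""
    results = []
    for outcome, cat, stratum, fset, kind in itertools.product(
        outcomes, age_categories, strata, feature_sets, feature_kinds
    ):
        task = GrowthTask(outcome, cat, stratum, fset, kind)
        try:
            res = fit_growth_model(task, tables, metadata, config, min_n=min_n)
        except ValueError as exc:
            res = GrowthModelResult(task, status=f"skipped: {exc}")
        results.append(res)
    return results


def performance_frame(results: list[GrowthModelResult]) -> pd.DataFrame:
    """Tidy performance table, one row per task cell."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.task.outcome,
                "age_category": r.task.age_category,
                "hiv_stratum": r.task.hiv_stratum,
                "feature_set": r.task.feature_set,
                "feature_kind": r.task.feature_kind,
                "status": r.status,
                "n": r.n,
                "pseudo_r2": r.pseudo_r2,
                "mae": r.mae,
            }
        )
    return pd.DataFrame(rows)
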