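"""Microbiota/metagenome age: staged gradient-boosting selection and MAZ scores.

The centre of the package: a 3-stage model-selection protocol around an
XGBoost regressor, the healthy/unhealthy cohort partition, age prediction
from microbiome features, and microbiota-for-age Z-scores (MAZ; MetAZ when
the features are metabolic pathways).

The selection protocol:

* **Stage 1** — hyperparameter search (Bayesian by default, random
  optionally) scored by k-fold cross-validated MSE.  Configurations in the
  lowest ``model_retention_quantile`` of CV MSE are retained; their
  feature-importance profiles are summed and the features contributing to
  the top ``importance_retention_fraction`` of cumulative importance are
  kept, separately within each feature group (microbiome vs
  epidemiological).
* **Stage 2** — the search is repeated on the retained features with
  leave-one-out CV (falling back to k-fold above ``max_loocv_n`` samples),
  and the importance filter is applied again.
* **Stage 3** — a final ensemble is fitted with the stage-2 winning
  hyperparameters and features; out-of-fold predictions over the training
  set give honest training metrics (pseudo-R², MAE, MSE).

For age models the response is log(age in months); predictions are
exponentiated back to months.  MAZ standardizes a child's predicted age
against the median and SD of healthy-reference predictions at the same
scheduled study visit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .feature_table import DAYS_PER_MONTH, FeatureTable

__all__ = [
    "ParamRange",
    "DEFAULT_SPACE",
    "SearchConfig",
    "SelectedModel",
    "CohortPartition",
    "MaturityReference",
    "pseudo_r2",
    "mae",
    "three_stage_select",
    "partition_cohort",
    "fit_age_model",
    "AgeModelResult",
    "build_reference",
    "compute_maz",
    "compute_maz_scores",
    "compare_maturity",
]

logger = logging.getLogger(__name__)


# -- metrics -----------------------------------------------------------------

def pseudo_r2(observed, predicted) -> float:
    """1 - SSE/SST; negative values mean the model is worse than predicting
    the mean response."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    sst = ((obs - obs.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("observed response has zero variance")
    return float(1.0 - ((obs - pred) ** 2).sum() / sst)


def mae(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    return float(np.abs(obs - pred).mean())


def _safe_metrics(obs: np.ndarray, pred: np.ndarray) -> dict:
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        r2 = 0.0 if sse == 0 else float("-inf")
    else:
        r2 = 1.0 - sse / sst
    return {"pseudo_r2": r2, "mae": mae(obs, pred), "mse": sse / len(obs)}


# -- hyperparameter space ----------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    low: float
    high: float
    integer: bool = False
    log: bool = False


#: Conventional ranges for boosted trees on sparse omics tables; fully
#: configurable through :class:`SearchConfig`.
DEFAULT_SPACE: Mapping[str, ParamRange] = {
    "max_depth": ParamRange(2, 8, integer=True),
    "learning_rate": ParamRange(0.01, 0.3, log=True),
    "n_estimators": ParamRange(50, 500, integer=True),
    "subsample": ParamRange(0.5, 1.0),
    "colsample_bytree": ParamRange(0.3, 1.0),
    "reg_alpha": ParamRange(0.0, 5.0),
    "reg_lambda": ParamRange(0.0, 5.0),
}


@dataclass
class SearchConfig:
    """Configuration of the 3-stage selection.

    ``backend='gp'`` runs expected-improvement Bayesian search over a
    Gaussian-process surrogate; ``'random'`` runs plain random search.
    ``importance_type`` is the XGBoost importance flavour used for the
    cumulative filter (gain | cover | frequency).
    """

    space: Mapping[str, ParamRange] = field(default_factory=lambda: dict(DEFAULT_SPACE))
    n_iterations: int = 30
    stage1_folds: int = 10
    model_retention_quantile: float = 0.05
    importance_retention_fraction: float = 0.95
    importance_type: str = "gain"
    backend: str = "gp"
    n_initial: int = 8
    max_loocv_n: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.model_retention_quantile <= 1.0):
            raise ValueError("model_retention_quantile must be in (0, 1]")
        if not (0.0 < self.importance_retention_fraction <= 1.0):
            raise ValueError("importance_retention_fraction must be in (0, 1]")
        if self.stage1_folds < 2:
            raise ValueError("stage1_folds must be >= 2")
        if self.importance_type not in ("gain", "cover", "frequency"):
            raise ValueError(f"unknown importance_type {self.importance_type!r}")
        if self.backend not in ("gp", "random"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def desk_scale(cls, seed: int = 0, n_iterations: int = 8) -> "SearchConfig":
        """Search configuration sized for the bundled synthetic cohorts:
        fewer search iterations and a tighter boosting-round range than the
        full-cohort defaults."""
        space = dict(DEFAULT_SPACE)
        space["n_estimators"] = ParamRange(50, 200, integer=True)
        return cls(space=space, n_iterations=n_iterations, n_initial=min(5, n_iterations),
                   seed=seed)


def _encode(params: dict, space: Mapping[str, ParamRange]) -> np.ndarray:
    x = []
    for name, r in space.items():
        v = params[name]
        if r.log:
            x.append((np.log(v) - np.log(r.low)) / (np.log(r.high) - np.log(r.low)))
        else:
            x.append((v - r.low) / (r.high - r.low))
    return np.array(x)


def _decode(u: np.ndarray, space: Mapping[str, ParamRange]) -> dict:
    params = {}
    for ui, (name, r) in zip(u, space.items()):
        if r.log:
            v = float(np.exp(np.log(r.low) + ui * (np.log(r.high) - np.log(r.low))))
        else:
            v = float(r.low + ui * (r.high - r.low))
        if r.integer:
            v = int(round(np.clip(v, r.low, r.high)))
        params[name] = v
    return params


def _propose_gp(trials: list, space, rng: np.random.Generator) -> dict:
    """Expected-improvement proposal from a GP surrogate over the unit cube."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel
    from scipy.stats import norm

    X = np.array([_encode(p, space) for p, _ in trials])
    y = np.array([m for _, m in trials])
    y_std = y.std()
    yn = (y - y.mean()) / (y_std if y_std > 0 else 1.0)
    kernel = Matern(nu=2.5, length_scale=np.full(X.shape[1], 0.3)) + WhiteKernel(1e-2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, alpha=1e-8,
                                      random_state=int(rng.integers(2**31)))
        gp.fit(X, yn)
        cand = rng.random((256, X.shape[1]))
        mu, sd = gp.predict(cand, return_std=True)
    best = yn.min()
    sd = np.maximum(sd, 1e-9)
    z = (best - mu) / sd
    ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
    return _decode(cand[int(np.argmax(ei))], space)


def _make_model(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        **params,
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def _build_folds(n: int, scheme: str, k: int, seed: int) -> list:
    if scheme == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    k = min(k, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _oof_predict(X: pd.DataFrame, y: np.ndarray, params: dict, folds, seed: int):
    """Out-of-fold predictions; every sample predicted by a model that never
    saw it.  Returns (predictions, fold assignment per sample)."""
    pred = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for f, (tr, te) in enumerate(folds):
        model = _make_model(params, seed)
        model.fit(X.iloc[tr], y[tr])
        pred[te] = model.predict(X.iloc[te])
        fold_of[te] = f
    return pred, fold_of


def _search_stage(X, y, folds, config: SearchConfig, rng) -> list:
    """Evaluate ``n_iterations`` hyperparameter configurations; return
    [(params, cv_mse), ...] in evaluation order."""
    trials = []
    for i in range(config.n_iterations):
        if config.backend == "gp" and len(trials) >= max(config.n_initial, 2):
            params = _propose_gp(trials, config.space, rng)
        else:
            params = _decode(rng.random(len(config.space)), config.space)
        pred, _ = _oof_predict(X, y, params, folds, config.seed)
        mse = float(((y - pred) ** 2).mean())
        trials.append((params, mse))
    return trials


def _retain_models(trials: list, quantile: float) -> list:
    mses = np.array([m for _, m in trials])
    cut = np.quantile(mses, quantile)
    retained = [(p, m) for p, m in trials if m <= cut]
    if not retained:
        retained = [min(trials, key=lambda t: t[1])]
    return retained


_IMPORTANCE_MAP = {"gain": "gain", "cover": "cover", "frequency": "weight"}


def _summed_importance(X, y, retained: list, config: SearchConfig) -> pd.Series:
    total = pd.Series(0.0, index=X.columns)
    for params, _ in retained:
        model = _make_model(params, config.seed)
        model.fit(X, y)
        score = model.get_booster().get_score(
            importance_type=_IMPORTANCE_MAP[config.importance_type]
        )
        total = total.add(pd.Series(score, dtype=float), fill_value=0.0)
    return total.reindex(X.columns).fillna(0.0)


def _filter_by_importance(
    importance: pd.Series, groups: Mapping[str, Sequence[str]], fraction: float
) -> list[str]:
    """Keep features reaching ``fraction`` of cumulative importance within
    each group.  fraction >= 1 keeps every feature (identity filter)."""
    if fraction >= 1.0:
        return [f for cols in groups.values() for f in cols]
    kept: list[str] = []
    for gname, cols in groups.items():
        cols = [c for c in cols if c in importance.index]
        imp = importance.loc[cols].sort_values(ascending=False)
        total = imp.sum()
        if total <= 0:
            # no information to filter on; keep the group intact
            kept.extend(cols)
            continue
        cum = imp.cumsum() / total
        # include the feature that crosses the threshold
        n_keep = int(np.searchsorted(cum.to_numpy(), fraction) + 1)
        kept.extend(imp.index[:n_keep])
    return kept


class _BoosterShim:
    """Predict-only wrapper around a deserialized Booster, presenting the
    small surface SelectedModel needs (predict on a DataFrame, get_booster)."""

    def __init__(self, booster):
        self._booster = booster

    @classmethod
    def load(cls, path) -> "_BoosterShim":
        import xgboost

        booster = xgboost.Booster()
        booster.load_model(path)
        return cls(booster)

    def get_booster(self):
        return self._booster

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        import xgboost

        return self._booster.predict(xgboost.DMatrix(X))


@dataclass
class SelectedModel:
    """Outcome of the 3-stage search."""

    retained_features: list
    retained_by_group: dict
    final_hyperparameters: dict
    model: XGBRegressor
    oof_predictions: pd.Series
    oof_fold_assignment: pd.Series
    metrics: dict
    response_transform: str
    stage_history: list

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.retained_features])

    def save(self, directory) -> None:
        """Serialize the fitted ensemble plus a manifest (features,
        hyperparameters, metrics, library version)."""
        import json
        import xgboost
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        booster = self.model.get_booster() if hasattr(self.model, "get_booster") else self.model
        booster.save_model(d / "model.json")
        manifest = {
            "retained_features": list(map(str, self.retained_features)),
            "retained_by_group": {g: list(map(str, c)) for g, c in self.retained_by_group.items()},
            "final_hyperparameters": self.final_hyperparameters,
            "metrics": self.metrics,
            "response_transform": self.response_transform,
            "xgboost_version": xgboost.__version__,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    @classmethod
    def load(cls, directory) -> "SelectedModel":
        import json
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        model = _BoosterShim.load(d / "model.json")
        return cls(
            retained_features=manifest["retained_features"],
            retained_by_group=manifest["retained_by_group"],
            final_hyperparameters=manifest["final_hyperparameters"],
            model=model,
            oof_predictions=pd.Series(dtype=float),
            oof_fold_assignment=pd.Series(dtype=int),
            metrics=manifest["metrics"],
            response_transform=manifest["response_transform"],
            stage_history=[],
        )


def three_stage_select(
    X: pd.DataFrame,
    y,
    config: SearchConfig,
    feature_groups: Mapping[str, Sequence[str]] | None = None,
    response_transform: str = "identity",
) -> SelectedModel:
    """Run the full staged hyperparameter/feature selection (see module docs)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if n < config.stage1_folds:
        raise ValueError(f"n={n} smaller than stage-1 folds ({config.stage1_folds})")
    if feature_groups is None:
        feature_groups = {"microbiome": list(X.columns)}
    rng = np.random.default_rng(config.seed)
    history = []

    # Stage 1: k-fold CV search, retain low-MSE models, filter features.
    folds1 = _build_folds(n, "kfold", config.stage1_folds, config.seed)
    trials1 = _search_stage(X, y, folds1, config, rng)
    retained1 = _retain_models(trials1, config.model_retention_quantile)
    imp1 = _summed_importance(X, y, retained1, config)
    feats1 = _filter_by_importance(imp1, feature_groups, config.importance_retention_fraction)
    if not feats1:
        raise ValueError(
            "stage 1 filtered out every feature; relax importance_retention_fraction"
        )
    history.append({"stage": 1, "trials": trials1, "retained_features": list(feats1)})

    # Stage 2: LOOCV (or k-fold fallback) on retained features, re-filter.
    scheme2 = "loo" if n <= config.max_loocv_n else "kfold"
    if scheme2 == "kfold":
        logger.warning(
            "n=%d exceeds max_loocv_n=%d; stage 2/3 use %d-fold CV instead of LOOCV",
            n, config.max_loocv_n, config.stage1_folds,
        )
    folds2 = _build_folds(n, scheme2, config.stage1_folds, config.seed)
    X2 = X[feats1]
    groups2 = {g: [c for c in cols if c in feats1] for g, cols in feature_groups.items()}
    trials2 = _search_stage(X2, y, folds2, config, rng)
    retained2 = _retain_models(trials2, config.model_retention_quantile)
    imp2 = _summed_importance(X2, y, retained2, config)
    feats2 = _filter_by_importance(imp2, groups2, config.importance_retention_fraction)
    if not feats2:
        raise ValueError(
            "stage 2 filtered out every feature; relax importance_retention_fraction"
        )
    history.append({"stage": 2, "trials": trials2, "retained_features": list(feats2)})

    # Stage 3: final fit with stage-2 winning hyperparameters and features.
    best_params = min(trials2, key=lambda t: t[1])[0]
    X3 = X[feats2]
    folds3 = _build_folds(n, scheme2, config.stage1_folds, config.seed)
    oof, fold_of = _oof_predict(X3, y, best_params, folds3, config.seed)
    final = _make_model(best_params, config.seed)
    final.fit(X3, y)
    metrics = _safe_metrics(y, oof)
    history.append({"stage": 3, "params": best_params, "metrics": metrics})

    groups3 = {g: [c for c in cols if c in feats2] for g, cols in groups2.items()}
    return SelectedModel(
        retained_features=list(X3.columns),
        retained_by_group=groups3,
        final_hyperparameters=dict(best_params),
        model=final,
        oof_predictions=pd.Series(oof, index=X.index),
        oof_fold_assignment=pd.Series(fold_of, index=X.index),
        metrics=metrics,
        response_transform=response_transform,
        stage_history=history,
    )


# -- cohort partition --------------------------------------------------------

@dataclass
class CohortPartition:
    """Healthy-train / healthy-test / unhealthy sample sets (disjoint; all
    samples of a child fall on one side)."""

    healthy_train: list
    healthy_test: list
    unhealthy: list
    excluded_missing_age: list

    def set_of(self, sample_id) -> str:
        if sample_id in set(self.healthy_train):
            return "healthy_train"
        if sample_id in set(self.healthy_test):
            return "healthy_test"
        return "unhealthy"


def partition_cohort(metadata: pd.DataFrame) -> CohortPartition:
    """Partition children for the age model.

    Healthy reference = HIV-unexposed-uninfected (CHU) children with 18-month
    LAZ > -2; those contributing more than one sample form the training set,
    single-sample healthy children the healthy test set.  Everyone else
    (CHEU, stunted at 18 months, HIV-positive/unknown status, or missing
    18-month LAZ — conservatively never allowed to contaminate the
    reference) forms the unhealthy test set.  Samples with missing age are
    excluded entirely.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing_age = meta.index[meta["age_days"].isna()].tolist()
    if missing_age:
        logger.info("excluding %d samples with missing age", len(missing_age))
    meta = meta.loc[meta["age_days"].notna()]
    healthy_train, healthy_test, unhealthy = [], [], []
    for child, sub in meta.groupby("child_id"):
        hiv = sub["hiv_exposure"].iloc[0]
        laz18 = sub["laz_18m"].iloc[0]
        if hiv == "CHU" and pd.isna(laz18):
            logger.info("child %s missing 18-month LAZ; assigned unhealthy", child)
        healthy = hiv == "CHU" and pd.notna(laz18) and laz18 > -2
        samples = sub.index.tolist()
        if healthy and len(samples) > 1:
            healthy_train.extend(samples)
        elif healthy:
            healthy_test.extend(samples)
        else:
            unhealthy.extend(samples)
    return CohortPartition(healthy_train, healthy_test, unhealthy, missing_age)


# -- age model ---------------------------------------------------------------

@dataclass
class AgeModelResult:
    model: SelectedModel
    predictions: pd.DataFrame  # sample_id index: set, age_months, predicted_age_months
    metrics: dict              # per set: pseudo_r2, mae (months)


def fit_age_model(
    table: FeatureTable,
    metadata: pd.DataFrame,
    partition: CohortPartition,
    config: SearchConfig,
) -> AgeModelResult:
    """Train the microbiota/metagenome age model on the healthy training set.

    Response is log(age in months); out-of-fold predictions give training
    metrics, the refitted final model scores the two held-out sets.  All
    predictions are exponentiated back to months.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if not partition.healthy_train:
        raise ValueError("empty healthy training set")
    train_ids = [s for s in partition.healthy_train if s in table.data.index]
    X_train = table.data.loc[train_ids]
    age_months = meta["age_days"].astype(float) / DAYS_PER_MONTH
    y_train = np.log(age_months.loc[train_ids].to_numpy())
    selected = three_stage_select(X_train, y_train, config, response_transform="log_age")

    rows = []
    oof_months = np.exp(selected.oof_predictions)
    for sid in train_ids:
        rows.append((sid, "healthy_train", age_months.loc[sid], float(oof_months.loc[sid])))
    for set_name, ids in (
        ("healthy_test", partition.healthy_test),
        ("unhealthy", partition.unhealthy),
    ):
        ids = [s for s in ids if s in table.data.index]
        if ids:
            pred = np.exp(selected.predict(table.data.loc[ids]))
            for sid, p in zip(ids, pred):
                rows.append((sid, set_name, age_months.loc[sid], float(p)))
    preds = pd.DataFrame(
        rows, columns=["sample_id", "set", "age_months", "predicted_age_months"]
    ).set_index("sample_id")

    metrics = {}
    for set_name, sub in preds.groupby("set"):
        obs = sub["age_months"].to_numpy()
        pred = sub["predicted_age_months"].to_numpy()
        if len(obs) >= 2 and obs.var() > 0:
            metrics[set_name] = {"pseudo_r2": pseudo_r2(obs, pred), "mae": mae(obs, pred)}
        else:
            metrics[set_name] = {"pseudo_r2": np.nan, "mae": mae(obs, pred)}
    return AgeModelResult(model=selected, predictions=preds, metrics=metrics)


# -- MAZ ---------------------------------------------------------------------

@dataclass
class MaturityReference:
    """Per-visit median and SD of predicted age among healthy-reference
    children; visits with SD = 0 or fewer than 2 children are unusable."""

    table: pd.DataFrame  # index visit: median, sd, n, usable

    @classmethod
    def from_predictions(cls, predicted_age: pd.Series, metadata: pd.DataFrame):
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        visits = meta.loc[predicted_age.index, "visit"]
        rows = {}
        for visit, sub in predicted_age.groupby(visits):
            n = len(sub)
            sd = float(sub.std(ddof=1)) if n >= 2 else 0.0
            usable = n >= 2 and sd > 0
            if not usable:
                warnings.warn(f"visit {visit!r} reference unusable (n={n}, sd={sd})")
            rows[visit] = {"median": float(sub.median()), "sd": sd, "n": n, "usable": usable}
        return cls(pd.DataFrame.from_dict(rows, orient="index"))


def build_reference(predicted_age: pd.Series, metadata: pd.DataFrame) -> MaturityReference:
    """Reference distribution of predicted age per scheduled visit (the visit
    label, not the derived age category, indexes the reference)."""
    return MaturityReference.from_predictions(predicted_age, metadata)


def compute_maz(predicted_age: float, visit: str, reference: MaturityReference) -> float:
    """(predicted age - visit median) / visit SD among healthy references;
    NaN (with a warning) where the visit reference is unusable."""
    if visit not in reference.table.index or not reference.table.loc[visit, "usable"]:
        warnings.warn(f"no usable reference at visit {visit!r}; MAZ missing")
        return float("nan")
    row = reference.table.loc[visit]
    return float((predicted_age - row["median"]) / row["sd"])


def compute_maz_scores(
    predicted_age: pd.Series, metadata: pd.DataFrame, reference: MaturityReference
) -> pd.DataFrame:
    """Vectorized MAZ for a set of samples; columns (visit,
    predicted_age_months, maz), indexed by sample."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, pred in predicted_age.items():
            visit = meta.loc[sid, "visit"]
            out.append((sid, visit, float(pred), compute_maz(pred, visit, reference)))
    return pd.DataFrame(
        out, columns=["sample_id", "visit", "predicted_age_months", "maz"]
    ).set_index("sample_id")


def compare_maturity(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=None,
    value_col: str = "maz",
) -> pd.DataFrame:
    """Covariate-adjusted regression of a maturity score on HIV exposure
    (CHEU vs CHU), per age category.

    HIV-positive / HIV-unknown children are excluded from the contrast.
    Returns a frame (age_category, beta, se, p, n): beta > 0 means greater
    maturity in CHEU.
    """
    from .differential_abundance import DEFAULT_COVARIATES, fit_feature_association

    if covariates is None:
        covariates = DEFAULT_COVARIATES
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    merged = scores.join(meta, how="inner", rsuffix="_meta")
    merged = merged[merged["hiv_exposure"].isin(["CHEU", "CHU"])]
    if merged["hiv_exposure"].nunique() < 2:
        raise ValueError("need both CHEU and CHU samples for the contrast")
    merged["cheu"] = (merged["hiv_exposure"] == "CHEU").astype(float)
    rows = []
    for cat, sub in merged.groupby("age_category"):
        if sub["cheu"].nunique() < 2:
            logger.info("age category %s has one exposure group; skipped", cat)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, se, p, n = fit_feature_association(
                    sub[value_col].to_numpy(), sub, "cheu", covariates
                )
        except ValueError as exc:
            logger.info("age category %s skipped: %s", cat, exc)
            continue
        rows.append({"age_category": cat, "beta": beta, "se": se, "p": p, "n": n})
    return pd.DataFrame(rows)
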