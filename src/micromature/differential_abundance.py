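"""Covariate-adjusted per-feature association of abundances with a phenotype.

Re-implements the analysis role of a MaAsLin-style differential-abundance
stage as a transparent, generic pipeline: per-feature log transform with a
half-minimum-nonzero pseudocount, ordinary least squares on the phenotype
with adjustment covariates, and Benjamini-Hochberg FDR control.  This is a
deliberate approximation of that package's default linear model, not a
clone of its normalization/model menu.

The default covariate set for the bundled analyses is age in days at stool
collection, exclusive breastfeeding at 3 months, caesarean delivery, and
randomized trial arm (four-level factor, SOC reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_COVARIATES",
    "DiffAbundResult",
    "transform_abundance",
    "fit_feature_association",
    "bh_adjust",
    "run_differential_abundance",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_days", "ebf_3m", "delivery_csection", "arm")
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_Q_THRESHOLD = 0.25


@dataclass
class DiffAbundResult:
    feature_id: str
    beta: float
    se: float
    p_value: float
    q_value: float
    n_used: int
    covariates_used: tuple
    significant: bool = False


def transform_abundance(values) -> np.ndarray | None:
    """Log-transform fractions, replacing zeros by half the minimum nonzero
    value of the feature.  Returns ``None`` for an all-zero feature (the
    caller skips it with a log entry)."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    nz = x[x > 0]
    if nz.size == 0:
        return None
    out = x.copy()
    out[out == 0] = nz.min() / 2.0
    return np.log(out)


def _design_matrix(meta: pd.DataFrame, phenotype: str, covariates) -> pd.DataFrame:
    cols = {}
    pheno = meta[phenotype]
    if pheno.dtype == object or str(pheno.dtype) == "category":
        levels = sorted(pheno.dropna().unique())
        if len(levels) < 2:
            raise ValueError(f"phenotype {phenotype!r} is constant")
        # binary contrast: second level vs first (alphabetical reference)
        cols[phenotype] = (pheno == levels[-1]).astype(float)
    else:
        if pheno.nunique(dropna=True) < 2:
            raise ValueError(f"phenotype {phenotype!r} is constant")
        cols[phenotype] = pheno.astype(float)
    for c in covariates:
        s = meta[c]
        if s.dtype == object or str(s.dtype) == "category":
            levels = list(pd.unique(s.dropna()))
            ref = "SOC" if "SOC" in levels else levels[0]
            for lv in levels:
                if lv == ref:
                    continue
                cols[f"{c}[{lv}]"] = (s == lv).astype(float)
        else:
            cols[c] = s.astype(float)
    X = pd.DataFrame(cols, index=meta.index)
    return X


def fit_feature_association(
    y, meta: pd.DataFrame, phenotype: str, covariates=DEFAULT_COVARIATES
) -> tuple[float, float, float, int]:
    """OLS of a transformed abundance on phenotype + covariates.

    Returns (beta, se, two-sided p, n_used) for the phenotype term.
    Constant/collinear covariate columns are dropped with a warning; a
    constant phenotype is an error.
    """
    X = _design_matrix(meta, phenotype, covariates)
    yv = pd.Series(np.asarray(y, dtype=float), index=meta.index)
    keep = yv.notna() & X.notna().all(axis=1)
    X, yv = X.loc[keep], yv.loc[keep]
    if X[phenotype].nunique() < 2:
        raise ValueError(f"phenotype {phenotype!r} constant after missing-data exclusion")
    # Drop constant adjustment columns (collinearity guard).
    for c in list(X.columns):
        if c != phenotype and X[c].nunique() <= 1:
            warnings.warn(f"dropping constant design column {c!r}")
            X = X.drop(columns=c)
    if len(yv) <= X.shape[1] + 1:
        raise ValueError(f"too few samples ({len(yv)}) for design with {X.shape[1]} columns")
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(yv, Xc).fit()
    return (
        float(fit.params[phenotype]),
        float(fit.bse[phenotype]),
        float(fit.pvalues[phenotype]),
        int(len(yv)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_differential_abundance(
    table,
    metadata: pd.DataFrame,
    phenotype: str,
    covariates=DEFAULT_COVARIATES,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    dedupe_per_child: bool = True,
) -> list[DiffAbundResult]:
    """Per-feature covariate-adjusted association over a (filtered) table.

    The caller subsets to an age category beforehand.  By default one sample
    per child (the earliest) is kept within the subset, to avoid
    pseudo-replication; all-zero features are skipped with a log entry, and
    samples with missing covariates are dropped listwise inside the fit.
    Results are sorted by q-value and flagged significant at
    p < ``p_threshold`` and q < ``q_threshold``.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[meta.index.intersection(table.data.index)]
    if dedupe_per_child and "child_id" in meta.columns:
        before = len(meta)
        meta = meta.sort_values("age_days").drop_duplicates("child_id", keep="first")
        if len(meta) < before:
            logger.info("deduplicated %d repeat samples per child", before - len(meta))
    data = table.data.loc[meta.index]
    results = []
    for feat in data.columns:
        ty = transform_abundance(data[feat].to_numpy())
        if ty is None:
            logger.info("feature %s all-zero; skipped", feat)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, se, p, n = fit_feature_association(ty, meta, phenotype, covariates)
        results.append(
            DiffAbundResult(
                feature_id=str(feat),
                beta=beta,
                se=se,
                p_value=p,
                q_value=np.nan,
                n_used=n,
                covariates_used=tuple(covariates),
            )
        )
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = bool(r.p_value < p_threshold and r.q_value < q_threshold)
        results.sort(key=lambda r: (r.q_value, r.p_value))
    return results


def results_to_frame(results: list[DiffAbundResult]) -> pd.DataFrame:
    """Tidy frame (feature, beta, se, p, q, n, significant) for CSV export."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_id,
                "beta": r.beta,
                "se": r.se,
                "p": r.p_value,
                "q": r.q_value,
                "n": r.n_used,
                "significant": r.significant,
            }
            for r in results
        ]
    )
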