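"""Relative-abundance feature tables, sample metadata, filtering and age binning.

The central container is :class:`FeatureTable`, a thin wrapper around a
samples x features :class:`pandas.DataFrame` of relative abundances
(unitless fractions in [0, 1]) produced by marker-based taxonomic profilers
(species tables) or pathway annotators (pathway tables).  Rows may sum to
less than one: the unannotated remainder of a metagenome is real and is not
stored as a feature.

Sample metadata travels as a plain :class:`pandas.DataFrame` with the column
dictionary in :data:`METADATA_COLUMNS`, validated by
:func:`validate_metadata`, which also derives the combined trial-arm
indicators and the age category of every sample.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "FilterSpec",
    "SPECIES_FILTER",
    "PATHWAY_FILTER",
    "AGE_CATEGORIES",
    "DAYS_PER_MONTH",
    "DAYS_PER_WEEK",
    "METADATA_COLUMNS",
    "load_feature_table",
    "write_feature_table",
    "filter_features",
    "assign_age_category",
    "load_metadata",
    "validate_metadata",
]

#: Average Gregorian month length in days, used for all month/day conversions.
DAYS_PER_MONTH = 30.4375
DAYS_PER_WEEK = 7.0

#: The six age categories (labelled by nominal month) used to re-bin samples.
AGE_CATEGORIES = (1, 2, 3, 6, 12, 18)

_ROW_SUM_TOL = 1e-6

#: Scheduled study visits (nominal month labels).
VISITS = ("1m", "3m", "6m", "12m", "18m")

#: Documented metadata column dictionary.  ``epi_`` prefixed columns are
#: free-form epidemiological covariates (numeric or categorical).
METADATA_COLUMNS = {
    "sample_id": "unique stool-sample identifier",
    "child_id": "child identifier; repeated across a child's visits",
    "age_days": "age at stool collection, integer days",
    "visit": "scheduled study visit, one of " + ", ".join(VISITS),
    "hiv_exposure": "CHEU | CHU | HIV_positive | HIV_unknown",
    "laz_18m": "length-for-age Z-score at 18 months (may be missing)",
    "laz": "length-for-age Z-score at this visit",
    "whz": "weight-for-height Z-score at this visit",
    "ebf_3m": "exclusively breastfed at 3 months (bool)",
    "delivery_csection": "caesarean delivery (bool)",
    "arm": "randomized trial arm: SOC | WASH | IYCF | WASH_IYCF",
}

ARMS = ("SOC", "WASH", "IYCF", "WASH_IYCF")
HIV_EXPOSURE_LEVELS = ("CHEU", "CHU", "HIV_positive", "HIV_unknown")


class FeatureTableError(ValueError):
    """Malformed feature table (parse error, invariant violation)."""


@dataclass
class FeatureTable:
    """Samples x features relative-abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as index and feature identifiers
        as columns; values are fractions in [0, 1].
    kind:
        ``"species"`` or ``"pathway"``.
    provenance:
        Free-form record of how the table was produced (source file,
        filtering history).
    """

    data: pd.DataFrame
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("species", "pathway"):
            raise FeatureTableError(f"unknown feature kind {self.kind!r}")
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FeatureTableError(f"duplicate sample id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FeatureTableError(f"duplicate feature id {dup!r}")
        values = df.to_numpy(dtype=float)
        if values.size:
            if not np.isfinite(values).all():
                raise FeatureTableError("non-finite abundance values")
            if (values < 0).any():
                row = df.index[np.where(values < 0)[0][0]]
                raise FeatureTableError(f"negative abundance in sample {row!r}")
            if (values > 1 + _ROW_SUM_TOL).any():
                row = df.index[np.where(values > 1 + _ROW_SUM_TOL)[0][0]]
                raise FeatureTableError(f"abundance > 1 in sample {row!r}")
            sums = values.sum(axis=1)
            if (sums > 1 + _ROW_SUM_TOL).any():
                row = df.index[int(np.argmax(sums))]
                raise FeatureTableError(
                    f"abundances of sample {row!r} sum to {sums.max():.6f} > 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], self.kind, dict(self.provenance))


@dataclass(frozen=True)
class FilterSpec:
    """Feature-retention thresholds, all as fractions in [0, 1].

    A feature is retained when its maximum relative abundance across samples
    exceeds ``min_rel_abund`` and it is detected (abundance strictly above
    ``detection_threshold``) in at least ``min_prevalence`` of samples.
    """

    min_rel_abund: float
    min_prevalence: float
    detection_threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("min_rel_abund", "min_prevalence", "detection_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


#: Default species filter: > 0.1 % relative abundance and >= 5 % prevalence.
SPECIES_FILTER = FilterSpec(min_rel_abund=1e-3, min_prevalence=0.05)

#: Default pathway filter: > 3e-7 % relative abundance (3e-9 as a fraction,
#: the literal reading of the stated percentage) and >= 5 % prevalence.
PATHWAY_FILTER = FilterSpec(min_rel_abund=3e-9, min_prevalence=0.05)


def load_feature_table(path, kind: str, unit: str = "percent") -> FeatureTable:
    """Read a merged profiler table (features in column 1, one column per sample).

    Parameters
    ----------
    unit:
        ``"percent"`` (values divided by 100) or ``"fraction"``.
    """
    if unit not in ("percent", "fraction"):
        raise ValueError(f"unit must be 'percent' or 'fraction', got {unit!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FeatureTableError(f"{path}: duplicated feature row {dup!r}")
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise FeatureTableError(f"{path}: ragged or non-numeric row {feat!r}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FeatureTableError(f"{path}: non-numeric values ({exc})") from exc
    if (values.to_numpy() < 0).any():
        feat = values.index[(values < 0).any(axis=1)][0]
        raise FeatureTableError(f"{path}: negative value in feature row {feat!r}")
    data = values.T  # samples x features
    if unit == "percent":
        data = data / 100.0
    return FeatureTable(data, kind=kind, provenance={"source": str(path), "unit": unit})


def write_feature_table(table: FeatureTable, path, unit: str = "percent") -> None:
    """Write in the same merged-table dialect (features as rows)."""
    data = table.data.T
    if unit == "percent":
        data = data * 100.0
    elif unit != "fraction":
        raise ValueError(f"unit must be 'percent' or 'fraction', got {unit!r}")
    data.to_csv(path, sep="\t", index_label=f"{table.kind}_id")


def filter_features(table: FeatureTable, spec: FilterSpec) -> FeatureTable:
    """Apply abundance/prevalence thresholds; never renormalizes rows.

    Retained abundances are left as profiled so that values stay comparable
    across samples and with the unfiltered table.  The returned table's
    provenance records the spec and the dropped feature identifiers, and is
    written as a JSON sidecar by :func:`write_filter_provenance`.
    """
    df = table.data
    if df.shape[1] == 0:
        prov = dict(table.provenance)
        prov["filter"] = {"spec": spec.__dict__, "dropped_features": []}
        return FeatureTable(df.copy(), table.kind, prov)
    max_abund = df.max(axis=0)
    prevalence = (df > spec.detection_threshold).mean(axis=0)
    keep = (max_abund > spec.min_rel_abund) & (prevalence >= spec.min_prevalence)
    dropped = [str(f) for f in df.columns[~keep]]
    prov = dict(table.provenance)
    prov["filter"] = {"spec": dict(spec.__dict__), "dropped_features": dropped}
    return FeatureTable(df.loc[:, keep], table.kind, prov)


def write_filter_provenance(table: FeatureTable, path) -> None:
    Path(path).write_text(json.dumps(table.provenance.get("filter", {}), indent=2))


# -- age categories ----------------------------------------------------------

# Half-open bins [lower, upper) in days, except the first (0-6 weeks,
# 42 days inclusive) and the last (capped at 20 months inclusive).
_AGE_BIN_EDGES = {
    1: (0.0, 6 * DAYS_PER_WEEK),           # 0 - 6 weeks, upper inclusive
    2: (6 * DAYS_PER_WEEK, 3 * DAYS_PER_MONTH),   # 7 weeks - <3 months
    3: (3 * DAYS_PER_MONTH, 6 * DAYS_PER_MONTH),
    6: (6 * DAYS_PER_MONTH, 9 * DAYS_PER_MONTH),
    12: (9 * DAYS_PER_MONTH, 15 * DAYS_PER_MONTH),
    18: (15 * DAYS_PER_MONTH, 20 * DAYS_PER_MONTH),  # upper inclusive
}


def assign_age_category(age_days) -> int | None:
    """Map an age in days to one of the six age categories (nominal month).

    Bins follow infant microbiome developmental stages: 1 month (0-6 weeks),
    2 months (7 weeks to <3 months), 3 months (3-6 months), 6 months
    (6-9 months), 12 months (9-15 months), 18 months (15-20 months), with a
    month of 30.4375 days.  Lower bounds are inclusive and upper bounds
    exclusive, except day 42 which belongs to "1 month" and the 20-month cap
    which is inclusive.  Ages beyond 20 months return ``None`` (sample is
    out of the study range and excluded downstream).
    """
    if not isinstance(age_days, numbers.Real) or not np.isfinite(age_days):
        raise ValueError(f"age_days must be a finite number, got {age_days!r}")
    if age_days < 0:
        raise ValueError(f"negative age_days: {age_days}")
    d = float(age_days)
    if d <= 6 * DAYS_PER_WEEK:
        return 1
    for cat in (2, 3, 6, 12):
        lo, hi = _AGE_BIN_EDGES[cat]
        if d < hi:
            return cat
    if d <= 20 * DAYS_PER_MONTH:
        return 18
    return None


# -- metadata ----------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame and attach derived columns.

    Checks the invariants (unique sample ids, unique (child, visit) pairs,
    non-negative ages, known categorical levels) and derives ``wash_arm``,
    ``iycf_arm``, ``age_months`` and ``age_category`` (missing where the age
    is missing or out of range).  Returns a new frame; missing optional
    fields are tolerated and left missing.
    """
    required = ["sample_id", "child_id", "age_days", "visit", "hiv_exposure", "arm"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    pair_dup = meta.duplicated(subset=["child_id", "visit"])
    if pair_dup.any():
        row = meta.loc[pair_dup].iloc[0]
        raise ValueError(
            f"duplicate (child_id, visit) pair ({row['child_id']!r}, {row['visit']!r})"
        )
    ages = meta["age_days"]
    if (ages.dropna() < 0).any():
        raise ValueError("negative age_days in metadata")
    bad_visit = ~meta["visit"].isin(VISITS)
    if bad_visit.any():
        raise ValueError(f"unknown visit label {meta.loc[bad_visit, 'visit'].iloc[0]!r}")
    bad_arm = ~meta["arm"].isin(ARMS)
    if bad_arm.any():
        raise ValueError(f"unknown arm {meta.loc[bad_arm, 'arm'].iloc[0]!r}")
    bad_hiv = ~meta["hiv_exposure"].isin(HIV_EXPOSURE_LEVELS)
    if bad_hiv.any():
        raise ValueError(
            f"unknown hiv_exposure {meta.loc[bad_hiv, 'hiv_exposure'].iloc[0]!r}"
        )
    meta["wash_arm"] = meta["arm"].isin(["WASH", "WASH_IYCF"])
    meta["iycf_arm"] = meta["arm"].isin(["IYCF", "WASH_IYCF"])
    meta["age_months"] = meta["age_days"] / DAYS_PER_MONTH
    meta["age_category"] = [
        assign_age_category(a) if pd.notna(a) else None for a in meta["age_days"]
    ]
    return meta


def load_metadata(path) -> pd.DataFrame:
    """Read a metadata CSV (see :data:`METADATA_COLUMNS`) and validate it."""
    meta = pd.read_csv(path)
    for col in ("ebf_3m", "delivery_csection"):
        if col in meta.columns:
            meta[col] = meta[col].astype("boolean")
    return validate_metadata(meta)


def epi_covariate_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the free-form epidemiological covariate columns (epi_ prefix)."""
    return [c for c in meta.columns if c.startswith("epi_")]
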