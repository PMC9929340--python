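"""Alpha diversity, Bray-Curtis distances, PCoA, PERMANOVA and permutation tests.

Alpha-diversity metrics use natural logarithms (nats) by default; the base
is configurable since conventions differ across ecology software.
Distance matrices are represented with :class:`skbio.DistanceMatrix`, and
principal-coordinates analysis delegates to scikit-bio's classical scaling.
PERMANOVA and the two-group location permutation test are implemented here
so that the permutation scheme is explicitly seeded and the p-value uses the
add-one convention p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), which can
never return zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .feature_table import FeatureTable

__all__ = [
    "shannon_index",
    "pielou_evenness",
    "richness",
    "alpha_diversity_frame",
    "bray_curtis",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "permutation_test_location",
]


def _as_composition(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D composition vector")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero composition")
    return x / total


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero p_i (nats by default)."""
    p = _as_composition(abundances)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def pielou_evenness(abundances) -> float:
    """Pielou's J = H / ln(richness); undefined (NaN, with a warning) for
    fewer than two detected taxa."""
    x = np.asarray(abundances, dtype=float)
    s = int((x > 0).sum())
    if s < 2:
        warnings.warn("Pielou evenness undefined for < 2 detected taxa")
        return float("nan")
    return shannon_index(abundances) / float(np.log(s))


def richness(abundances, detection_threshold: float = 0.0) -> int:
    """Count of features with abundance strictly above the threshold."""
    x = np.asarray(abundances, dtype=float)
    return int((x > detection_threshold).sum())


def alpha_diversity_frame(table: FeatureTable, detection_threshold: float = 0.0) -> pd.DataFrame:
    """Per-sample Shannon, Pielou evenness and richness for a table."""
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, row in table.data.iterrows():
            v = row.to_numpy()
            rows[sid] = {
                "shannon": shannon_index(v) if v.sum() > 0 else np.nan,
                "evenness": pielou_evenness(v),
                "richness": richness(v, detection_threshold),
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d(x, y) = sum|x-y| / sum(x+y) between samples."""
    df = table.data
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    condensed = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in df.index])


def pcoa(dm: DistanceMatrix, n_axes: int | None = None):
    """Classical scaling (PCoA) of a distance matrix.

    Negative eigenvalues of the double-centered Gram matrix are reported,
    not silently dropped.  ``n_axes`` beyond n-1 is clipped with a warning.
    Returns a :class:`skbio.stats.ordination.OrdinationResults`.
    """
    n = dm.shape[0]
    if n_axes is not None and n_axes > n - 1:
        warnings.warn(f"n_axes={n_axes} clipped to {n - 1}")
        n_axes = n - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dm, method="eigh", dimensions=0, warn_neg_eigval=False)
    if n_axes is not None:
        res.samples = res.samples.iloc[:, :n_axes]
    return res


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    r2 is the among-group fraction of the total sum of squared distances
    (1 - SSW/SST); p is the add-one-corrected permutation p-value.
    """

    r2: float
    f_stat: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    # Diagonal is zero, so the upper-triangle sum is half the full sum.
    n = d2.shape[0]
    sst = d2.sum() / (2 * n)
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return sst, ssw


def _pseudo_f(d2, labels, groups, n, a):
    sst, ssw = _permanova_ss(d2, labels, groups)
    ssa = sst - ssw
    denom = ssw / (n - a)
    if denom <= 0:
        return np.inf, ssa / sst if sst > 0 else 0.0
    return (ssa / (a - 1)) / denom, ssa / sst if sst > 0 else 0.0


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Single-factor PERMANOVA with seeded label permutations.

    pseudo-F = (SSA/(a-1)) / (SSW/(N-a)) from among/within sums of squared
    distances; ties between permuted and observed F count toward the
    p-value (>= comparison, conservative).
    """
    labels = np.asarray(pd.Series(list(grouping)).to_numpy())
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError("grouping length does not match distance matrix")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    a = len(groups)
    f_obs, r2 = _pseudo_f(d2, labels, groups, n, a)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_p, _ = _pseudo_f(d2, perm, groups, n, a)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(r2=float(r2), f_stat=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations)


def permutation_test_location(
    values, groups, n_permutations: int = 9999, seed: int | None = None
) -> float:
    """Two-sided permutation test for a difference in group means.

    Suited to unbalanced two-group comparisons where a t-test's assumptions
    are doubtful; p is add-one corrected and reproducible under ``seed``.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(pd.Series(list(groups)).to_numpy())
    if len(v) != len(g):
        raise ValueError("values and groups length mismatch")
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    mask = g == levels[0]
    n1 = int(mask.sum())
    if n1 == 0 or n1 == len(v):
        raise ValueError("empty group")
    t_obs = abs(v[mask].mean() - v[~mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(v))
    for _ in range(n_permutations):
        rng.shuffle(idx)
        pm = np.zeros(len(v), dtype=bool)
        pm[idx[:n1]] = True
        if abs(v[pm].mean() - v[~pm].mean()) >= t_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)
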