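"""Diversity metrics and permutation machinery against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from micromature.diversity import (
    bray_curtis,
    pcoa,
    permanova,
    permutation_test_location,
    pielou_evenness,
    richness,
    shannon_index,
)
from micromature.feature_table import FeatureTable


# -- brute-force oracles ------------------------------------------------------

def shannon_oracle(p):
    p = np.asarray(p, float)
    p = p / p.sum()
    return -sum(pi * np.log(pi) for pi in p if pi > 0)


def bray_curtis_oracle(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def exhaustive_mean_diff_p(values, groups):
    """Exact two-sided permutation p for a mean difference, enumerating all
    assignments of labels to positions."""
    v = np.asarray(values, float)
    g = np.asarray(groups)
    n1 = int((g == g[0]).sum())
    obs = abs(v[g == g[0]].mean() - v[g != g[0]].mean())
    count = total = 0
    for comb in itertools.combinations(range(len(v)), n1):
        mask = np.zeros(len(v), bool)
        mask[list(comb)] = True
        if abs(v[mask].mean() - v[~mask].mean()) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestAlpha:
    def test_single_taxon_shannon_zero(self):
        assert shannon_index([1, 0, 0]) == 0

    def test_uniform_shannon_is_log_richness(self):
        assert shannon_index([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_formula_value(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.03972, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    def test_evenness_uniform_is_one(self):
        assert pielou_evenness([0.2] * 5) == pytest.approx(1.0, abs=1e-12)

    def test_evenness_skewed_composition(self):
        # oracle: H([.97,.01,.01,.01]) / ln 4 computed by direct formula
        expected = shannon_oracle([0.97, 0.01, 0.01, 0.01]) / np.log(4)
        assert expected == pytest.approx(0.120966, abs=1e-5)
        assert pielou_evenness([0.97, 0.01, 0.01, 0.01]) == pytest.approx(expected, abs=1e-12)

    def test_evenness_single_taxon_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pielou_evenness([1.0, 0.0]))

    @pytest.mark.parametrize(
        "vec,thr,expected",
        [([0.5, 0.5, 0], 0.0, 2), ([0, 0, 0], 0.0, 0), ([0.001, 0.999], 0.01, 1)],
    )
    def test_richness_threshold_semantics(self, vec, thr, expected):
        assert richness(vec, thr) == expected

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_shannon_maximized_by_uniform(self, comp):
        k = len(comp)
        assert shannon_index(comp) <= np.log(k) + 1e-9

    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_shannon_matches_oracle(self, comp):
        assert shannon_index(comp) == pytest.approx(shannon_oracle(comp), abs=1e-10)


class TestBrayCurtis:
    def _table(self, rows):
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        return FeatureTable(df, "species")

    def test_identical_samples_zero(self):
        dm = bray_curtis(self._table([[0.2, 0.3], [0.2, 0.3]]))
        assert dm[0, 1] == 0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(self._table([[0.5, 0.0], [0.0, 0.5]]))
        assert dm[0, 1] == pytest.approx(1.0)

    def test_formula_value(self):
        dm = bray_curtis(self._table([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]))
        assert dm[0, 1] == pytest.approx(0.5)

    def test_zero_sum_sample_named(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(self._table([[0.5, 0.5], [0.0, 0.0]]))

    def test_matches_pairwise_oracle_and_bounds(self):
        rng = np.random.default_rng(4)
        rows = rng.dirichlet(np.ones(6), size=5) * 0.9
        dm = bray_curtis(self._table(list(rows)))
        for i in range(5):
            assert dm[i, i] == 0
            for j in range(i + 1, 5):
                assert dm[i, j] == pytest.approx(bray_curtis_oracle(rows[i], rows[j]))
                assert 0 <= dm[i, j] <= 1
                assert dm[i, j] == dm[j, i]


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        res = pcoa(dm)
        pos = sorted(e for e in res.eigvals if e > 1e-9)
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-6)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert np.allclose(res.samples.iloc[0], res.samples.iloc[1], atol=1e-8)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        d_in = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d_in, ids=[str(i) for i in range(6)]))
        coords = res.samples.to_numpy()
        d_out = squareform(pdist(coords))
        assert np.allclose(d_in, d_out, atol=1e-8)

    def test_axes_clipped_with_warning(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab"))
        with pytest.warns(UserWarning, match="clipped"):
            res = pcoa(dm, n_axes=5)
        assert res.samples.shape[1] <= 1


def _clustered_dm(n_per=6, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 0.1, (n_per, 2)), rng.normal(sep, 0.1, (n_per, 2))])
    ids = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids), ["a"] * n_per + ["b"] * n_per


class TestPermanova:
    def test_separated_clusters(self):
        # 10 per cluster: the chance a permutation re-creates the partition
        # (tying the observed F) is ~2/C(20,10), negligible over 199 draws
        dm, labels = _clustered_dm(n_per=10)
        res = permanova(dm, labels, n_permutations=199, seed=1)
        assert res.r2 > 0.9
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_skbio_f_statistic(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio_permanova(dm, labels, permutations=999, seed=0)
        assert mine.f_stat == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_sampled_p_near_exhaustive_enumeration(self):
        # n=6: enumerate all 720 orderings for the exact null distribution
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d2 = d**2

        def f_stat(lab):
            sst = d2.sum() / (2 * 6)
            ssw = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
            return ((sst - ssw) / 1) / (ssw / 4)

        obs = f_stat(labels)
        perms = [f_stat(np.array(p)) for p in itertools.permutations(labels)]
        p_exact = np.mean([f >= obs - 1e-12 for f in perms])

        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = permanova(dm, labels, n_permutations=4999, seed=7)
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p_value - p_exact) < 4 * mc_sd + 1e-3

    def test_r2_invariant_to_sample_order(self):
        dm, labels = _clustered_dm(seed=2)
        res1 = permanova(dm, labels, n_permutations=99, seed=0)
        order = list(range(dm.shape[0]))[::-1]
        ids2 = [dm.ids[i] for i in order]
        dm2 = DistanceMatrix(dm.data[np.ix_(order, order)], ids=ids2)
        labels2 = [labels[i] for i in order]
        res2 = permanova(dm2, labels2, n_permutations=99, seed=0)
        assert res1.r2 == pytest.approx(res2.r2, abs=1e-12)

    def test_single_group_rejected(self):
        dm, _ = _clustered_dm()
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * dm.shape[0], n_permutations=99)

    def test_seed_reproducibility(self):
        dm, labels = _clustered_dm(sep=0.5, seed=4)
        a = permanova(dm, labels, n_permutations=199, seed=42)
        b = permanova(dm, labels, n_permutations=199, seed=42)
        assert a.p_value == b.p_value


class TestPermutationLocation:
    def test_identical_multisets_p_one(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["a"] * 3 + ["b"] * 3
        assert permutation_test_location(v, g, n_permutations=999, seed=0) == 1.0

    def test_extreme_separation_matches_enumeration(self):
        v = [1, 2, 3, 101, 102, 103]
        g = ["a"] * 3 + ["b"] * 3
        p_exact = exhaustive_mean_diff_p(v, g)
        assert p_exact == pytest.approx(0.1)  # 2 extreme splits of C(6,3)=20
        p = permutation_test_location(v, g, n_permutations=9999, seed=1)
        assert abs(p - p_exact) < 0.02

    def test_label_swap_invariance(self):
        v = [1.0, 5.0, 2.0, 8.0, 0.0, 7.0]
        g1 = ["a", "b", "a", "b", "a", "b"]
        g2 = ["b", "a", "b", "a", "b", "a"]
        p1 = permutation_test_location(v, g1, n_permutations=999, seed=3)
        p2 = permutation_test_location(v, g2, n_permutations=999, seed=3)
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_location([1, 2, 3], ["a", "a", "a"], n_permutations=999)
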