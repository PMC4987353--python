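import itertools

import numpy as np
import pandas as pd
import pytest
import skbio.diversity
from scipy.spatial.distance import pdist, squareform

from gutenv.diversity import (
    DistanceMatrix,
    anosim,
    distance_matrix,
    faith_pd,
    observed_otus,
    pcoa,
    unifrac,
)
from gutenv.model import CountTable

from .conftest import random_table, random_tree, tree_from_newick
from .oracles import brute_anosim_exact_p, brute_anosim_r, brute_faith_pd, brute_unifrac

IDX4 = pd.Index(["A", "B", "C", "D"])


def series(vals):
    return pd.Series(vals, index=IDX4)


class TestObservedOtus:
    @pytest.mark.parametrize("col,expected", [([3, 0, 1], 2), ([0, 0, 0], 0)])
    def test_examples(self, col, expected):
        assert observed_otus(np.array(col)) == expected

    def test_counts_binary_column(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=50)
        assert observed_otus(col) == col.sum()


class TestFaithPD:
    def test_whole_tree(self, balanced_tree):
        assert faith_pd(series([1, 1, 1, 1]), balanced_tree) == pytest.approx(6.0)

    def test_single_tip_includes_root_path(self, balanced_tree):
        assert faith_pd(series([1, 0, 0, 0]), balanced_tree) == pytest.approx(2.0)

    def test_empty_sample(self, balanced_tree):
        assert faith_pd(series([0, 0, 0, 0]), balanced_tree) == 0.0

    def test_present_otu_missing_from_tree_errors(self, balanced_tree):
        s = pd.Series([1, 1], index=["A", "X"])
        with pytest.raises(KeyError, match="X"):
            faith_pd(s, balanced_tree)

    def test_monotone_in_added_taxa(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree = random_tree(rng, 8)
            present = np.zeros(8)
            last = 0.0
            for i in rng.permutation(8):
                present[i] = 1
                pd_val = faith_pd(pd.Series(present, index=[f"T{k}" for k in range(8)]),
                                  tree)
                assert pd_val >= last - 1e-12
                last = pd_val


class TestUnifrac:
    def test_identical_columns_zero_in_every_variant(self, balanced_tree):
        s = series([2, 1, 0, 3])
        for w, nrm in [(False, True), (True, True), (True, False)]:
            assert unifrac(s, s, balanced_tree, weighted=w, normalized=nrm) == 0.0

    def test_disjoint_clades_distance_one(self, balanced_tree):
        assert unifrac(series([1, 0, 0, 0]), series([0, 0, 1, 0]),
                       balanced_tree) == pytest.approx(1.0)

    def test_nested_communities(self, balanced_tree):
        # unique branch B (length 1) over union branches {A, B, AB} (length 3)
        d = unifrac(series([1, 1, 0, 0]), series([1, 0, 0, 0]), balanced_tree)
        assert d == pytest.approx(1 / 3)

    def test_both_empty_errors(self, balanced_tree):
        with pytest.raises(ValueError):
            unifrac(series([0, 0, 0, 0]), series([0, 0, 0, 0]), balanced_tree)

    def test_weighted_normalized_bounds_and_disjoint_subtrees(self, balanced_tree):
        d = unifrac(series([3, 1, 0, 0]), series([0, 0, 2, 5]), balanced_tree,
                    weighted=True, normalized=True)
        assert d == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            tree = random_tree(rng, 6)
            idx = pd.Index([f"T{i}" for i in range(6)])
            s1 = pd.Series(rng.integers(0, 9, 6), index=idx)
            s2 = pd.Series(rng.integers(0, 9, 6), index=idx)
            if s1.sum() == 0 or s2.sum() == 0:
                continue
            d = unifrac(s1, s2, tree, weighted=True, normalized=True)
            assert -1e-12 <= d <= 1 + 1e-12


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self, balanced_tree):
        table = CountTable(pd.DataFrame({"s1": [2, 1, 0, 1], "s2": [2, 1, 0, 1]},
                                        index=IDX4))
        dm = distance_matrix(table, balanced_tree, "weighted_unifrac")
        np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)

    def test_matches_pairwise_recomputation(self, balanced_tree, toy_table):
        dm = distance_matrix(toy_table, balanced_tree, "unweighted_unifrac")
        for i, j in itertools.combinations(range(3), 2):
            si = toy_table.data.iloc[:, i]
            sj = toy_table.data.iloc[:, j]
            assert dm.d[i, j] == pytest.approx(unifrac(si, sj, balanced_tree))

    def test_sample_permutation_permutes_matrix(self, balanced_tree, toy_table):
        dm = distance_matrix(toy_table, balanced_tree, "weighted_unifrac")
        perm = ["s3", "s1", "s2"]
        dm2 = distance_matrix(toy_table.select_samples(perm), balanced_tree,
                              "weighted_unifrac")
        order = [toy_table.sample_ids.index(s) for s in perm]
        np.testing.assert_allclose(dm2.d, dm.d[np.ix_(order, order)], atol=1e-12)

    def test_unweighted_triangle_inequality_on_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            tree = random_tree(rng, 6)
            table = random_table(rng, 6, 4)
            d = distance_matrix(table, tree, "unweighted_unifrac").d
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestAgainstScikitBio:
    """Cross-check against the independent scikit-bio implementations."""

    def _skbio_beta(self, metric, table, tree, **kw):
        args = dict(ids=table.sample_ids, tree=tree.tree, **kw)
        try:
            return skbio.diversity.beta_diversity(
                metric, table.counts.T, taxa=table.otu_ids, **args)
        except TypeError:
            return skbio.diversity.beta_diversity(
                metric, table.counts.T, otu_ids=table.otu_ids, **args)

    def test_unifrac_variants(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            tree = random_tree(rng, 6)
            table = random_table(rng, 6, 4)
            for metric, kw in [("unweighted_unifrac", {}),
                               ("weighted_unifrac", {"normalized": True})]:
                ref = self._skbio_beta(metric, table, tree, **kw)
                mine = distance_matrix(table, tree, metric)
                np.testing.assert_allclose(mine.d, ref.data, atol=1e-9)

    def test_faith_pd(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            tree = random_tree(rng, 6)
            table = random_table(rng, 6, 3)
            try:
                ref = skbio.diversity.alpha_diversity(
                    "faith_pd", table.counts.T, ids=table.sample_ids,
                    taxa=table.otu_ids, tree=tree.tree)
            except TypeError:
                ref = skbio.diversity.alpha_diversity(
                    "faith_pd", table.counts.T, ids=table.sample_ids,
                    otu_ids=table.otu_ids, tree=tree.tree)
            for s, expected in zip(table.sample_ids, ref):
                assert faith_pd(table.data[s], tree) == pytest.approx(
                    expected, abs=1e-9)


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-9)
        coords = res.coordinates.to_numpy()
        d = squareform(pdist(coords))
        np.testing.assert_allclose(d, dm.d, atol=1e-9)

    def test_points_on_a_line_reconstructed(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert (res.eigenvalues > 1e-9).sum() == 1
        recon = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(list("abc"), d))
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-9)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        recon = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, d, atol=1e-9)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], d)

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, 8, 5)
        tree = random_tree(rng, 8)
        dm = distance_matrix(table, tree, "weighted_unifrac")
        res = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, dm.sample_ids))
        np.testing.assert_allclose(
            res.eigenvalues[: len(ref.eigvals)][res.eigenvalues[: len(ref.eigvals)] > 1e-9],
            np.asarray(ref.eigvals)[np.asarray(ref.eigvals) > 1e-9],
            atol=1e-9,
        )


class TestAnosim:
    @staticmethod
    def separated_dm():
        # two groups, every between distance > every within distance
        d = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.7, 0.9],
            [0.9, 0.7, 0.0, 0.2],
            [0.8, 0.9, 0.2, 0.0],
        ])
        return DistanceMatrix(list("abcd"), d)

    def test_maximal_separation_gives_r_one(self):
        res = anosim(self.separated_dm(), ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_p_floor_respected(self):
        res = anosim(self.separated_dm(), ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.p_value >= 1 / (res.n_permutations + 1)

    def test_constant_matrix_r_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = anosim(DistanceMatrix(list("abcd"), d * 0.5),
                     ["g1", "g1", "g2", "g2"], 99, seed=0)
        assert res.R == 0.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(self.separated_dm(), ["g1", "g1", "g1", "g2"], 99, seed=0)

    def test_null_mean_r_near_zero(self):
        """With labels independent of distances, E[R] = 0."""
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(300):
            d = squareform(rng.uniform(0.1, 1.0, size=15))
            labels = rng.permutation(["a", "a", "a", "b", "b", "b"])
            rs.append(anosim(DistanceMatrix(list("uvwxyz"), d), labels,
                             1, seed=0).R)
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) < 3 * se

    def test_exact_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = squareform(rng.uniform(0.1, 1.0, size=6))
            labels = ["g1", "g1", "g2", "g2"]
            res = anosim(DistanceMatrix(list("abcd"), d), labels, "exact")
            assert res.R == pytest.approx(brute_anosim_r(d, labels), abs=1e-12)
            assert res.p_value == pytest.approx(
                brute_anosim_exact_p(d, labels), abs=1e-12)

    def test_matches_skbio_r(self):
        rng = np.random.default_rng(10)
        d = squareform(rng.uniform(0.1, 1.0, size=28))
        ids = [f"s{i}" for i in range(8)]
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        res = anosim(DistanceMatrix(ids, d), labels, 99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d, ids), labels, permutations=0)
        assert res.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_same_seed_same_p(self):
        dm = self.separated_dm()
        a = anosim(dm, ["g1", "g1", "g2", "g2"], 199, seed=7)
        b = anosim(dm, ["g1", "g1", "g2", "g2"], 199, seed=7)
        assert (a.R, a.p_value) == (b.R, b.p_value)


class TestBruteForceOracles:
    """Implementation vs. literal branch/rank enumeration on random data."""

    def test_unifrac_and_pd_agree_with_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_tips = int(rng.integers(3, 7))
            tree = random_tree(rng, n_tips)
            table = random_table(rng, n_tips, 3)
            c1 = dict(zip(table.otu_ids, table.counts[:, 0]))
            c2 = dict(zip(table.otu_ids, table.counts[:, 1]))
            s1, s2 = table.data.iloc[:, 0], table.data.iloc[:, 1]
            assert unifrac(s1, s2, tree) == pytest.approx(
                brute_unifrac(tree.tree, c1, c2, weighted=False), abs=1e-9)
            assert unifrac(s1, s2, tree, weighted=True) == pytest.approx(
                brute_unifrac(tree.tree, c1, c2, weighted=True), abs=1e-9)
            present = {o for o, c in c1.items() if c > 0}
            assert faith_pd(s1, tree) == pytest.approx(
                brute_faith_pd(tree.tree, present), abs=1e-9)
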