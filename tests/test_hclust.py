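"""Clustering variants, lifetime cuts, validation, selection, PCA, Newick."""

import numpy as np
import pandas as pd
import pytest

from somscape import hclust


def _matrix(columns: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(columns)


def _blobs(rng, n_per=10, n_features=30, sep=20.0):
    """Two well-separated sample blobs (distinct profiles) as matrix columns."""
    va = rng.normal(0.0, sep, size=n_features)
    vb = rng.normal(0.0, sep, size=n_features)
    a = va[:, None] + rng.normal(0.0, 1.0, size=(n_features, n_per))
    b = vb[:, None] + rng.normal(0.0, 1.0, size=(n_features, n_per))
    cols = np.hstack([a, b])
    names = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    truth = np.array([0] * n_per + [1] * n_per)
    return pd.DataFrame(cols, columns=names), truth


class TestPairwiseDistance:
    def test_identical_vectors_zero_under_all_metrics(self):
        m = _matrix({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        for metric in hclust.METRICS:
            d = hclust.pairwise_distance(m, metric)
            assert d.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_pythagorean(self):
        m = _matrix({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        d = hclust.pairwise_distance(m, "euclidean")
        assert d.values[0] == pytest.approx(5.0)

    def test_pearson_anticorrelation_is_two(self):
        m = _matrix({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        d = hclust.pairwise_distance(m, "pearson")
        assert d.values[0] == pytest.approx(2.0)

    def test_constant_vector_rejected_by_name(self):
        m = _matrix({"flatline": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flatline"):
            hclust.pairwise_distance(m, "pearson")
        m0 = _matrix({"zerovec": [0.0, 0.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="zerovec"):
            hclust.pairwise_distance(m0, "cosine")


class TestLinkageTree:
    def test_single_link_hand_case(self):
        m = _matrix({"a": [0.0], "b": [1.0], "c": [10.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        np.testing.assert_allclose(sorted(tree.heights), [1.0, 9.0])

    def test_complete_link_hand_case(self):
        m = _matrix({"a": [0.0], "b": [1.0], "c": [10.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "complete")
        np.testing.assert_allclose(sorted(tree.heights), [1.0, 10.0])

    def test_two_items_single_merge(self):
        m = _matrix({"a": [0.0], "b": [7.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "average")
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(7.0)


def lifetime_oracle(heights: np.ndarray) -> int:
    """Brute force: try every cut level, return k of the longest-lived partition."""
    heights = np.sort(heights)
    n = len(heights) + 1
    best_k, best_life = 1, 0.0
    for i in range(len(heights) - 1):
        life = heights[i + 1] - heights[i]
        if life > best_life:
            best_life = life
            best_k = n - (i + 1)
    return best_k


class TestLifetimeCut:
    def test_max_gap_two_clusters(self):
        m = _matrix({"a": [0.0], "b": [1.0], "c": [2.1], "d": [11.0]})
        # single-link heights: 1.0, 1.1, 8.9 -> largest gap before the last merge
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        part = hclust.lifetime_cut(tree)
        assert part.k == 2
        assert part.labels["a"] == part.labels["b"] == part.labels["c"]
        assert part.labels["d"] != part.labels["a"]

    def test_equal_heights_single_cluster(self):
        m = _matrix({"a": [0.0, 0.0], "b": [1.0, 0.0], "c": [0.5, np.sqrt(3) / 2]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        assert hclust.lifetime_cut(tree).k == 1

    def test_two_items_one_cluster(self):
        m = _matrix({"a": [0.0], "b": [1.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        assert hclust.lifetime_cut(tree).k == 1

    def test_planted_blobs_pure_two_clusters(self, rng):
        data, truth = _blobs(rng)
        tree = hclust.linkage_tree(hclust.pairwise_distance(data, "euclidean"),
                                   "average")
        part = hclust.lifetime_cut(tree)
        assert part.k == 2
        labels = part.labels.to_numpy()
        assert len(set(zip(labels, truth))) == 2  # one-to-one blob/cluster map

    def test_matches_bruteforce_on_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            data = pd.DataFrame(rng.normal(size=(5, n)),
                                columns=[f"s{i}" for i in range(n)])
            tree = hclust.linkage_tree(
                hclust.pairwise_distance(data, "euclidean"), "average")
            assert hclust.lifetime_cut(tree).k == lifetime_oracle(tree.heights)


class TestValidation:
    def test_distant_blobs_high_silhouette(self, rng):
        data, truth = _blobs(rng)
        labels = pd.Series(truth + 1, index=data.columns)
        part = hclust.Partition(labels, 2, "truth")
        scores = hclust.validate_partition(data, part, "euclidean")
        assert scores.silhouette > 0.9
        assert scores.calinski_harabasz > 100

    def test_random_labels_near_zero_silhouette(self, rng):
        data = pd.DataFrame(rng.normal(size=(20, 30)),
                            columns=[f"s{i}" for i in range(30)])
        sils = []
        for _ in range(20):
            labels = pd.Series(rng.integers(1, 3, size=30), index=data.columns)
            if labels.nunique() < 2:
                continue
            part = hclust.Partition(labels, int(labels.nunique()), "rand")
            sils.append(hclust.validate_partition(data, part).silhouette)
        assert abs(np.mean(sils)) < 0.15

    def test_degenerate_k_undefined(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 4)),
                            columns=[f"s{i}" for i in range(4)])
        singletons = hclust.Partition(
            pd.Series(range(1, 5), index=data.columns), 4, "x")
        assert not hclust.validate_partition(data, singletons).defined
        onecluster = hclust.Partition(
            pd.Series(1, index=data.columns), 1, "x")
        assert not hclust.validate_partition(data, onecluster).defined


class TestRunAllVariants:
    def test_emits_nine_records_one_selected(self, paper_cond):
        results = hclust.run_all_variants(paper_cond)
        assert len(results) == 9
        combos = {(r.metric, r.linkage) for r in results}
        assert len(combos) == 9
        assert sum(r.selected for r in results) == 1

    def test_planted_blobs_recovered_by_all_variants(self, rng):
        data, truth = _blobs(rng, n_per=8, sep=50.0)
        results = hclust.run_all_variants(data)
        for r in results:
            assert r.partition.k == 2, (r.metric, r.linkage)
        sel = hclust.selected_variant(results)
        assert sel.partition.k == 2

    def test_rank_sum_disagreement_rule(self):
        # partition 0 wins silhouette, partition 2 wins CH; 1 is second on both
        sil = np.array([0.9, 0.8, 0.1])
        ch = np.array([10.0, 150.0, 200.0])
        # rank sums: 0 -> 1+3=4, 1 -> 2+2=4, 2 -> 3+1=4; silhouette breaks the tie
        assert hclust.rank_sum_select(sil, ch) == 0
        sil = np.array([0.9, 0.85, 0.1])
        ch = np.array([10.0, 200.0, 150.0])
        # rank sums: 4, 3, 5 -> partition 1 wins outright
        assert hclust.rank_sum_select(sil, ch) == 1

    def test_sample_permutation_invariance(self, rng, paper_cond):
        base = hclust.run_all_variants(paper_cond)
        perm = paper_cond.iloc[:, rng.permutation(paper_cond.shape[1])]
        shuffled = hclust.run_all_variants(perm)
        for r0, r1 in zip(base, shuffled):
            l0 = r0.partition.labels
            l1 = r1.partition.labels.loc[l0.index]
            assert r0.partition.k == r1.partition.k
            # identical up to label renaming
            assert len(set(zip(l0, l1))) == r0.partition.k

    def test_monotone_rescaling_invariance_for_correlation_metrics(self, paper_cond):
        results = hclust.run_all_variants(paper_cond)
        scaled = hclust.run_all_variants(paper_cond * 3.7)
        for r0, r1 in zip(results, scaled):
            if r0.metric in ("cosine", "pearson"):
                pd.testing.assert_series_equal(r0.partition.labels,
                                               r1.partition.labels)


class TestPCA:
    def test_rank_one_data(self):
        gene = np.array([1.0, -1.0, 2.0, -2.0])
        data = pd.DataFrame(np.outer(np.arange(1, 6), gene).T,
                            columns=[f"s{i}" for i in range(5)])
        _, frac = hclust.pca_scores(data)
        assert frac[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, paper_cond):
        _, frac = hclust.pca_scores(paper_cond)
        assert np.sum(frac) == pytest.approx(1.0)

    def test_scores_orthogonal_and_reconstruction(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 8)),
                            columns=[f"s{i}" for i in range(8)])
        centred = data.sub(data.mean(axis=1), axis=0)
        scores, _ = hclust.pca_scores(centred)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        x = centred.to_numpy().T
        x = x - x.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        np.testing.assert_allclose((u * s) @ vt, x, atol=1e-8)

    def test_isotropic_noise_flat_spectrum(self, rng):
        data = pd.DataFrame(rng.normal(size=(2000, 10)),
                            columns=[f"s{i}" for i in range(10)])
        _, frac = hclust.pca_scores(data)
        # column centering removes one dimension; compare within the rest
        assert frac[0] / frac[-2] < 2.0


class TestNewick:
    def test_two_leaf_tree(self):
        m = _matrix({"A": [0.0], "B": [3.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        assert hclust.tree_to_newick(tree) == "(A:3,B:3);"

    def test_three_leaf_hand_case(self):
        m = _matrix({"a": [0.0], "b": [1.0], "c": [10.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        # (a,b) at height 1, joined with c at height 9
        assert hclust.tree_to_newick(tree) == "(c:9,(a:1,b:1):8);"

    def test_round_trip_through_reader(self, paper_cond):
        import dendropy

        tree = hclust.linkage_tree(
            hclust.pairwise_distance(paper_cond, "euclidean"), "average")
        text = hclust.tree_to_newick(tree)
        read = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        assert {t.label for t in read.taxon_namespace} == set(tree.item_ids)
        # ultrametric: every leaf at the same depth (root height)
        depths = [leaf.distance_from_root() for leaf in read.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-6

    def test_reserved_characters_quoted(self):
        m = _matrix({"a b": [0.0], "c(d)": [3.0]})
        tree = hclust.linkage_tree(hclust.pairwise_distance(m, "euclidean"), "single")
        text = hclust.tree_to_newick(tree)
        assert "'a b'" in text and "'c(d)'" in text
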