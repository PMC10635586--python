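"""Spearman profiles, UPGMA agglomeration, cluster formation, Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import rpqcluster as rc
from rpqcluster.symptom_clustering import Merge, MergeTree


def brute_force_upgma(d):
    """Independent O(n^3) UPGMA: recompute every cross-pair average from the
    original leaf distances at every step (no Lance-Williams update)."""
    n = d.shape[0]
    groups = [(i,) for i in range(n)]
    merges = []
    while len(groups) > 1:
        best = None
        for a, b in itertools.combinations(groups, 2):
            avg = np.mean([d[i, j] for i in a for j in b])
            lo, hi = sorted((min(a), min(b)))
            key = (avg, lo, hi)
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((tuple(sorted(min(a, b))), tuple(sorted(max(a, b))), best[0][0]))
        groups = [g for g in groups if g not in (a, b)]
        groups.append(tuple(sorted(a + b)))
    return merges


def random_distance_matrix(rng, n):
    x = rng.random((n, 3))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    return d


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, rng):
        scores = rng.integers(0, 5, size=(30, 16))
        corr = rc.spearman_matrix(scores)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_perfect_anti_monotone(self):
        x = np.array([0, 2, 3, 4])
        y = np.array([4, 3, 2, 0])
        scores = np.column_stack([x, y] + [np.arange(4)] * 14)
        corr = rc.spearman_matrix(scores)
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_equals_pearson_on_midranks(self):
        x = np.array([2, 0, 4, 2])
        y = np.array([0, 2, 3, 3])
        scores = np.column_stack([x, y] + [[1, 3, 0, 2]] * 14)
        corr = rc.spearman_matrix(scores)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert corr.values[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_random_matrix_equals_midrank_pearson(self, rng):
        scores = rng.integers(0, 5, size=(40, 16))
        corr = rc.spearman_matrix(scores)
        ranks = np.apply_along_axis(stats.rankdata, 0, scores.astype(float))
        oracle = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(corr.values, oracle, atol=1e-10)

    def test_constant_column_warns_and_zeroes(self, caplog):
        scores = np.column_stack(
            [np.zeros(20, dtype=int)] + [np.arange(20) % 5] * 15
        )
        with caplog.at_level("WARNING", logger="rpqcluster"):
            corr = rc.spearman_matrix(scores)
        assert "constant" in caplog.text
        assert (corr.values[0, 1:] == 0).all() and corr.values[0, 0] == 1.0

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rc.spearman_matrix(np.zeros((2, 16)))


class TestProfileDistances:
    def test_identical_rows_have_zero_distance(self):
        values = np.ones((16, 16)) * 0.5
        np.fill_diagonal(values, 1.0)
        corr = rc.CorrelationMatrix(values, rc.RPQ_ITEMS, 10)
        d = rc.profile_distances(corr)
        # all off-diagonal profiles differ only in the diagonal positions
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(np.sqrt(2 * 0.25))

    def test_three_item_hand_value(self):
        values = np.eye(3)
        corr = rc.CorrelationMatrix(values, ("a", "b", "c"), 10)
        d = rc.profile_distances(corr)
        assert d[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_metric_laws_on_random_valid_matrices(self, rng):
        for _ in range(10):
            raw = rng.uniform(-1, 1, size=(16, 16))
            values = np.clip((raw + raw.T) / 2, -0.99, 0.99)
            np.fill_diagonal(values, 1.0)
            corr = rc.CorrelationMatrix(values, rc.RPQ_ITEMS, 10)
            d = rc.profile_distances(corr)
            np.testing.assert_allclose(d, d.T, atol=1e-12)
            for i, j, k in itertools.combinations(range(16), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestAverageLinkage:
    def test_two_leaves(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = rc.average_linkage(d, ("a", "b"))
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(3.0)

    def test_four_leaf_hand_agglomeration(self):
        # d(A,B)=1, d(C,D)=2, all cross distances 10
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 2.0
        tree = rc.average_linkage(d, ("A", "B", "C", "D"))
        assert [m.height for m in tree.merges] == pytest.approx([1.0, 2.0, 10.0])
        assert tree.merges[0].members == (0, 1)
        assert tree.merges[1].members == (2, 3)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            d = random_distance_matrix(rng, 8)
            labels = tuple("abcdefgh")
            tree = rc.average_linkage(d, labels)
            oracle = brute_force_upgma(d)
            for merge, (ol, orr, oh) in zip(tree.merges, oracle):
                assert set(merge.left) == set(ol) and set(merge.right) == set(orr)
                assert merge.height == pytest.approx(oh, abs=1e-9)

    def test_heights_monotone_on_random_instances(self, rng):
        for _ in range(20):
            d = random_distance_matrix(rng, 12)
            tree = rc.average_linkage(d, tuple(f"l{i}" for i in range(12)))
            heights = [m.height for m in tree.merges]
            assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_deterministic_tie_break(self):
        # three equidistant leaves: (0,1) must merge first
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        tree = rc.average_linkage(d, ("a", "b", "c"))
        assert tree.merges[0].members == (0, 1)

    def test_nan_distance_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            rc.average_linkage(d, ("a", "b", "c"))

    def test_matches_reference_row_clustering_on_synthetic_cohort(self, default_cohort):
        """Cross-check against SciPy average linkage (the engine behind the
        reference clustermap row dendrogram) on one fixed cohort."""
        _, prolonged = rc.split_by_duration(default_cohort)
        scored = rc.score_cohort(prolonged)
        corr = rc.spearman_matrix(scored.corrected)
        dist = rc.profile_distances(corr)
        tree = rc.average_linkage(dist)
        Z = linkage(squareform(dist, checks=False), method="average")
        np.testing.assert_allclose(tree.to_linkage()[:, 2], Z[:, 2], atol=1e-9)
        # identical partitions at every cut cardinality
        ours = tree.to_linkage()
        for k in (2, 3, 5, 8):
            a = fcluster(ours, k, criterion="maxclust")
            b = fcluster(Z, k, criterion="maxclust")
            assert len(np.unique(a)) == len(np.unique(b))
            # same partition up to label permutation
            from sklearn.metrics import adjusted_rand_score

            assert adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestClusterFormation:
    def _tree(self, merges, labels):
        return MergeTree(
            merges=[Merge(left=l, right=r, height=h) for l, r, h in merges],
            labels=labels,
        )

    def test_two_pairs_form_two_clusters(self):
        tree = self._tree(
            [((0,), (1,), 1.0), ((2,), (3,), 2.0), ((0, 1), (2, 3), 5.0)],
            ("A", "B", "C", "D"),
        )
        cs = rc.form_clusters(tree)
        assert cs.formation_level == 2
        assert sorted(map(sorted, cs.clusters.values())) == [["A", "B"], ["C", "D"]]

    def test_chain_with_late_singleton_gives_one_cluster(self):
        tree = self._tree(
            [((0,), (1,), 1.0), ((0, 1), (2,), 2.0), ((0, 1, 2), (3,), 3.0)],
            ("A", "B", "C", "D"),
        )
        cs = rc.form_clusters(tree)
        assert cs.formation_level == 3
        assert cs.n_clusters == 1

    def test_two_leaf_tree_one_cluster(self):
        tree = self._tree([((0,), (1,), 1.0)], ("A", "B"))
        assert rc.form_clusters(tree).n_clusters == 1

    def test_groups_cover_items_with_size_at_least_two(self, default_cohort):
        _, prolonged = rc.split_by_duration(default_cohort)
        scored = rc.score_cohort(prolonged)
        _, _, clusters = rc.cluster_symptoms(scored.corrected)
        members = [m for g in clusters.clusters.values() for m in g]
        assert sorted(members) == sorted(rc.RPQ_ITEMS)
        assert min(len(g) for g in clusters.clusters.values()) >= 2

    def test_supercluster_annotation_joins_formed_clusters(self):
        tree = self._tree(
            [((0,), (1,), 1.0), ((2,), (3,), 2.0), ((0, 1), (2, 3), 5.0)],
            ("A", "B", "C", "D"),
        )
        cs = rc.form_clusters(tree)
        assert len(cs.superclusters) == 1
        assert set(cs.superclusters[0]) == set(cs.clusters)

    def test_small_group_logs_preliminary_warning(self, default_cohort, caplog):
        early, _ = rc.split_by_duration(default_cohort)
        scored = rc.score_cohort(early)
        with caplog.at_level("WARNING", logger="rpqcluster"):
            rc.cluster_symptoms(scored.corrected)
        assert "preliminary" in caplog.text


class TestNewick:
    def test_two_leaf_string(self):
        tree = MergeTree(
            merges=[Merge(left=(0,), right=(1,), height=2.5)], labels=("A", "B")
        )
        assert rc.to_newick(tree) == "(A:2.5,B:2.5);"

    def test_round_trip_on_random_trees(self, rng):
        for _ in range(10):
            d = random_distance_matrix(rng, 9)
            labels = tuple(f"leaf{i}" for i in range(9))
            tree = rc.average_linkage(d, labels)
            parsed = dendropy.Tree.get(data=rc.to_newick(tree), schema="newick")
            assert {t.label for t in parsed.taxon_namespace} == set(labels)
            # root-to-leaf path length equals the final merge height (ultrametric)
            root_height = tree.merges[-1].height
            for leaf in parsed.leaf_node_iter():
                assert leaf.distance_from_root() == pytest.approx(root_height, abs=1e-6)
            # pairwise leaf-to-leaf patristic distances recover merge heights
            pdm = parsed.phylogenetic_distance_matrix()
            for merge in tree.merges:
                i, j = merge.left[0], merge.right[0]
                t1 = parsed.taxon_namespace.get_taxon(labels[i])
                t2 = parsed.taxon_namespace.get_taxon(labels[j])
                assert pdm.patristic_distance(t1, t2) == pytest.approx(
                    2 * merge.height, abs=1e-6
                )

    def test_full_rpq_tree_has_16_leaves(self, default_cohort):
        _, prolonged = rc.split_by_duration(default_cohort)
        scored = rc.score_cohort(prolonged)
        _, tree, _ = rc.cluster_symptoms(scored.corrected)
        newick = rc.to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert len(parsed.leaf_nodes()) == 16


class TestPartitionAgreement:
    def test_identical_partitions(self, planted):
        assert rc.partition_agreement(planted, planted) == pytest.approx(1.0)

    def test_singletons_vs_one_block_is_zero(self):
        singletons = rc.SymptomClusterSet(
            clusters={f"s{i}": (lab,) for i, lab in enumerate(rc.RPQ_ITEMS)}
        )
        one_block = rc.SymptomClusterSet(clusters={"all": rc.RPQ_ITEMS})
        assert rc.partition_agreement(singletons, one_block) == pytest.approx(0.0)

    def test_symmetric(self, planted):
        other = rc.SymptomClusterSet(
            clusters={"a": rc.RPQ_ITEMS[:8], "b": rc.RPQ_ITEMS[8:]}
        )
        assert rc.partition_agreement(planted, other) == pytest.approx(
            rc.partition_agreement(other, planted)
        )

    def test_item_set_mismatch_rejected(self, planted):
        other = rc.SymptomClusterSet(
            clusters={"a": ("x", "y")}, item_labels=("x", "y")
        )
        with pytest.raises(ValueError, match="item set"):
            rc.partition_agreement(planted, other)
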