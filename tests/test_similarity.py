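"""PCA reduction, distance metrics, UPGMA/NJ trees and Newick export."""

import io

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from dcgr import (
    build_tree,
    cophenetic_matrix,
    distance_matrix,
    pca_reduce,
    read_newick,
    write_newick,
)
from dcgr.similarity import ReducedFeatures, SequenceDistanceMatrix


class FakeFeatures:
    def __init__(self, ids, values):
        self.sequence_ids = ids
        self.values = np.asarray(values, dtype=float)


def reduced(ids, rows):
    rows = np.asarray(rows, dtype=float)
    return ReducedFeatures(ids, rows, np.full(rows.shape[1], np.nan))


def dmat(labels, entries, metric="euclidean"):
    return SequenceDistanceMatrix(labels, np.asarray(entries, float), metric)


class TestPCA:
    def test_reduces_9x632_to_9x6(self, rng):
        X = rng.random((9, 632))
        out = pca_reduce(FakeFeatures([f"s{i}" for i in range(9)], X), 6)
        assert out.components.shape == (9, 6)
        assert len(out.explained_variance) == 6

    def test_rank_one_data_distances_preserved_by_first_component(self, rng):
        t = rng.normal(size=12)
        direction = rng.normal(size=40)
        X = np.outer(t, direction) + rng.normal(size=40)  # points on a line
        out = pca_reduce(FakeFeatures(list("abcdefghijkl"), X), 1)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(out.components), pdist(X), atol=1e-9, rtol=1e-9
        )

    def test_variance_conserved_and_nonincreasing(self, rng):
        X = rng.random((10, 7))
        out = pca_reduce(FakeFeatures([str(i) for i in range(10)], X), 7)
        ev = out.explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        total = ((X - X.mean(axis=0)) ** 2).sum() / (len(X) - 1)
        assert abs(ev.sum() - total) < 1e-9

    def test_isometry_at_full_rank(self, rng):
        X = rng.random((8, 20))
        # full rank of centered data is min(N-1, p) = 7
        out = pca_reduce(FakeFeatures([str(i) for i in range(8)], X), 7)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(out.components), pdist(X), atol=1e-9)

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.random((6, 10))
        a = pca_reduce(FakeFeatures(list("abcdef"), X), 3)
        b = pca_reduce(FakeFeatures(list("abcdef"), X.copy()), 3)
        np.testing.assert_array_equal(a.components, b.components)

    def test_component_bound_error_names_the_bound(self, rng):
        X = rng.random((4, 10))
        with pytest.raises(ValueError, match=r"\[1, 4\]"):
            pca_reduce(FakeFeatures(list("abcd"), X), 5)


class TestDistances:
    def test_euclidean_and_manhattan(self):
        r = reduced(["a", "b"], [(0, 0), (3, 4)])
        assert distance_matrix(r, "euclidean").entries[0, 1] == pytest.approx(5.0)
        assert distance_matrix(r, "manhattan").entries[0, 1] == pytest.approx(7.0)

    def test_identical_rows_distance_zero(self):
        r = reduced(["a", "b"], [(1.5, -2.0), (1.5, -2.0)])
        for metric in ("euclidean", "manhattan", "cosine"):
            assert distance_matrix(r, metric).entries[0, 1] == pytest.approx(0.0)

    def test_cosine_orthogonal_is_one(self):
        r = reduced(["a", "b"], [(1, 0), (0, 1)])
        assert distance_matrix(r, "cosine").entries[0, 1] == pytest.approx(1.0)

    def test_cosine_zero_vector_names_sequence(self):
        r = reduced(["a", "zed"], [(1, 0), (0, 0)])
        with pytest.raises(ValueError, match="zed"):
            distance_matrix(r, "cosine")

    def test_seuclidean_matches_manual_standardization(self, rng):
        X = rng.random((6, 4))
        r = reduced(list("abcdef"), X)
        got = distance_matrix(r, "seuclidean").entries
        sd = X.std(axis=0, ddof=1)
        from scipy.spatial.distance import pdist

        expected = squareform(pdist(X / sd))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_seuclidean_drops_constant_columns(self, rng):
        X = rng.random((5, 3))
        X[:, 1] = 7.0
        r = reduced(list("abcde"), X)
        with pytest.warns(UserWarning, match="zero-variance"):
            got = distance_matrix(r, "seuclidean").entries
        sd = X[:, [0, 2]].std(axis=0, ddof=1)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(got, squareform(pdist(X[:, [0, 2]] / sd)), atol=1e-12)

    def test_matrix_axioms_and_tsv_roundtrip(self, rng):
        r = reduced([f"s{i}" for i in range(5)], rng.random((5, 3)))
        dm = distance_matrix(r, "euclidean")
        assert (dm.entries >= 0).all()
        np.testing.assert_array_equal(dm.entries, dm.entries.T)
        np.testing.assert_array_equal(np.diag(dm.entries), 0.0)
        buf = io.StringIO()
        dm.write_tsv(buf)
        buf.seek(0)
        back = SequenceDistanceMatrix.read_tsv(buf)
        assert back.labels == dm.labels and back.metric == "euclidean"
        np.testing.assert_array_equal(back.entries, dm.entries)

    def test_unknown_metric_rejected(self):
        r = reduced(["a", "b"], [(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="unknown metric"):
            distance_matrix(r, "chebyshev")


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8: A,B join at height 1, C attaches at height 4
        dm = dmat(["A", "B", "C"], [[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        tree = build_tree(dm, "upgma")
        dist = {t.label: t for t in tree.taxon_namespace}
        pdm = tree.phylogenetic_distance_matrix()
        assert pdm.patristic_distance(dist["A"], dist["B"]) == pytest.approx(2.0)
        assert pdm.patristic_distance(dist["A"], dist["C"]) == pytest.approx(8.0)
        c_edge = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == "C"][0].edge
        assert c_edge.length == pytest.approx(4.0)

    def test_ultrametric_output(self, rng):
        n = 7
        X = rng.random((n, 3))
        from scipy.spatial.distance import pdist

        dm = dmat([f"s{i}" for i in range(n)], squareform(pdist(X)))
        coph = cophenetic_matrix(build_tree(dm, "upgma")).entries
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    a, b, c = sorted((coph[i, j], coph[i, k], coph[j, k]))
                    assert abs(c - b) < 1e-9  # two largest cophenetic values equal

    def test_matches_scipy_average_linkage(self, rng):
        n = 9
        from scipy.spatial.distance import pdist

        cond = pdist(rng.random((n, 4)))
        labels = [f"s{i}" for i in range(n)]
        tree = build_tree(dmat(labels, squareform(cond)), "upgma")
        coph_mine = cophenetic_matrix(tree)
        Z = linkage(cond, method="average")
        coph_scipy = squareform(cophenet(Z))
        order = np.argsort(labels)  # cophenetic_matrix sorts labels
        np.testing.assert_allclose(
            coph_mine.entries, coph_scipy[np.ix_(order, order)], atol=1e-9
        )

    def test_identical_sequences_are_siblings_at_height_zero(self):
        dm = dmat(
            ["a", "b", "c"], [[0, 0, 5], [0, 0, 5], [5, 5, 0]]
        )
        tree = build_tree(dm, "upgma")
        taxa = {t.label: t for t in tree.taxon_namespace}
        pdm = tree.phylogenetic_distance_matrix()
        assert pdm.patristic_distance(taxa["a"], taxa["b"]) == pytest.approx(0.0)
        a_leaf = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == "a"][0]
        sibling_taxa = {lf.taxon.label for lf in a_leaf.parent_node.leaf_nodes()}
        assert sibling_taxa == {"a", "b"}

    def test_two_leaf_tree(self):
        tree = build_tree(dmat(["A", "B"], [[0, 2], [2, 0]]), "upgma")
        buf = io.StringIO()
        write_newick(tree, buf)
        assert buf.getvalue().strip() == "(A:1.0,B:1.0);"


class TestNJ:
    @staticmethod
    def additive_case():
        newick = "((A:1,B:2):1,(C:3,(D:1,E:1.5):2):0.5,F:4);"
        ref = dendropy.Tree.get(data=newick, schema="newick")
        pdm = ref.phylogenetic_distance_matrix()
        taxa = sorted(ref.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return labels, d

    def test_recovers_additive_tree_path_lengths(self):
        labels, d = self.additive_case()
        tree = build_tree(dmat(labels, d), "nj")
        coph = cophenetic_matrix(tree)
        assert coph.labels == labels
        np.testing.assert_allclose(coph.entries, d, atol=1e-9)

    def test_recovers_four_leaf_topology(self):
        # tree ((A,B),(C,D)) with all internal/external branches length 1
        newick = "((A:1,B:1):1,(C:1,D:1):1);"
        ref = dendropy.Tree.get(data=newick, schema="newick")
        pdm = ref.phylogenetic_distance_matrix()
        taxa = sorted(ref.taxon_namespace, key=lambda t: t.label)
        d = np.array(
            [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
        )
        tree = build_tree(dmat([t.label for t in taxa], d), "nj")
        coph = cophenetic_matrix(tree).entries
        np.testing.assert_allclose(coph, d, atol=1e-9)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_tree(dmat(["A", "B"], [[0, 1], [1, 0]]), "nj")


class TestTreeIO:
    def test_nonfinite_distances_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            build_tree(dmat(["A", "B"], [[0, np.inf], [np.inf, 0]]), "upgma")

    def test_newick_roundtrip_preserves_patristic_distances(self, rng):
        from scipy.spatial.distance import pdist

        labels = [f"s{i}" for i in range(6)]
        dm = dmat(labels, squareform(pdist(rng.random((6, 3)))))
        tree = build_tree(dm, "upgma")
        buf = io.StringIO()
        write_newick(tree, buf)
        assert buf.getvalue().rstrip().endswith(";")
        buf.seek(0)
        back = read_newick(buf)
        np.testing.assert_allclose(
            cophenetic_matrix(back).entries, cophenetic_matrix(tree).entries, atol=1e-9
        )

    def test_labels_with_spaces_survive_roundtrip(self):
        dm = dmat(
            ["Fin whale", "Blue whale", "Opossum"],
            [[0, 1, 8], [1, 0, 8], [8, 8, 0]],
        )
        tree = build_tree(dm, "upgma")
        buf = io.StringIO()
        write_newick(tree, buf)
        buf.seek(0)
        back = read_newick(buf)
        assert {t.label for t in back.taxon_namespace} == set(dm.labels)
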