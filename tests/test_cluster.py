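import numpy as np
import pytest

import phenomine as pm


class TestUncenteredDistance:
    def test_identical_nonzero_vectors_distance_zero(self):
        d = pm.uncentered_distance(np.array([[1.0, 2, 3], [1.0, 2, 3]]))
        assert d[0] == pytest.approx(0.0)

    def test_hand_vectors(self):
        d = pm.uncentered_distance(np.array([[1.0, 2, 2], [2.0, 1, 2]]))
        assert 1 - d[0] == pytest.approx(8 / 9)

    def test_all_zero_row_named_in_error(self):
        with pytest.raises(ValueError, match="'zero'"):
            pm.uncentered_distance(
                np.array([[1.0, 1], [0.0, 0]]), row_labels=["ok", "zero"]
            )

    def test_pairwise_complete_equals_full_without_missing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(1, 0.2, size=(5, 8))
        full = pm.uncentered_distance(X)
        pc = pm.uncentered_distance(X, pairwise_complete=True)
        assert np.allclose(full, pc)

    def test_pairwise_complete_skips_missing_columns(self):
        X = np.array([[1.0, 2, np.nan], [1.0, 2, 50.0]])
        d = pm.uncentered_distance(X, pairwise_complete=True)
        assert d[0] == pytest.approx(0.0)


class TestHAC:
    def test_near_points_merge_first(self):
        X = np.array([[0.0, 0], [0.0, 1], [10.0, 10]])
        dend = pm.hac(X, ["p0", "p1", "far"])
        first = dend.node_leaf_sets()[0]
        assert first == frozenset({"p0", "p1"})

    def test_heights_monotone_rootward(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 6))
        dend = pm.hac(X, [f"r{i}" for i in range(12)])
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_zscore_sign_does_not_change_tree(self):
        rng = np.random.default_rng(6)
        import scipy.sparse as sp

        m = pm.TermDocMatrix(
            [f"t{i}" for i in range(8)],
            [f"a{j}" for j in range(40)],
            sp.csr_matrix(rng.integers(0, 2, size=(8, 40))),
            "presence",
        )
        a = pm.zscore_normalize(m, "zscore_inverted")
        b = pm.zscore_normalize(m, "zscore_conventional")
        da = pm.hac(a.values, a.row_labels)
        db = pm.hac(b.values, b.row_labels)
        assert np.allclose(da.merges, db.merges)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="two rows"):
            pm.hac(np.array([[1.0, 2]]), ["only"])


class TestBootstrapSupport:
    def test_constant_rows_bp_100_everywhere(self):
        # constant rows: every pairwise distance scales by the same factor
        # under any column resample, so every resampled tree is identical
        X = np.tile((3.0 ** np.arange(6))[:, None], (1, 40))
        dend = pm.bootstrap_support(
            X, [f"r{i}" for i in range(6)], n_boot=30, seed=0, compute_au=False
        )
        assert (dend.bp == 100.0).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(7, 25))
        labels = [f"r{i}" for i in range(7)]
        with pytest.warns(UserWarning):
            d1 = pm.bootstrap_support(X, labels, n_boot=20, seed=5)
            d2 = pm.bootstrap_support(X, labels, n_boot=20, seed=5)
        assert np.array_equal(d1.bp, d2.bp)
        assert np.array_equal(d1.au, d2.au)

    def test_column_order_invariance(self):
        # the base tree is exactly invariant to column order; BP of clearly
        # supported clusters is invariant too (the resample realizations
        # differ, but every one of them reproduces the separated structure)
        rng = np.random.default_rng(9)
        X = np.hstack([rng.normal(0, 0.1, (6, 15)), rng.normal(0, 0.1, (6, 15))])
        X[:3] += 50.0
        labels = [f"r{i}" for i in range(6)]
        perm = rng.permutation(30)
        t1 = pm.hac(X, labels)
        t2 = pm.hac(X[:, perm], labels)
        assert np.allclose(t1.merges, t2.merges)
        d1 = pm.bootstrap_support(X, labels, n_boot=25, seed=3, compute_au=False)
        d2 = pm.bootstrap_support(X[:, perm], labels, n_boot=25, seed=3, compute_au=False)
        sets = d1.node_leaf_sets()
        for group in (frozenset(labels[:3]), frozenset(labels[3:])):
            i1 = sets.index(group)
            i2 = d2.node_leaf_sets().index(group)
            assert d1.bp[i1] == 100.0 == d2.bp[i2]

    def test_support_ranges(self):
        rng = np.random.default_rng(10)
        X = np.hstack([rng.normal(0, 1, (6, 20)), rng.normal(5, 1, (6, 20))])
        with pytest.warns(UserWarning):
            dend = pm.bootstrap_support(X, [f"r{i}" for i in range(6)], n_boot=20, seed=1)
        assert ((dend.bp >= 0) & (dend.bp <= 100)).all()
        assert ((dend.au >= 0) & (dend.au <= 100)).all()

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            pm.bootstrap_support(np.eye(3), ["a", "b", "c"], n_boot=1)


class TestEmbedding:
    def test_two_blobs_linearly_separable(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (30, 10)), rng.normal(8, 1, (30, 10))])
        coords = pm.tsne_embed(X, perplexity=9, n_iter=500, seed=0)
        labels = [0] * 30 + [1] * 30
        assert silhouette_score(coords, labels) > 0.5

    def test_same_seed_same_coordinates(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 5))
        a = pm.tsne_embed(X, perplexity=5, n_iter=300, seed=7)
        b = pm.tsne_embed(X, perplexity=5, n_iter=300, seed=7)
        assert np.array_equal(a, b)

    def test_perplexity_must_be_below_n(self):
        with pytest.raises(ValueError, match="perplexity"):
            pm.tsne_embed(np.eye(5), perplexity=5)

    def test_kmeans_partitions_blobs_exactly(self):
        rng = np.random.default_rng(14)
        coords = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        labels = pm.kmeans_clusters(coords, k=2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_kmeans_degenerate_ks(self):
        rng = np.random.default_rng(15)
        coords = rng.normal(size=(6, 2))
        assert set(pm.kmeans_clusters(coords, k=1, seed=0)) == {1}
        assert sorted(pm.kmeans_clusters(coords, k=6, seed=0)) == [1, 2, 3, 4, 5, 6]
        with pytest.raises(ValueError, match="exceeds"):
            pm.kmeans_clusters(coords, k=7)


class TestNewick:
    def test_two_leaf_tree(self):
        X = np.array([[0.0, 0], [3.0, 4]])
        dend = pm.hac(X, ["A", "B"])
        assert pm.to_newick(dend) == "(A:5,B:5);"

    def test_round_trip_preserves_topology_and_heights(self):
        import dendropy

        rng = np.random.default_rng(16)
        X = rng.normal(size=(8, 5))
        labels = [f"leaf {i}" for i in range(8)]
        dend = pm.hac(X, labels)
        tree = dendropy.Tree.get(data=pm.to_newick(dend), schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(labels)
        # root-to-leaf path length equals the root merge height for every leaf
        root_h = dend.heights[-1]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h, rel=1e-6)

    def test_three_leaves_one_support_label(self):
        X = np.array([[0.0], [1.0], [10.0]])
        dend = pm.bootstrap_support(X, ["A", "B", "C"], n_boot=10, seed=0, compute_au=False)
        nwk = pm.to_newick(dend)
        # two internal nodes (one plus root), each carries a BP label
        assert nwk.count("|") == 0  # BP-only labels have no separator
        import re

        assert len(re.findall(r"\)\d+", nwk)) == 2

    def test_cut_clusters_counts(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(9, 0.1, (4, 3))])
        dend = pm.hac(X, [f"r{i}" for i in range(8)])
        assign = pm.cut_clusters(dend, 2)
        assert len(set(assign.values())) == 2
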