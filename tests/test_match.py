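"""Pearson matching, distance matrices, clustering, Newick export."""

import numpy as np
import pytest
import skbio

import ramanmatch as rm
from ramanmatch.match import (
    AxisError,
    DegenerateVectorError,
    DistanceMatrix,
    pairwise_pearson,
)


def brute_force_r(a, b):
    """Textbook definition: covariance over the product of sample sds."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    cov = np.sum((a - a.mean()) * (b - b.mean())) / (n - 1)
    return cov / (a.std(ddof=1) * b.std(ddof=1))


class TestPearsonR:
    def test_self_and_negation(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert rm.pearson_r(v, v) == pytest.approx(1.0)
        assert rm.pearson_r(v, -v) == pytest.approx(-1.0)

    def test_permuted_triple(self):
        # independent hand computation: cov=0.5, unit sds -> r = 0.5
        a, b = [1.0, 2.0, 3.0], [1.0, 3.0, 2.0]
        assert brute_force_r(a, b) == pytest.approx(0.5)
        assert rm.pearson_r(np.array(a), np.array(b)) == pytest.approx(0.5)

    def test_matches_definition_on_random_vectors(self, rng):
        for _ in range(20):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            assert rm.pearson_r(a, b) == pytest.approx(brute_force_r(a, b), abs=1e-12)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            rm.pearson_r(np.ones(5), np.arange(5.0))


def _library_from_matrix(mat, grid=None):
    grid = grid if grid is not None else np.arange(mat.shape[1], dtype=float)
    ids = [f"S{i:02d}" for i in range(mat.shape[0])]
    meta = {
        uid: rm.SpecimenMetadata(unique_id=uid, polymer=f"poly{i}",
                                 category="pristine anthropogenic")
        for i, uid in enumerate(ids)
    }
    return rm.SpectrumLibrary(grid=grid, ids=ids, matrix=mat, metadata=meta)


class TestDistanceMatrix:
    def test_identical_pair_all_zero(self, rng):
        row = rng.random(50)
        row[np.argmin(row)] = 0.0
        row[np.argmax(row)] = 1.0
        lib = _library_from_matrix(np.vstack([row, row]))
        dm = rm.distance_matrix(lib)
        np.testing.assert_allclose(dm.d_matrix, 0.0, atol=1e-12)

    def test_equals_double_loop_brute_force(self, rng):
        mat = rng.random((5, 60))
        lib = _library_from_matrix(mat)
        dm = rm.distance_matrix(lib)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else brute_force_r(mat[i], mat[j])
                assert dm.r_matrix[i, j] == pytest.approx(expected, abs=1e-12)
        assert dm.d_matrix.min() >= 0.0 and dm.d_matrix.max() <= 2.0

    def test_constant_spectrum_named_in_error(self, rng):
        mat = rng.random((3, 40))
        mat[1] = 0.5
        lib = _library_from_matrix(mat)
        with pytest.raises(DegenerateVectorError, match="S01"):
            rm.distance_matrix(lib)


class TestMatchQuery:
    @pytest.fixture()
    def library(self, rng):
        mat = rng.random((6, 80))
        mat[:, 0] = 0.0  # keep within [0, 1] bounds exactly
        mat[:, 1] = 1.0
        return _library_from_matrix(mat)

    def _query(self, lib, values, qid="Q"):
        return rm.ProcessedSpectrum(qid, lib.grid, np.asarray(values, float),
                                    "rescaled")

    def test_exact_copy_is_perfect_match(self, library):
        res = rm.match_query(self._query(library, library.matrix[3]), library)
        uid, r, d = res.best
        assert uid == "S03"
        assert r == pytest.approx(1.0, abs=1e-12)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert res.metadata_echo.polymer == "poly3"

    def test_affine_transform_still_matches(self, library):
        q = self._query(library, 2.0 * library.matrix[1] + 5.0)
        assert rm.match_query(q, library).best[0] == "S01"
        assert rm.match_query(q, library).best[2] == pytest.approx(0.0, abs=1e-12)

    def test_candidates_sorted_and_capped(self, library):
        res = rm.match_query(self._query(library, library.matrix[0]), library,
                             top_k=3)
        assert len(res.candidates) == 3
        ds = [c[2] for c in res.candidates]
        assert ds == sorted(ds)

    def test_library_order_invariance(self, library, rng):
        q = self._query(library, rng.random(80))
        best1 = rm.match_query(q, library).best[0]
        perm = rng.permutation(len(library.ids))
        shuffled = rm.SpectrumLibrary(
            grid=library.grid,
            ids=[library.ids[i] for i in perm],
            matrix=library.matrix[perm],
            metadata=library.metadata,
        )
        assert rm.match_query(q, shuffled).best[0] == best1

    def test_grid_mismatch_is_axis_error(self, library):
        other = rm.ProcessedSpectrum("Q", library.grid + 1.0,
                                     library.matrix[0], "rescaled")
        with pytest.raises(AxisError):
            rm.match_query(other, library)


def _dm_from_d(ids, d):
    d = np.asarray(d, float)
    return DistanceMatrix(ids=ids, r_matrix=1.0 - d, d_matrix=d)


class TestHCluster:
    def test_identical_pair_merges_first(self):
        d = [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        tree = rm.hcluster(_dm_from_d(["A", "B", "C"], d))
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_complete_linkage_hand_example(self):
        # d(A,B)=0.1, d(A,C)=0.4, d(B,C)=0.6: merge {A,B}@0.1, then @0.6
        d = [[0.0, 0.1, 0.4], [0.1, 0.0, 0.6], [0.4, 0.6, 0.0]]
        tree = rm.hcluster(_dm_from_d(["A", "B", "C"], d), "complete")
        np.testing.assert_allclose(tree.merge_heights, [0.1, 0.6])
        assert np.all(np.diff(tree.merge_heights) >= 0)

    def test_too_few_leaves(self):
        with pytest.raises(ValueError, match="3 leaves"):
            rm.hcluster(_dm_from_d(["A", "B"], [[0.0, 0.1], [0.1, 0.0]]))

    def test_simulated_four_class_recovery(self, sim_library, processed_library):
        from sklearn.metrics import adjusted_rand_score

        tree = rm.hcluster(rm.distance_matrix(processed_library))
        labels = tree.cut(4)
        truth = [processed_library.metadata[uid].polymer
                 for uid in processed_library.ids]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_leaf_permutation_preserves_cophenetic(self, rng):
        mat = rng.random((8, 40))
        lib = _library_from_matrix(mat)
        dm = rm.distance_matrix(lib)
        tree = rm.hcluster(dm)
        from scipy.spatial.distance import squareform

        c1 = squareform(tree.cophenetic())
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(
            ids=[dm.ids[i] for i in perm],
            r_matrix=dm.r_matrix[np.ix_(perm, perm)],
            d_matrix=dm.d_matrix[np.ix_(perm, perm)],
        )
        c2 = squareform(rm.hcluster(dm2).cophenetic())
        inv = np.empty(8, int)
        inv[perm] = np.arange(8)
        np.testing.assert_allclose(c2, c1[np.ix_(perm, perm)], atol=1e-12)


class TestNewickExport:
    def test_three_leaf_hand_example(self):
        d = [[0.0, 0.1, 0.4], [0.1, 0.0, 0.6], [0.4, 0.6, 0.0]]
        tree = rm.hcluster(_dm_from_d(["A", "B", "C"], d), "complete")
        nwk = rm.export_tree(tree)
        parsed = skbio.TreeNode.read([nwk])
        tips = {t.name: t for t in parsed.tips()}
        assert set(tips) == {"A", "B", "C"}
        assert tips["A"].length == pytest.approx(0.05)
        assert tips["B"].length == pytest.approx(0.05)
        assert tips["C"].length == pytest.approx(0.30)
        # A-B path = cophenetic 0.1; A-C path = 0.6
        assert parsed.find("A").distance(parsed.find("B")) == pytest.approx(0.1)
        assert parsed.find("A").distance(parsed.find("C")) == pytest.approx(0.6)

    def test_round_trip_leaf_ids(self, rng):
        mat = rng.random((6, 30))
        lib = _library_from_matrix(mat)
        tree = rm.hcluster(rm.distance_matrix(lib))
        parsed = skbio.TreeNode.read([rm.export_tree(tree)])
        assert {t.name for t in parsed.tips()} == set(lib.ids)


class TestEstimators:
    def test_nearest_neighbor_predicts_training_labels(self, rng):
        X = rng.random((10, 50))
        y = np.array([f"c{i % 3}" for i in range(10)])
        clf = rm.PearsonNearestNeighbor().fit(X, y)
        assert list(clf.predict(X)) == list(y)
        assert clf.score_r(X) == pytest.approx(np.ones(10))

    def test_nearest_neighbor_affine_invariant_queries(self, rng):
        X = rng.random((5, 50))
        y = np.arange(5)
        clf = rm.PearsonNearestNeighbor().fit(X, y)
        np.testing.assert_array_equal(clf.predict(3.0 * X + 7.0), y)

    def test_clusterer_exposes_sklearn_attributes(self, rng):
        up = np.linspace(0, 1, 30)
        X = np.vstack(
            [up + rng.normal(0, 0.05, (4, 30)), up[::-1] + rng.normal(0, 0.05, (4, 30))]
        )  # two shape groups: ascending vs descending
        cl = rm.PearsonHierarchicalClustering(n_clusters=2).fit(X)
        assert cl.labels_.shape == (8,)
        assert cl.linkage_.shape == (7, 4)
        assert cl.get_params()["n_clusters"] == 2

    def test_pairwise_pearson_symmetric_bounds(self, rng):
        X = rng.random((7, 40))
        R = pairwise_pearson(X, X)
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert R.min() >= -1.0 and R.max() <= 1.0
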