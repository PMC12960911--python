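import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cemusa.errors import ValidationError
from cemusa.matching import hungarian_assign, jaccard_matrix, match_clusters, relabel


def brute_force_best_assignment(J):
    """Exhaustive maximum-sum assignment; returns (best total, lexicographically
    smallest optimal permutation)."""
    m = J.shape[0]
    best_total, best_perm = -np.inf, None
    for perm in itertools.permutations(range(m)):
        total = sum(J[r, c] for r, c in enumerate(perm))
        if total > best_total + 1e-12:
            best_total, best_perm = total, perm
    return best_total, best_perm


def jaccard_by_sets(pred, true):
    out = np.zeros((max(pred), max(true)))
    for u in range(1, max(pred) + 1):
        cu = {i for i, p in enumerate(pred) if p == u}
        for v in range(1, max(true) + 1):
            cv = {i for i, t in enumerate(true) if t == v}
            out[u - 1, v - 1] = len(cu & cv) / len(cu | cv)
    return out


class TestJaccardMatrix:
    def test_identical_two_class_labelings(self):
        labels = np.array([1, 1, 2, 2])
        np.testing.assert_array_equal(jaccard_matrix(labels, labels), np.eye(2))

    def test_partial_overlap_is_one_third(self):
        # C_u = {s1, s2} vs C_v = {s2, s3}: intersection 1, union 3
        pred = np.array([1, 1, 2, 2])
        true = np.array([2, 1, 1, 2])
        assert jaccard_matrix(pred, true)[0, 0] == pytest.approx(1 / 3)

    def test_single_cluster_against_equal_domains(self):
        pred = np.ones(10, dtype=int)
        true = np.array([1] * 5 + [2] * 5)
        np.testing.assert_allclose(jaccard_matrix(pred, true), [[0.5, 0.5]])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            jaccard_matrix(np.array([1, 2]), np.array([1, 2, 1]))

    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 4)), min_size=8, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_set_computation(self, pairs):
        pred = np.array([p for p, _ in pairs])
        true = np.array([t for _, t in pairs])
        # densify so every label in 1..max is non-empty
        pred = np.unique(pred, return_inverse=True)[1] + 1
        true = np.unique(true, return_inverse=True)[1] + 1
        J = jaccard_matrix(pred, true)
        np.testing.assert_allclose(J, jaccard_by_sets(pred, true))
        assert J.sum(axis=1).max() <= J.shape[1]


class TestHungarianAssign:
    def test_identity_dominant(self):
        J = np.eye(3) * 0.9 + 0.01
        np.testing.assert_array_equal(hungarian_assign(J), [0, 1, 2])

    def test_two_by_two_derived_case(self):
        J = np.array([[0.9, 0.1], [0.2, 0.8]])
        assign = hungarian_assign(J)
        np.testing.assert_array_equal(assign, [0, 1])
        assert J[[0, 1], assign].sum() == pytest.approx(1.7)

    def test_tie_breaks_to_lexicographically_smallest(self):
        J = np.full((2, 2), 0.5)
        np.testing.assert_array_equal(hungarian_assign(J), [0, 1])
        J3 = np.full((3, 3), 0.25)
        np.testing.assert_array_equal(hungarian_assign(J3), [0, 1, 2])

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            hungarian_assign(np.zeros((2, 3)))

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            m = rng.integers(2, 7)
            J = rng.random((m, m))
            assign = hungarian_assign(J)
            total = J[np.arange(m), assign].sum()
            best, _ = brute_force_best_assignment(J)
            assert total == pytest.approx(best)


class TestMatchClusters:
    def test_equal_counts_recovers_permutation(self, rng):
        n = 60
        coords = rng.random((n, 2))
        true = rng.integers(1, 4, size=n)
        true[:3] = [1, 2, 3]
        perm = {1: 3, 2: 1, 3: 2}
        pred = np.array([perm[t] for t in true])
        res = match_clusters(pred, true, coords)
        assert res.mapping == {3: 1, 1: 2, 2: 3}
        np.testing.assert_array_equal(res.remapped_labels, true)

    def test_extra_cluster_takes_its_best_row(self):
        # K1=3 > K=2: the cluster relegated to a dummy column maps to its
        # highest-Jaccard domain (verified against the padded brute force).
        coords = np.zeros((20, 2))
        coords[:, 0] = np.arange(20)
        true = np.array([1] * 10 + [2] * 10)
        pred = np.array([1] * 8 + [3] * 3 + [2] * 9)
        res = match_clusters(pred, true, coords)
        J = res.jaccard
        padded = np.zeros((3, 3))
        padded[:, :2] = J
        _, perm = brute_force_best_assignment(padded)
        dummy_row = perm.index(2)
        assert res.mapping[dummy_row + 1] == int(np.argmax(J[dummy_row])) + 1
        assert set(res.mapping.keys()) == {1, 2, 3}
        assert set(res.mapping.values()) <= {1, 2}

    def test_missing_cluster_triggers_spatial_rematch(self):
        # K1=2 < K=3.  Cluster B wins domain 1 by Jaccard, but its spots all
        # sit on domain 2's centroid, so the dummy-row rule re-matches B to 2.
        coords = np.zeros((14, 2))
        #          A: 2 of domain 1 + 6 of domain 3 at x=0; B: 4 of domain 1
        #          and 3 of domain 2 at x=20
        coords[:, 0] = [0, 0, 0, 0, 0, 0, 0, 0, 20, 20, 20, 20, 20, 20]
        true = np.array([1, 1, 3, 3, 3, 3, 3, 3, 1, 1, 1, 1, 2, 2])
        true[12:] = 2
        pred = np.array([1] * 8 + [2] * 6)
        res = match_clusters(pred, true, coords)
        assert res.mapping[1] == 3  # A keeps its dominant domain
        assert res.mapping[2] == 2  # B re-matched from 1 to 2
        assert res.rematched_clusters == [2]

    def test_rematch_declined_when_not_closer(self):
        # Single cluster over two symmetric domains: tie in Jaccard, and the
        # centroid-distance condition is not strictly satisfied.
        coords = np.zeros((6, 2))
        coords[:, 0] = [0, 1, 2, 10, 11, 12]
        true = np.array([1, 1, 1, 2, 2, 2])
        pred = np.ones(6, dtype=int)
        res = match_clusters(pred, true, coords)
        assert res.mapping == {1: 1}
        assert res.rematched_clusters == []
        np.testing.assert_array_equal(res.remapped_labels, np.ones(6))

    def test_invariant_to_predicted_label_names(self, rng):
        n = 80
        coords = rng.random((n, 2))
        true = rng.integers(1, 5, size=n)
        true[:4] = [1, 2, 3, 4]
        pred = rng.integers(1, 5, size=n)
        pred[:4] = [1, 2, 3, 4]
        base = match_clusters(pred, true, coords).remapped_labels
        perm = np.array([0, 3, 1, 4, 2])  # relabel predicted clusters
        shuffled = match_clusters(perm[pred], true, coords).remapped_labels
        np.testing.assert_array_equal(base, shuffled)


class TestRelabel:
    def test_identity_mapping(self):
        pred = np.array([1, 2, 1, 2])
        np.testing.assert_array_equal(relabel(pred, {1: 1, 2: 2}), pred)

    def test_mapping_applies_per_spot(self):
        np.testing.assert_array_equal(
            relabel(np.array([1, 2, 1]), {1: 2, 2: 1}), [2, 1, 2]
        )

    def test_unseen_label_rejected(self):
        with pytest.raises(ValidationError):
            relabel(np.array([1, 2, 3]), {1: 1, 2: 2})

    def test_rematch_moves_exactly_the_identified_cluster(self):
        coords = np.zeros((14, 2))
        coords[:, 0] = [0] * 8 + [20] * 6
        true = np.array([1, 1, 3, 3, 3, 3, 3, 3, 1, 1, 1, 1, 2, 2])
        pred = np.array([1] * 8 + [2] * 6)
        res = match_clusters(pred, true, coords)
        naive = relabel(pred, {1: 3, 2: 1})  # assignment before the re-match rule
        differs = np.nonzero(naive != res.remapped_labels)[0]
        np.testing.assert_array_equal(differs, np.nonzero(pred == 2)[0])
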