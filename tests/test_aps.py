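"""Adaptive positive sampling: smoothing, thresholding, intersection, PPV/NPV."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from sccontrast import (CellGraph, final_adjacency, pair_sampling_quality,
                        smooth_soft_labels, soft_label_adjacency)
from sccontrast.aps import compute_cluster_state


def graph_from_dense(a):
    return CellGraph(adjacency=sp.csr_matrix(a), k=1)


class TestSmoothing:
    def test_isolated_node_keeps_own_label(self):
        y = np.array([[0.7, 0.3]])
        g = smooth_soft_labels(y, y, sp.csr_matrix((1, 1)))
        assert np.allclose(g, y)

    def test_constant_labels_unchanged(self, rng):
        row = np.array([0.2, 0.5, 0.3])
        y = np.tile(row, (6, 1))
        a = (rng.random((6, 6)) < 0.5).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        g = smooth_soft_labels(y, y, sp.csr_matrix(a))
        assert np.allclose(g, y)

    def test_three_node_path_hand_computed(self):
        # path 0-1-2; one-hot labels e0, e1, e2; Ã = rownorm(A+I)
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        y = np.eye(3)
        g = smooth_soft_labels(y, y, sp.csr_matrix(a))
        expected = np.array(
            [[0.5, 0.5, 0.0], [1 / 3, 1 / 3, 1 / 3], [0.0, 0.5, 0.5]]
        )
        assert np.allclose(g, expected)

    def test_rows_stay_on_simplex(self, rng):
        y1 = rng.dirichlet(np.ones(4), size=10)
        y2 = rng.dirichlet(np.ones(4), size=10)
        a = (rng.random((10, 10)) < 0.3).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        g = smooth_soft_labels(y1, y2, sp.csr_matrix(a))
        assert np.allclose(g.sum(axis=1), 1.0)
        assert np.all(g >= 0)

    def test_unnormalized_variant_scales_with_degree(self):
        a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        y = np.full((3, 2), 0.5)
        g = smooth_soft_labels(y, y, sp.csr_matrix(a), normalize="none")
        assert np.allclose(g[0], [1.0, 1.0])  # degree-2 node sums neighbors


class TestSoftLabelAdjacency:
    def test_lambda_below_minus_one_all_ones(self, rng):
        g = rng.random((5, 3)) + 0.1
        a_hat = soft_label_adjacency(g, -1.0).toarray()
        assert np.all(a_hat == 1)

    def test_lambda_above_one_empty(self, rng):
        g = rng.random((5, 3)) + 0.1
        assert soft_label_adjacency(g, 1.0 + 1e-9).nnz == 0

    def test_orthogonal_one_hot_rows_disconnected(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        a_hat = soft_label_adjacency(g, 0.5).toarray()
        assert a_hat[0, 1] == 0 and a_hat[1, 0] == 0

    def test_lazy_candidate_equals_full_after_intersection(self, rng):
        g = rng.dirichlet(np.ones(3), size=12)
        a = (rng.random((12, 12)) < 0.3).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        full = final_adjacency(sp.csr_matrix(a), soft_label_adjacency(g, 0.8))
        lazy = final_adjacency(
            sp.csr_matrix(a), soft_label_adjacency(g, 0.8, candidate=sp.csr_matrix(a))
        )
        assert (full != lazy).nnz == 0


class TestFinalAdjacency:
    def test_all_ones_hat_is_identity_of_intersection(self, rng):
        a = (rng.random((8, 8)) < 0.4).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        out = final_adjacency(sp.csr_matrix(a), sp.csr_matrix(np.ones((8, 8))))
        assert np.array_equal(out.toarray(), a)

    def test_zero_hat_gives_empty(self, rng):
        a = np.ones((5, 5)) - np.eye(5)
        out = final_adjacency(sp.csr_matrix(a), sp.csr_matrix((5, 5)))
        assert out.nnz == 0

    def test_matches_elementwise_and_oracle(self, rng):
        for _ in range(5):
            a = (rng.random((10, 10)) < 0.4).astype(float)
            a = np.maximum(a, a.T)
            np.fill_diagonal(a, 0)
            h = (rng.random((10, 10)) < 0.5).astype(float)
            h = np.maximum(h, h.T)
            out = final_adjacency(sp.csr_matrix(a), sp.csr_matrix(h)).toarray()
            expected = np.array(
                [[1.0 if a[i, j] and h[i, j] and i != j else 0.0
                  for j in range(10)] for i in range(10)]
            )
            assert np.array_equal(out, expected)


class TestMonotonicity:
    def test_edge_set_shrinks_as_lambda_grows(self, rng):
        y1 = rng.dirichlet(np.ones(3), size=20)
        a = (rng.random((20, 20)) < 0.3).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        graph = graph_from_dense(a)
        prev = None
        for lam in (-1.0, 0.0, 0.5, 0.9, 0.99):
            state = compute_cluster_state(y1, y1, graph, lam=lam)
            cur = state.A_final.toarray()
            assert np.all(cur <= a)  # always a subgraph of A
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur

    def test_lambda_minus_one_recovers_A_exactly(self, rng):
        y1 = rng.dirichlet(np.ones(3), size=15)
        a = (rng.random((15, 15)) < 0.3).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        state = compute_cluster_state(y1, y1, graph_from_dense(a), lam=-1.0)
        assert np.array_equal(state.A_final.toarray(), a)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(-1.0, 1.0))
def test_final_adjacency_always_subgraph_and_monotone(seed, lam):
    """For any soft labels and any λ, A_final ⊆ A, and raising λ never
    adds an edge."""
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 15))
    y = r.dirichlet(np.ones(3), size=n)
    a = (r.random((n, n)) < 0.4).astype(float)
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, 0)
    graph = graph_from_dense(a)
    low = compute_cluster_state(y, y, graph, lam=lam).A_final.toarray()
    high = compute_cluster_state(y, y, graph, lam=min(lam + 0.3, 1.0)).A_final.toarray()
    assert np.all(low <= a)
    assert np.all(high <= low)


class TestPairSamplingQuality:
    def _pairs_to_dense(self, pairs, n=6):
        a = np.zeros((n, n))
        for i, j in pairs:
            a[i, j] = a[j, i] = 1
        return sp.csr_matrix(a)

    def test_hand_counted_ppv_npv(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        candidates = [(0, 1), (0, 2), (1, 2), (3, 4), (4, 5), (0, 3), (1, 4), (2, 5)]
        kept = [(0, 1), (0, 2), (1, 2), (3, 4), (0, 3)]  # 4 same-type + 1 cross
        a = self._pairs_to_dense(candidates)
        af = self._pairs_to_dense(kept)
        ppv, npv = pair_sampling_quality(af, a, labels)
        assert ppv == pytest.approx(4 / 5)
        assert npv == pytest.approx(2 / 3)

    def test_degenerate_all_same_type(self):
        labels = np.zeros(4, dtype=int)
        a = self._pairs_to_dense([(0, 1), (2, 3)], n=4)
        ppv, npv = pair_sampling_quality(a, a, labels)
        assert ppv == 1.0
        assert np.isnan(npv)  # no predicted negatives

    def test_invariant_to_cell_permutation(self, rng):
        n = 12
        labels = rng.integers(0, 3, size=n)
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        keep = a * (rng.random((n, n)) < 0.6)
        keep = np.maximum(keep, keep.T)
        base = pair_sampling_quality(sp.csr_matrix(keep), sp.csr_matrix(a), labels)
        perm = rng.permutation(n)
        permuted = pair_sampling_quality(
            sp.csr_matrix(keep[perm][:, perm]),
            sp.csr_matrix(a[perm][:, perm]),
            labels[perm],
        )
        for x, y in zip(base, permuted):
            assert x == pytest.approx(y, nan_ok=True)
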