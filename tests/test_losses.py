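"""Loss values against literal double-loop transcriptions, closed forms,
invariances, and finite-difference gradients."""

import numpy as np
import pytest

from oracles import cluster_loss_oracle, entropy_reg_oracle, neighbor_loss_oracle
from sccontrast import (cluster_contrastive_loss, cluster_entropy_reg,
                        combine_losses, neighbor_contrastive_loss)
from sccontrast.autodiff import Tensor


def random_instance(rng, n=None, q=None):
    n = n or int(rng.integers(4, 16))
    q = q or int(rng.integers(2, 6))
    z1 = rng.normal(size=(n, q))
    z2 = rng.normal(size=(n, q))
    a = (rng.random((n, n)) < 0.3).astype(float)
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, 0)
    return z1, z2, a


class TestNeighborLoss:
    @pytest.mark.parametrize("exclude_self", [False, True])
    def test_matches_literal_transcription(self, rng, exclude_self):
        for _ in range(8):
            z1, z2, a = random_instance(rng)
            tau = float(rng.uniform(0.2, 2.0))
            got = neighbor_contrastive_loss(z1, z2, a, tau, exclude_self)
            want = neighbor_loss_oracle(z1, z2, a, tau, exclude_self)
            assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("tau", [0.2, 0.5, 2.0])
    def test_closed_form_log4_identical_rows_no_neighbors(self, tau):
        # every cosine = 1 → each term −log(e^{1/τ}/(4·e^{1/τ})) = log 4
        z = np.tile([[1.0, 2.0, 3.0]], (2, 1))
        got = neighbor_contrastive_loss(z, z, np.zeros((2, 2)), tau)
        assert got == pytest.approx(np.log(4.0), abs=1e-10)

    def test_nonnegative(self, rng):
        for _ in range(5):
            z1, z2, a = random_instance(rng)
            assert neighbor_contrastive_loss(z1, z2, a, 0.5) >= 0

    def test_invariant_to_row_rescaling(self, rng):
        z1, z2, a = random_instance(rng, n=8, q=4)
        s1 = rng.uniform(0.1, 10, size=(8, 1))
        s2 = rng.uniform(0.1, 10, size=(8, 1))
        base = neighbor_contrastive_loss(z1, z2, a, 0.5)
        scaled = neighbor_contrastive_loss(z1 * s1, z2 * s2, a, 0.5)
        assert scaled == pytest.approx(base, rel=1e-10)

    def test_input_validation(self, rng):
        z1, z2, a = random_instance(rng, n=5, q=3)
        with pytest.raises(ValueError):
            neighbor_contrastive_loss(z1, z2, a, tau=0.0)
        z1[0] = 0
        with pytest.raises(ValueError, match="zero-norm"):
            neighbor_contrastive_loss(z1, z2, a, 0.5)

    def test_extreme_temperature_stable(self, rng):
        z1, z2, a = random_instance(rng, n=6, q=4)
        val = neighbor_contrastive_loss(z1, z2, a, tau=1e-3)
        assert np.isfinite(val)


class TestClusterLoss:
    @pytest.mark.parametrize("exclude_self", [False, True])
    def test_matches_literal_transcription(self, rng, exclude_self):
        for _ in range(8):
            n, m = int(rng.integers(5, 12)), int(rng.integers(2, 6))
            y1 = rng.dirichlet(np.ones(m), size=n)
            y2 = rng.dirichlet(np.ones(m), size=n)
            tau = float(rng.uniform(0.2, 2.0))
            got = cluster_contrastive_loss(y1, y2, tau, exclude_self)
            want = cluster_loss_oracle(y1, y2, tau, exclude_self)
            assert got == pytest.approx(want, abs=1e-6)

    def test_closed_form_orthogonal_identical_views(self):
        # M=2, Y1==Y2 one-hot columns: numerator e^{1/τ}; denominator
        # 2e^{1/τ} + 2e^0 → −log(e²/(2e²+2)) at τ=0.5
        y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        got = cluster_contrastive_loss(y, y, tau=0.5)
        expected = -np.log(np.exp(2.0) / (2 * np.exp(2.0) + 2.0))
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(0.8200752, abs=1e-6)

    def test_invariant_to_joint_cluster_permutation(self, rng):
        y1 = rng.dirichlet(np.ones(4), size=10)
        y2 = rng.dirichlet(np.ones(4), size=10)
        perm = rng.permutation(4)
        base = cluster_contrastive_loss(y1, y2, 0.5)
        permuted = cluster_contrastive_loss(y1[:, perm], y2[:, perm], 0.5)
        assert permuted == pytest.approx(base, rel=1e-10)

    def test_empty_cluster_column_raises(self):
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="L_reg"):
            cluster_contrastive_loss(y, y, 0.5)


class TestEntropyReg:
    def test_uniform_masses_give_zero(self):
        y = np.full((8, 4), 0.25)
        assert cluster_entropy_reg(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_one_hot_mass_gives_log_m(self):
        m = 5
        y = np.zeros((6, m))
        y[:, 2] = 1.0
        assert cluster_entropy_reg(y, y) == pytest.approx(np.log(m), abs=1e-12)

    @pytest.mark.parametrize("joint", [False, True])
    def test_matches_literal_transcription(self, rng, joint):
        for _ in range(8):
            n, m = int(rng.integers(4, 12)), 4
            y1 = rng.dirichlet(np.ones(m), size=n)
            y2 = rng.dirichlet(np.ones(m), size=n)
            got = cluster_entropy_reg(y1, y2, joint_view_entropy=joint)
            want = entropy_reg_oracle(y1, y2, joint=joint)
            assert got == pytest.approx(want, abs=1e-10)

    def test_bounded_between_zero_and_log_m(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 7))
            y1 = rng.dirichlet(np.ones(m), size=int(rng.integers(3, 20)))
            y2 = rng.dirichlet(np.ones(m), size=y1.shape[0])
            val = cluster_entropy_reg(y1, y2)
            assert -1e-12 <= val <= np.log(m) + 1e-12


class TestCombine:
    def test_boundaries_and_arithmetic(self):
        assert combine_losses(2.0, 3.0, 1.0, alpha=1.0).L_total == pytest.approx(2.0)
        assert combine_losses(2.0, 3.0, 1.0, alpha=0.0).L_total == pytest.approx(4.0)
        lc = combine_losses(2.0, 3.0, 1.0, alpha=0.5)
        assert lc.L_cls == pytest.approx(4.0)
        assert lc.L_total == pytest.approx(3.0)

    def test_alpha_range_checked(self):
        with pytest.raises(ValueError):
            combine_losses(1.0, 1.0, 0.0, alpha=1.5)


def test_loss_gradients_match_finite_difference(rng):
    """Autodiff gradients of the combined loss w.r.t. embeddings on a
    6-cell instance agree with central differences."""
    n, q, m = 6, 4, 3
    z1d = rng.normal(size=(n, q))
    z2d = rng.normal(size=(n, q))
    y_logits = rng.normal(size=(n, m))
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1

    def value():
        from sccontrast.autodiff import softmax

        z1 = Tensor(z1d, requires_grad=True)
        y = softmax(Tensor(y_logits, requires_grad=True), axis=1)
        total = 0.5 * neighbor_contrastive_loss(z1, Tensor(z2d), a, 0.5) + 0.5 * (
            cluster_contrastive_loss(y, y, 0.5) + cluster_entropy_reg(y, y)
        )
        return total, z1

    total, z1 = value()
    total.backward()
    eps = 1e-6
    for _ in range(6):
        i, j = rng.integers(0, n), rng.integers(0, q)
        z1d[i, j] += eps
        fp = value()[0].item()
        z1d[i, j] -= 2 * eps
        fm = value()[0].item()
        z1d[i, j] += eps
        fd = (fp - fm) / (2 * eps)
        assert fd == pytest.approx(z1.grad[i, j], rel=1e-4, abs=1e-8)
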