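"""Learned FC adjacency, distance view, Laplacians and fixed baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sleepgcn import autodiff as ad
from sleepgcn.features import ChannelMontage
from sleepgcn.graphs import (
    GraphLearner,
    build_distance_adjacency,
    fc_adjacency_t,
    fixed_adjacency,
    graph_learning_loss,
    graph_loss_t,
    learn_fc_adjacency,
    scaled_laplacian,
)
from sleepgcn.synthetic import ring_montage


def fc_oracle(X, w):
    """Direct elementwise evaluation of the learned-adjacency formula."""
    n = X.shape[0]
    logits = np.zeros((n, n))
    for m in range(n):
        for k in range(n):
            logits[m, k] = max(0.0, w @ np.abs(X[m] - X[k]))
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


class TestLearnedAdjacency:
    def test_identical_features_give_exact_uniform_rows(self):
        X = np.ones((4, 3)) * 2.5
        A = learn_fc_adjacency(X, GraphLearner(np.array([1.0, -2.0, 0.5])))
        assert np.all(A == 0.25)

    def test_zero_weights_give_uniform_regardless_of_features(self, rng):
        X = rng.normal(size=(5, 3))
        A = learn_fc_adjacency(X, GraphLearner(np.zeros(3)))
        assert np.all(A == 0.2)

    def test_three_node_instance_matches_direct_evaluation(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        w = np.array([1.0, 1.0])
        A = learn_fc_adjacency(X, GraphLearner(w))
        assert np.allclose(A, fc_oracle(X, w), atol=1e-10)

    @given(
        X=arrays(np.float64, (4, 3), elements=st.floats(-5, 5)),
        w=arrays(np.float64, (3,), elements=st.floats(-2, 2)),
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_always_stochastic(self, X, w):
        A = learn_fc_adjacency(X, GraphLearner(w))
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(A > 0)

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 0.0]])
        with pytest.raises(ValueError):
            learn_fc_adjacency(X, GraphLearner(np.ones(2)))


class TestGraphLoss:
    def test_identical_features_loss_equals_lambda(self):
        X = np.ones((4, 3))
        A = learn_fc_adjacency(X, GraphLearner(np.ones(3)))
        assert graph_learning_loss(X, A, 0.001) == pytest.approx(0.001, abs=1e-12)

    def test_matches_brute_force_double_sum(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        w = np.array([1.0, 1.0])
        A = learn_fc_adjacency(X, GraphLearner(w))
        lam = 0.001
        expected = lam * (A**2).sum()
        for m in range(3):
            for n in range(3):
                expected += ((X[m] - X[n]) ** 2).sum() * A[m, n]
        assert graph_learning_loss(X, A, lam) == pytest.approx(expected, abs=1e-10)

    def test_increasing_in_lambda(self, rng):
        X = rng.normal(size=(4, 2))
        A = learn_fc_adjacency(X, GraphLearner(np.ones(2)))
        losses = [graph_learning_loss(X, A, lam) for lam in (0.001, 0.01, 0.1)]
        assert losses[0] < losses[1] < losses[2]

    def test_negative_lambda_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        A = learn_fc_adjacency(X, GraphLearner(np.ones(2)))
        with pytest.raises(ValueError):
            graph_learning_loss(X, A, -0.1)

    def test_gradient_wrt_w_matches_finite_differences(self, rng):
        X = rng.normal(size=(1, 4, 3))
        w0 = rng.normal(size=3)

        def loss_value(w):
            A = fc_adjacency_t(ad.Tensor(X), ad.Tensor(w))
            return float(graph_loss_t(ad.Tensor(X), A, 0.001).data)

        wt = ad.Tensor(w0, requires_grad=True)
        A = fc_adjacency_t(ad.Tensor(X), wt)
        graph_loss_t(ad.Tensor(X), A, 0.001).backward()
        eps = 1e-6
        for i in range(3):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            num = (loss_value(wp) - loss_value(wm)) / (2 * eps)
            assert wt.grad[i] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestDistanceAdjacency:
    def test_antipodal_pair_weight(self):
        montage = ChannelMontage(["A", "B"], np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        A = build_distance_adjacency(montage, sigma=1.0, threshold=0.0)
        assert A[0, 1] == pytest.approx(np.exp(-2.0))
        assert A[0, 0] == 0.0

    def test_high_threshold_disconnects_with_warning(self):
        montage = ChannelMontage(["A", "B"], np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        with pytest.warns(UserWarning, match="disconnected"):
            A = build_distance_adjacency(montage, sigma=1.0, threshold=0.99)
        assert not A.any()

    def test_three_electrode_distances_match_pairwise_oracle(self):
        coords = np.eye(3)
        montage = ChannelMontage(["A", "B", "C"], coords)
        A = build_distance_adjacency(montage, sigma=1.0, threshold=0.0)
        for m in range(3):
            for n in range(3):
                if m == n:
                    assert A[m, n] == 0.0
                else:
                    d2 = ((coords[m] - coords[n]) ** 2).sum()
                    assert A[m, n] == pytest.approx(np.exp(-d2 / 2.0))

    def test_invariant_under_global_rotation(self, rng):
        montage = ring_montage(6)
        theta = 0.83
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        rotated = ChannelMontage(montage.names, montage.coords @ R.T)
        A1 = build_distance_adjacency(montage, sigma=1.0, threshold=0.1)
        A2 = build_distance_adjacency(rotated, sigma=1.0, threshold=0.1)
        assert np.allclose(A1, A2, atol=1e-12)


class TestScaledLaplacian:
    def test_two_node_graph_closed_form(self):
        L_tilde = scaled_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(L_tilde, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-12)

    def test_zero_graph_falls_back_to_minus_identity(self):
        with pytest.warns(UserWarning, match="zero graph"):
            L_tilde = scaled_laplacian(np.zeros((3, 3)))
        assert np.allclose(L_tilde, -np.eye(3))

    def test_spectrum_bounded_for_random_graphs(self, rng):
        for _ in range(20):
            A = np.abs(rng.normal(size=(6, 6)))
            A = 0.5 * (A + A.T)
            np.fill_diagonal(A, 0.0)
            eigs = np.linalg.eigvalsh(scaled_laplacian(A))
            assert eigs.max() <= 1 + 1e-6
            assert eigs.min() >= -1 - 1e-6

    def test_asymmetric_input_is_symmetrised(self, rng):
        A = np.abs(rng.normal(size=(4, 4)))
        np.fill_diagonal(A, 0.0)
        assert np.allclose(scaled_laplacian(A), scaled_laplacian(0.5 * (A + A.T)))


class TestFixedAdjacency:
    def test_full_is_all_ones(self):
        assert np.array_equal(fixed_adjacency("full", n_channels=4), np.ones((4, 4)))

    def test_plv_of_identical_sinusoids_is_one(self):
        t = np.arange(1024) / 128.0
        x = np.sin(2 * np.pi * 7 * t)
        data = np.stack([x, x])
        P = fixed_adjacency("plv", data)
        assert P[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_pcc_matches_direct_correlation_oracle(self, rng):
        data = rng.normal(size=(3, 500))
        C = fixed_adjacency("pcc", data)
        for m in range(3):
            for n in range(3):
                r = np.corrcoef(data[m], data[n])[0, 1]
                assert C[m, n] == pytest.approx(abs(r), abs=1e-10)

    def test_pcc_constant_channel_defined_as_zero(self, rng):
        data = rng.normal(size=(3, 100))
        data[1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            C = fixed_adjacency("pcc", data)
        assert np.all(C[1] == 0.0) and np.all(C[:, 1] == 0.0)

    def test_knn_keeps_k_neighbours_and_symmetrises(self, rng):
        data = rng.normal(size=(5, 300))
        A = fixed_adjacency("knn", data, k=2)
        assert np.array_equal(A, A.T)
        assert np.all(A.sum(axis=1) >= 2)
        assert set(np.unique(A)) <= {0.0, 1.0}

    def test_mi_scaled_to_unit_interval_and_symmetric(self, rng):
        data = rng.normal(size=(4, 400))
        M = fixed_adjacency("mi", data)
        assert np.array_equal(M, M.T)
        assert M.min() >= 0.0 and M.max() <= 1.0
        # self-information dominates every cross-channel dependence
        assert np.all(np.diag(M)[:, None] >= M - 1e-12)
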