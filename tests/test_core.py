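"""Tests for the layer-weight and scoring computations.

Every vectorized operation is checked against an independent scalar
nested-loop implementation on random instances (the oracles below), in
addition to hand-enumerated small cases.
"""

import numpy as np
import pytest

from mras import (
    NCRNA,
    TARGET,
    SequenceRecord,
    TripartiteNetwork,
    combine_weights,
    layer1_weights,
    layer2_weights,
    prediction_scores,
    rank_predictions,
    run_mras,
    score_network,
)
from conftest import random_network


# ---- independent scalar oracles -------------------------------------------

def oracle_layer1(a_dt, k):
    m, n = a_dt.shape
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for l in range(m):
                deg = a_dt[l].sum()
                if deg > 0:
                    s += a_dt[l, i] * a_dt[l, j] / deg
            w[i, j] = k[i, j] * s
    return w


def oracle_layer2(a_tr, k):
    n, p = a_tr.shape
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            s = 0.0
            for l in range(n):
                deg = a_tr[l].sum()
                if deg > 0:
                    s += a_tr[l, i] * a_tr[l, j] / deg
            w[i, j] = k[i, j] * s
    return w


def oracle_combine(w_t, a_tr, w_r):
    n, p = a_tr.shape
    w_c = np.zeros((n, p))
    for i in range(n):
        for j in range(p):
            total = 0.0
            for t in range(n):
                inner = 0.0
                for r in range(p):
                    inner += a_tr[t, r] * w_r[r, j]
                total += w_t[i, t] * inner
            w_c[i, j] = total
    return w_c


def oracle_scores(a_dt, w_c):
    m, n = a_dt.shape
    p = w_c.shape[1]
    out = np.zeros((m, p))
    for i in range(m):
        for j in range(p):
            out[i, j] = sum(a_dt[i, t] * w_c[t, j] for t in range(n))
    return out


def random_symmetric(rng, size):
    a = rng.normal(size=(size, size))
    return (a + a.T) / 2.0


# ---- hand-enumerated cases -------------------------------------------------

class TestLayerWeightsHandCases:
    def test_single_disease_two_targets(self):
        # one disease adjacent to t1, t2 (deg 2), all-ones kernel
        a_dt = np.array([[1.0, 1.0]])
        w = layer1_weights(a_dt, np.ones((2, 2)))
        np.testing.assert_allclose(w, [[0.5, 0.5], [0.5, 0.5]])

    def test_all_zero_adjacency_gives_zero_weights(self):
        assert np.all(layer1_weights(np.zeros((3, 2)), np.ones((2, 2))) == 0)

    def test_single_target_three_ncrnas(self):
        # one target adjacent to r1..r3 (deg' 3): every pairwise weight 1/3
        a_tr = np.array([[1.0, 1.0, 1.0]])
        w = layer2_weights(a_tr, np.ones((3, 3)))
        np.testing.assert_allclose(w, np.full((3, 3), 1 / 3))

    def test_one_to_one_targets_give_diagonal(self):
        a_tr = np.eye(3)
        w = layer2_weights(a_tr, np.ones((3, 3)))
        np.testing.assert_allclose(w, np.eye(3))

    def test_layer2_alternative_degree_vector(self):
        a_tr = np.array([[1.0, 1.0]])
        w = layer2_weights(a_tr, np.ones((2, 2)), degrees=np.array([4.0]))
        np.testing.assert_allclose(w, np.full((2, 2), 0.25))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            layer1_weights(np.ones((2, 3)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            layer2_weights(np.ones((2, 3)), np.ones((2, 2)))


class TestCombineAndScoresHandCases:
    def test_identity_weights_reduce_to_adjacency(self, rng):
        a_tr = (rng.random((4, 3)) < 0.5).astype(float)
        np.testing.assert_allclose(combine_weights(np.eye(4), a_tr, np.eye(3)), a_tr)

    def test_zero_adjacency_gives_zero_combined(self):
        assert np.all(combine_weights(np.ones((3, 3)), np.zeros((3, 2)), np.ones((2, 2))) == 0)

    def test_single_disease_selects_target_row(self):
        w_c = np.array([[2.0, 3.0], [5.0, 7.0]])
        p = prediction_scores(np.array([[1.0, 0.0]]), w_c)
        np.testing.assert_allclose(p, [[2.0, 3.0]])

    def test_conformability_enforced(self):
        with pytest.raises(ValueError):
            combine_weights(np.ones((2, 2)), np.ones((3, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            prediction_scores(np.ones((2, 3)), np.ones((2, 2)))


# ---- oracle equivalence on random instances --------------------------------

class TestOracleEquivalence:
    def test_all_stages_match_scalar_loops(self, rng):
        """W_T, W_R, W_C and P match nested-loop evaluation to 1e-12."""
        for _ in range(100):
            m, n, p = rng.integers(1, 8, size=3)
            a_dt = (rng.random((m, n)) < 0.5).astype(float)
            a_tr = (rng.random((n, p)) < 0.5).astype(float)
            k_t = random_symmetric(rng, n)
            k_r = random_symmetric(rng, p)
            w_t = layer1_weights(a_dt, k_t)
            w_r = layer2_weights(a_tr, k_r)
            w_c = combine_weights(w_t, a_tr, w_r)
            scores = prediction_scores(a_dt, w_c)
            np.testing.assert_allclose(w_t, oracle_layer1(a_dt, k_t), atol=1e-12)
            np.testing.assert_allclose(w_r, oracle_layer2(a_tr, k_r), atol=1e-12)
            np.testing.assert_allclose(w_c, oracle_combine(w_t, a_tr, w_r), atol=1e-12)
            np.testing.assert_allclose(scores, oracle_scores(a_dt, w_c), atol=1e-12)


class TestAlgebraicProperties:
    def test_layer_weights_symmetric(self, rng):
        a_dt = (rng.random((5, 4)) < 0.5).astype(float)
        w = layer1_weights(a_dt, random_symmetric(rng, 4))
        assert np.abs(w - w.T).max() < 1e-12

    def test_kernel_scaling_scales_scores_linearly(self, rng):
        """Multiplying one layer's kernel by c scales W_T, W_C and P by c."""
        a_dt = (rng.random((4, 3)) < 0.6).astype(float)
        a_tr = (rng.random((3, 4)) < 0.6).astype(float)
        k_r = np.ones((4, 4))
        c = 3.7
        _, p1 = score_network(a_dt, a_tr, np.ones((3, 3)), k_r)
        _, p2 = score_network(a_dt, a_tr, c * np.ones((3, 3)), k_r)
        np.testing.assert_allclose(p2, c * p1, atol=1e-12)

    def test_nonnegative_with_nonnegative_kernels(self, rng):
        a_dt = (rng.random((5, 4)) < 0.5).astype(float)
        a_tr = (rng.random((4, 5)) < 0.5).astype(float)
        k_t = np.abs(random_symmetric(rng, 4))
        k_r = np.abs(random_symmetric(rng, 5))
        w_c, p = score_network(a_dt, a_tr, k_t, k_r)
        assert w_c.min() >= 0 and p.min() >= 0

    def test_isolated_disease_leaves_scores_unchanged(self, rng):
        a_dt = (rng.random((3, 4)) < 0.6).astype(float)
        a_tr = (rng.random((4, 3)) < 0.6).astype(float)
        _, p = score_network(a_dt, a_tr, np.ones((4, 4)), np.ones((3, 3)))
        a_dt_aug = np.vstack([a_dt, np.zeros(4)])
        _, p_aug = score_network(a_dt_aug, a_tr, np.ones((4, 4)), np.ones((3, 3)))
        np.testing.assert_allclose(p_aug[:3], p, atol=1e-12)
        assert np.all(p_aug[3] == 0)


# ---- end-to-end pipeline ----------------------------------------------------

def _seqs_for(net, rng):
    targets = [
        SequenceRecord(t, "".join(rng.choice(list("ACDEFGHIK"), size=30)), TARGET)
        for t in net.targets
    ]
    ncrnas = [
        SequenceRecord(r, "".join(rng.choice(list("ACGU"), size=40)), NCRNA)
        for r in net.ncrnas
    ]
    return targets, ncrnas


class TestRunMras:
    def test_ones_kernel_reduces_to_pure_resource_allocation(self, rng):
        net = random_network(rng, 4, 3, 4)
        targets, ncrnas = _seqs_for(net, rng)
        sm = run_mras(net, targets, ncrnas, l=1, kernel="ones")
        w_t = layer1_weights(net.A_DT, np.ones((3, 3)))
        w_r = layer2_weights(net.A_TR, np.ones((4, 4)))
        expected = net.A_DT @ (w_t @ (net.A_TR @ w_r))
        np.testing.assert_allclose(sm.P, expected, atol=1e-12)

    def test_ncrna_permutation_permutes_score_columns(self, rng):
        net = random_network(rng, 4, 3, 5)
        targets, ncrnas = _seqs_for(net, rng)
        sm = run_mras(net, targets, ncrnas, l=1, sigma1=0.5, sigma2=0.5)
        perm = rng.permutation(5)
        net_perm = TripartiteNetwork(
            net.diseases, net.targets, [net.ncrnas[j] for j in perm],
            net.A_DT, net.A_TR[:, perm],
        )
        sm_perm = run_mras(net_perm, targets, ncrnas, l=1, sigma1=0.5, sigma2=0.5)
        np.testing.assert_allclose(sm_perm.P, sm.P[:, perm], atol=1e-12)

    def test_repeated_runs_bitwise_identical(self, rng):
        net = random_network(rng, 3, 3, 3)
        targets, ncrnas = _seqs_for(net, rng)
        p1 = run_mras(net, targets, ncrnas, l=2).P
        p2 = run_mras(net, targets, ncrnas, l=2).P
        assert np.array_equal(p1, p2)

    def test_missing_sequence_raises_naming_entity(self, rng):
        net = random_network(rng, 3, 3, 3)
        targets, ncrnas = _seqs_for(net, rng)
        with pytest.raises(ValueError, match="t1"):
            run_mras(net, [t for t in targets if t.id != "t1"], ncrnas, l=1)

    def test_sigma_assignment_swaps_kernels(self, rng):
        net = random_network(rng, 4, 3, 4)
        targets, ncrnas = _seqs_for(net, rng)
        a = run_mras(net, targets, ncrnas, l=1, sigma1=0.2, sigma2=0.8,
                     sigma_assignment="layer").P
        b = run_mras(net, targets, ncrnas, l=1, sigma1=0.8, sigma2=0.2,
                     sigma_assignment="formula").P
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rank_predictions_orders_by_score(self, rng):
        net = random_network(rng, 3, 3, 4)
        targets, ncrnas = _seqs_for(net, rng)
        sm = run_mras(net, targets, ncrnas, l=1, kernel="ones")
        ranked = rank_predictions(sm, top_k=2)
        for d, grp in ranked.groupby("disease"):
            assert list(grp["rank"]) == [1, 2]
            assert grp["score"].is_monotonic_decreasing
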