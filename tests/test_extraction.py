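"""ANLS-NMF factorization, coefficient averaging, cross-subgroup sorting."""

import numpy as np
import pytest

from choosyn import (
    average_coefficients,
    build_synergy_stack,
    extract_all,
    nmf_anls,
    preprocess,
)
from choosyn.errors import OrderExceedsMusclesError
from choosyn.extraction import (
    FactorizationResult,
    NmfParams,
    cosine_kmeans,
    sort_synergies,
)
from choosyn.selection_vaf import vaf


def random_lowrank(rng, m=12, t=2000, k=3, noise=0.02):
    V = rng.uniform(size=(m, k)) @ rng.uniform(size=(k, t))
    V *= 1 + noise * rng.standard_normal(V.shape)
    return np.maximum(V, 0.0)


class TestNmfAnls:
    def test_exact_rank_one_recovered(self, rng, fast_nmf):
        V = np.outer(np.abs(rng.standard_normal(12)),
                     np.abs(rng.standard_normal(1500)))
        res = nmf_anls(V, 1, seed=0, params=fast_nmf)
        assert vaf(V, res.W @ res.C_full) >= 99.99

    def test_factors_nonnegative_and_unit_norm_columns(self, rng, fast_nmf):
        V = random_lowrank(rng)
        res = nmf_anls(V, 4, seed=1, params=fast_nmf)
        assert (res.W >= 0).all() and (res.C_full >= 0).all()
        norms = np.linalg.norm(res.W, axis=0)
        np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-10)

    def test_residual_is_min_of_rerun_errors(self, rng, fast_nmf):
        V = random_lowrank(rng)
        res = nmf_anls(V, 3, seed=2, params=fast_nmf)
        assert res.residual == min(res.rerun_errors)
        assert len(res.rerun_errors) == fast_nmf.reruns

    def test_residual_nonincreasing_in_order(self, fast_nmf):
        # reconstruction can only improve as the order grows
        rng = np.random.default_rng(5)
        for trial in range(4):
            V = random_lowrank(rng, k=3 + trial % 2)
            errs = [nmf_anls(V, k, seed=3, params=fast_nmf).residual
                    for k in (2, 3, 4)]
            assert errs[1] <= errs[0] + 1e-6 * errs[0]
            assert errs[2] <= errs[1] + 1e-6 * errs[1]

    def test_zero_row_gives_zero_weight_row(self, rng, fast_nmf):
        V = random_lowrank(rng)
        V[5] = 0.0
        res = nmf_anls(V, 3, seed=4, params=fast_nmf)
        np.testing.assert_allclose(res.W[5], 0.0, atol=1e-8)

    def test_determinism(self, rng, fast_nmf):
        V = random_lowrank(rng)
        a = nmf_anls(V, 3, seed=9, params=fast_nmf)
        b = nmf_anls(V, 3, seed=9, params=fast_nmf)
        assert a.rerun_errors == b.rerun_errors
        np.testing.assert_array_equal(a.W, b.W)

    def test_domain_errors(self, rng, fast_nmf):
        V = random_lowrank(rng)
        with pytest.raises(OrderExceedsMusclesError):
            nmf_anls(V, 13, params=fast_nmf)
        with pytest.raises(ValueError):
            nmf_anls(-V - 1.0, 2, params=fast_nmf)

    def test_decimated_fit_close_to_full(self, rng):
        V = random_lowrank(rng, t=4000)
        full = nmf_anls(V, 3, seed=0, params=NmfParams(max_iter=150, reruns=2))
        dec = nmf_anls(V, 3, seed=0,
                       params=NmfParams(max_iter=150, reruns=2, decimate=5))
        v_full = vaf(V, full.W @ full.C_full)
        v_dec = vaf(V, dec.W @ dec.C_full)
        assert abs(v_full - v_dec) < 0.1


class TestAverageCoefficients:
    def test_periodic_signal_collapses_to_one_period(self, rng):
        period = np.abs(rng.standard_normal((2, 1000)))
        C = np.tile(period, (1, 10))
        np.testing.assert_allclose(average_coefficients(C), period,
                                   rtol=1e-12)

    def test_arithmetic_mean_oracle(self):
        r = np.linspace(0, 1, 1000)
        C = np.concatenate([k * r for k in range(1, 11)])[None, :]
        np.testing.assert_allclose(average_coefficients(C)[0], 5.5 * r,
                                   rtol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            average_coefficients(np.zeros((2, 5000)))


class TestExtractAll:
    def test_counts_vaf_and_determinism(self, recording4, fast_nmf):
        subs = preprocess(recording4)
        results = extract_all(subs, n_range=(1, 4), seed=5, params=fast_nmf)
        assert len(results) == subs.n_subgroups * 4
        again = extract_all(subs, n_range=(1, 4), seed=5, params=fast_nmf)
        assert ([r.residual for r in results]
                == [r.residual for r in again])
        # VAF non-decreasing in order, per subgroup
        for j in range(subs.n_subgroups):
            vafs = [r.vaf_percent for r in results if r.subgroup_index == j]
            assert all(b >= a - 1e-3 for a, b in zip(vafs, vafs[1:]))

    def test_rank4_truth_reaches_high_vaf_at_4(self, recording4, fast_nmf):
        subs = preprocess(recording4)
        results = extract_all(subs, n_range=(4, 4), seed=5, params=fast_nmf)
        mean_vaf = np.mean([r.vaf_percent for r in results])
        assert mean_vaf > 98.5


class TestCosineKmeans:
    def test_exact_orthogonal_clusters(self):
        basis = np.eye(3)
        X = np.vstack([basis, 0.9 * basis, 1.1 * basis])
        labels, cents, inertia = cosine_kmeans(X, 3, seed=0, replicas=5)
        assert inertia == pytest.approx(0.0, abs=1e-12)
        # the three copies of each basis vector share a label
        for i in range(3):
            assert labels[i] == labels[i + 3] == labels[i + 6]

    def test_scale_invariance_of_assignment(self, rng):
        X = np.abs(rng.standard_normal((12, 5)))
        l1, _, _ = cosine_kmeans(X, 3, seed=1, replicas=5)
        l2, _, _ = cosine_kmeans(X * 7.5, 3, seed=1, replicas=5)
        np.testing.assert_array_equal(l1, l2)


def _fake_result(W, order_n, subgroup, c_avg=None):
    n = W.shape[1]
    return FactorizationResult(order_n=order_n, subgroup_index=subgroup,
                               W=W, C_full=np.ones((n, 10_000)),
                               C_avg=(np.tile(np.arange(n)[:, None],
                                              (1, 1000)).astype(float)
                                      if c_avg is None else c_avg),
                               residual=0.0, rerun_errors=[0.0])


class TestSortSynergies:
    def test_shuffled_orthogonal_vectors_align(self, rng):
        basis = np.eye(4)
        results = []
        for j in range(3):
            perm = rng.permutation(4)
            c_avg = np.tile(perm[:, None], (1, 1000)).astype(float) + 1.0
            results.append(_fake_result(basis[:, perm], 4, j, c_avg=c_avg))
        so = sort_synergies(results, 4, seed=0)
        for j in range(1, 3):
            np.testing.assert_allclose(so.weights[j], so.weights[0],
                                       atol=1e-12)
        # coefficients permuted consistently with the weights
        for j in range(3):
            np.testing.assert_allclose(so.coeffs[j], so.coeffs[0], atol=1e-12)

    def test_two_subgroup_pairing_matches_brute_force(self):
        w1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        w2 = np.array([[0.9, 0.1], [0.1, 0.9]])
        w2 /= np.linalg.norm(w2, axis=0)
        results = [_fake_result(w1, 2, 0), _fake_result(w2, 2, 1)]
        so = sort_synergies(results, 2, seed=0)
        # nearest-by-cosine pairing: column i of both subgroups align
        cos = (so.weights[0][:, 0] @ so.weights[1][:, 0])
        assert cos > 0.9

    def test_subgroup_order_invariance_of_centroids(self, rng):
        results = []
        base = np.abs(rng.standard_normal((12, 3))) + 0.1
        for j in range(4):
            W = base + 0.02 * rng.standard_normal((12, 3))
            W = np.abs(W)
            W /= np.linalg.norm(W, axis=0)
            results.append(_fake_result(W[:, rng.permutation(3)], 3, j))
        so1 = sort_synergies(results, 3, seed=2)
        shuffled = [
            FactorizationResult(order_n=r.order_n,
                                subgroup_index=3 - r.subgroup_index,
                                W=r.W, C_full=r.C_full, C_avg=r.C_avg,
                                residual=r.residual,
                                rerun_errors=r.rerun_errors)
            for r in results
        ]
        so2 = sort_synergies(shuffled, 3, seed=2)
        got = sorted(map(tuple, np.round(so1.centroid_w.T, 8)))
        exp = sorted(map(tuple, np.round(so2.centroid_w.T, 8)))
        np.testing.assert_allclose(got, exp, atol=1e-8)

    def test_labels_are_permutations(self, recording4, fast_nmf):
        subs = preprocess(recording4)
        results = extract_all(subs, n_range=(1, 5), seed=5, params=fast_nmf)
        stack = build_synergy_stack(results, seed=0)
        for n, so in stack.orders.items():
            for Wj in so.weights:
                assert Wj.shape == (12, n)
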