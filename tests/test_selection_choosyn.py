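"""Consistency/similarity parameters, step detection and selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choosyn.errors import ClusteringDomainError
from choosyn.selection_choosyn import (
    N_MAX,
    N_MIN,
    Candidate,
    ChoosynProfile,
    coefficient_similarity,
    detect_candidates,
    find_split_pair,
    intra_cluster_variability,
    select_n,
    weight_similarity,
)

SQ2 = np.sqrt(2) / 2


class TestIntraClusterVariability:
    def test_identical_members_give_zero(self):
        cent = np.array([[1.0, 0.0], [0.0, 1.0]])
        members = [cent.copy(), cent.copy(), 2.0 * cent]
        assert intra_cluster_variability(members, cent) == pytest.approx(0.0)

    def test_orthogonal_members_hand_value(self):
        # two subgroups at (1,0) and (0,1) around centroid (0.5,0.5):
        # cosine 0.7071 each, ICV = 1 - 0.7071 = 0.2929
        members = [np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])]
        cent = np.array([[0.5], [0.5]])
        assert intra_cluster_variability(members, cent) == pytest.approx(
            1 - SQ2, abs=1e-4)

    def test_max_over_synergies(self):
        cent = np.array([[1.0, 0.5], [0.0, 0.5]])
        members = [np.array([[1.0, 1.0], [0.0, 0.0]]),
                   np.array([[1.0, 0.0], [0.0, 1.0]])]
        # synergy 1 perfectly repeatable; synergy 2 orthogonal across
        # subgroups -> the max rule returns synergy 2's 0.2929
        assert intra_cluster_variability(members, cent) == pytest.approx(
            1 - SQ2, abs=1e-6)

    def test_zero_norm_rejected(self):
        with pytest.raises(ClusteringDomainError):
            intra_cluster_variability([np.zeros((2, 1))],
                                      np.array([[1.0], [0.0]]))


class TestWeightSimilarity:
    def test_identical_and_orthogonal(self):
        assert weight_similarity(np.array([[1.0, 1.0], [0.0, 0.0]])) \
            == pytest.approx(1.0)
        assert weight_similarity(np.eye(2)) == pytest.approx(0.0)

    def test_hand_cosine_and_bruteforce_pairs(self, rng):
        cents = np.array([[1.0, 1.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]])
        assert weight_similarity(cents) == pytest.approx(SQ2, abs=1e-9)
        # brute force over all pairs on a random set
        X = np.abs(rng.standard_normal((6, 5))) + 0.01
        got = weight_similarity(X)
        Xu = X / np.linalg.norm(X, axis=0)
        best = max((Xu[:, i] @ Xu[:, k])
                   for i in range(5) for k in range(i + 1, 5))
        assert got == pytest.approx(best, abs=1e-12)


class TestFindSplitPair:
    def test_n2_trivial(self):
        assert find_split_pair(np.eye(2), None, 2) == [(0, 1)]

    def test_split_detected_by_clustering(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.3])
        c = np.array([0.0, 0.3, 1.0])          # cos(b, c) ~ 0.55
        level3 = np.column_stack([a, b, c])
        level2 = np.column_stack([a, (b + c) / 2])
        pairs = find_split_pair(level3, level2, 3)
        assert pairs == [(1, 2)]

    def test_pigeonhole_always_finds_a_pair(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 8))
            cents = np.abs(rng.standard_normal((12, n))) + 0.05
            prev = np.abs(rng.standard_normal((12, n - 1))) + 0.05
            assert len(find_split_pair(cents, prev, n)) >= 1


class TestCoefficientSimilarity:
    def test_identical_orthogonal_and_hand_value(self):
        C = np.array([[1.0, 1.0], [1.0, 0.0]])
        assert coefficient_similarity(np.array([[1.0, 0.0], [1.0, 0.0]]),
                                      [(0, 1)]) == pytest.approx(1.0)
        assert coefficient_similarity(np.eye(2), [(0, 1)]) \
            == pytest.approx(0.0)
        assert coefficient_similarity(C, [(0, 1)]) == pytest.approx(SQ2)


def profile_from(choosyn_w, choosyn_c):
    w = np.asarray(choosyn_w, dtype=float)
    c = np.asarray(choosyn_c, dtype=float)
    zeros = np.zeros_like(w)
    return ChoosynProfile(n_values=np.arange(N_MIN, N_MAX + 1),
                          icv_w=zeros, icv_c=zeros, ws=w, cs=c,
                          choosyn_w=w, choosyn_c=c)


class TestDetectCandidates:
    def test_step_worked_example(self):
        # threshold 0.1033; step at the level before the sharp rise
        got = detect_candidates([0.30, 0.32, 0.31, 0.75, 0.80, 0.85, 0.90])
        assert got == [Candidate(4, "step")]

    def test_local_minimum_worked_example(self):
        got = detect_candidates([0.50, 0.48, 0.20, 0.55, 0.57, 0.58, 0.60])
        assert got == [Candidate(4, "local_minimum")]

    def test_two_highest_kept(self):
        # profile with steps at 3, 5 and 7: only the two highest remain
        vals = [0.1, 0.1, 0.5, 0.5, 0.9, 0.9, 1.5]
        got = detect_candidates(vals)
        assert [c.n for c in got] == [5, 7]   # steps at 3, 5, 7 trimmed

    def test_flat_profile_gives_nothing(self):
        assert detect_candidates([0.4] * 7) == []

    def test_matches_bruteforce_rule_evaluator(self, rng):
        def brute(values):
            d = np.diff(values)
            theta = np.mean(np.abs(d))
            if theta == 0:
                return []
            found = {}
            for i in range(6):
                n = 2 + i
                if d[i] > theta and (i == 0 or abs(d[i - 1]) <= theta):
                    found.setdefault(n, "step")
                if i >= 1 and -d[i - 1] > theta and d[i] > theta:
                    found.setdefault(n, "local_minimum")
            kept = sorted(found)[-2:]
            return [(n, found[n]) for n in kept]

        for _ in range(10_000):
            vals = rng.uniform(0, 2, size=7)
            got = [(c.n, c.kind) for c in detect_candidates(vals)]
            assert got == brute(vals)


class TestSelectN:
    def test_common_candidate_wins(self):
        # W side steps at 4 and 6, C side at 4 only -> 4
        p = profile_from([0.1, 0.1, 0.1, 0.6, 0.6, 1.2, 1.2],
                         [0.1, 0.1, 0.1, 0.8, 0.8, 0.8, 0.8])
        n, diag = select_n(p)
        assert n == 4 and diag["rule"] == "common"

    def test_lowest_sum_rule(self):
        # disjoint candidates: W {5}, C {4}; sums favour 4
        p = profile_from([0.2, 0.2, 0.2, 0.21, 0.9, 0.9, 0.9],
                         [0.2, 0.2, 0.25, 0.9, 0.95, 0.95, 0.95])
        n, diag = select_n(p)
        assert diag["rule"] == "lowest_sum"
        w_ns = {c[0] for c in diag["candidates_w"]}
        c_ns = {c[0] for c in diag["candidates_c"]}
        assert not (w_ns & c_ns)
        total = p.choosyn_w + p.choosyn_c
        best = min(w_ns | c_ns, key=lambda k: total[k - 2])
        assert n == best

    def test_flat_profiles_fall_back_to_argmin(self):
        p = profile_from([0.5] * 7, [0.4] * 7)
        n, diag = select_n(p)
        assert diag["fallback"] is True
        assert n == 2  # argmin of a constant sum resolves to the smallest n


class TestScaleInvariance:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_parameters_unchanged_by_positive_scaling(self, scale):
        rng = np.random.default_rng(3)
        cents = np.abs(rng.standard_normal((8, 4))) + 0.01
        members = [np.abs(cents + 0.1 * rng.standard_normal(cents.shape))
                   for _ in range(3)]
        base_ws = weight_similarity(cents)
        base_icv = intra_cluster_variability(members, cents)
        scaled_members = [m * scale for m in members]
        assert weight_similarity(cents * scale) == pytest.approx(base_ws)
        assert intra_cluster_variability(scaled_members, cents) \
            == pytest.approx(base_icv)
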