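"""Consistency/similarity criterion for the number of synergies (ChoOSyn).

For every candidate order n in 2..8 the criterion scores the sorted
synergy stack with four cosine-based parameters:

* ICV_W, ICV_C (intra-cluster variability): worst-case, across synergies,
  of one minus the mean cosine similarity between a synergy's per-subgroup
  members and its centroid — consistency of the decomposition in time;
* WS (weight similarity): largest pairwise cosine between weight
  centroids — redundancy of the basis at this order;
* CS (coefficient similarity): cosine between the averaged activation
  profiles of the two synergies born by splitting one synergy of order
  n-1 — information gained by the extra synergy.

Their sums ChoOSyn_W = WS + ICV_W and ChoOSyn_C = CS + ICV_C stay low and
stable up to the correct order and jump beyond it; the selection rules
look for that step (or a local minimum) in each profile and reconcile the
two parameters' candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ClusteringDomainError, IncompleteStackError
from .extraction import SynergyStack, cosine_kmeans

__all__ = [
    "ChoosynProfile",
    "Candidate",
    "CandidateSet",
    "intra_cluster_variability",
    "weight_similarity",
    "find_split_pair",
    "coefficient_similarity",
    "build_profile",
    "detect_candidates",
    "select_n",
]

N_MIN, N_MAX = 2, 8


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ClusteringDomainError("zero-norm vector in cosine similarity")
    return float(a @ b / (na * nb))


def intra_cluster_variability(members: list[np.ndarray],
                              centroids: np.ndarray) -> float:
    """Worst-case synergy inconsistency across subgroups.

    ``members[j]`` holds subgroup j's vectors as columns (one per synergy);
    ``centroids`` holds the matching centroid columns.  For each synergy the
    cosine to the centroid is averaged over subgroups; the returned value is
    the maximum of one minus that mean.
    """
    n = centroids.shape[1]
    worst = 0.0
    for i in range(n):
        sims = [_cos(M[:, i], centroids[:, i]) for M in members]
        worst = max(worst, 1.0 - float(np.mean(sims)))
    return worst


def weight_similarity(centroids: np.ndarray) -> float:
    """Largest pairwise cosine between weight centroids (columns)."""
    n = centroids.shape[1]
    if n < 2:
        raise ValueError("need at least two centroids")
    best = -np.inf
    for i in range(n):
        for k in range(i + 1, n):
            best = max(best, _cos(centroids[:, i], centroids[:, k]))
    return float(best)


def find_split_pair(centroids_n: np.ndarray, centroids_prev: np.ndarray | None,
                    order_n: int) -> list[tuple[int, int]]:
    """Identify the two order-n synergies split from one order-(n-1) synergy.

    The n weight centroids are clustered into n-1 groups by cosine k-means
    initialized at the previous order's centroids; by pigeonhole at least
    one group holds two synergies — that pair is returned.  If several
    groups are multiply occupied, every within-group pair is returned and
    the caller scores the worst case.  For n = 2 the pair is trivially
    (0, 1).
    """
    if order_n == 2:
        return [(0, 1)]
    if centroids_prev is None:
        raise ValueError("previous-order centroids required for n >= 3")
    labels, _, _ = cosine_kmeans(centroids_n.T, order_n - 1,
                                 init_centroids=centroids_prev.T)
    pairs = []
    for c in range(order_n - 1):
        idx = np.where(labels == c)[0]
        if len(idx) >= 2:
            pairs.extend((int(a), int(b))
                         for ai, a in enumerate(idx) for b in idx[ai + 1:])
    if not pairs:   # cannot happen with exact one-to-... pigeonhole guard
        raise RuntimeError("pigeonhole violation in split-pair clustering")
    return pairs


def coefficient_similarity(centroid_c: np.ndarray,
                           pairs: list[tuple[int, int]]) -> float:
    """Cosine between the split pair's averaged activation profiles.

    With several candidate pairs the largest similarity (worst case) is
    returned.
    """
    return max(_cos(centroid_c[i], centroid_c[k]) for i, k in pairs)


@dataclass
class ChoosynProfile:
    """Per-order parameter table and the combined selection profiles."""

    n_values: np.ndarray                # 2..8
    icv_w: np.ndarray
    icv_c: np.ndarray
    ws: np.ndarray
    cs: np.ndarray
    choosyn_w: np.ndarray               # ws + icv_w
    choosyn_c: np.ndarray               # cs + icv_c

    @property
    def delta_w(self) -> np.ndarray:
        return np.diff(self.choosyn_w)

    @property
    def delta_c(self) -> np.ndarray:
        return np.diff(self.choosyn_c)


def build_profile(stack: SynergyStack) -> ChoosynProfile:
    """Score a sorted synergy stack at every order 2..8."""
    ns = list(range(N_MIN, N_MAX + 1))
    missing = [n for n in ns if n not in stack.orders]
    if missing:
        raise IncompleteStackError(f"stack is missing orders {missing}")
    icv_w, icv_c, ws, cs = [], [], [], []
    for n in ns:
        so = stack.orders[n]
        icv_w.append(intra_cluster_variability(so.weights, so.centroid_w))
        icv_c.append(intra_cluster_variability(
            [c.T for c in so.coeffs], so.centroid_c.T))
        ws.append(weight_similarity(so.centroid_w))
        prev = stack.orders[n - 1].centroid_w if n - 1 in stack.orders else None
        pairs = find_split_pair(so.centroid_w, prev, n)
        cs.append(coefficient_similarity(so.centroid_c, pairs))
    icv_w, icv_c = np.array(icv_w), np.array(icv_c)
    ws, cs = np.array(ws), np.array(cs)
    return ChoosynProfile(n_values=np.array(ns), icv_w=icv_w, icv_c=icv_c,
                          ws=ws, cs=cs, choosyn_w=ws + icv_w,
                          choosyn_c=cs + icv_c)


@dataclass(frozen=True)
class Candidate:
    n: int
    kind: str                           # "step" or "local_minimum"


@dataclass
class CandidateSet:
    w_side: list[Candidate] = field(default_factory=list)
    c_side: list[Candidate] = field(default_factory=list)


def detect_candidates(values: np.ndarray) -> list[Candidate]:
    """Step / local-minimum candidates of one 7-point profile (n = 2..8).

    With signed differences d(n) = value(n+1) - value(n) and threshold
    theta = mean(|d|):

    * a STEP sits at n when d(n) rises above theta while the preceding
      difference was stable (|d(n-1)| <= theta, or n is the first order);
      the candidate is the level before the sharp rise;
    * a LOCAL MINIMUM sits at n when an above-threshold drop into n is
      followed by an above-threshold rise out of it.

    Only the two highest candidate orders are kept.  A flat profile
    (all differences zero) yields no candidates.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != N_MAX - N_MIN + 1:
        raise ValueError(f"expected {N_MAX - N_MIN + 1} profile values")
    d = np.diff(values)                  # d[i] = d(n) with n = N_MIN + i
    theta = float(np.mean(np.abs(d)))
    if theta == 0.0:
        return []
    found: dict[int, Candidate] = {}
    for i, dn in enumerate(d):
        n = N_MIN + i
        if dn > theta and (i == 0 or abs(d[i - 1]) <= theta):
            found.setdefault(n, Candidate(n, "step"))
        if i >= 1 and -d[i - 1] > theta and dn > theta:
            found.setdefault(n, Candidate(n, "local_minimum"))
    kept = sorted(found)[-2:]
    return [found[n] for n in kept]


def select_n(profile: ChoosynProfile) -> tuple[int, dict]:
    """Reconcile the two parameters' candidates into one selected order.

    Rule 1: a common candidate order wins (two common orders: the one with
    the smaller combined profile value; exact tie: the smaller order).
    Rule 2: no common order — the candidate (from either side) minimizing
    ChoOSyn_W(n) + ChoOSyn_C(n) wins.  If neither side produced candidates
    the order minimizing the combined profile over 2..8 is returned with a
    fallback flag.
    """
    cand_w = detect_candidates(profile.choosyn_w)
    cand_c = detect_candidates(profile.choosyn_c)
    total = profile.choosyn_w + profile.choosyn_c

    def combined(n: int) -> float:
        return float(total[n - N_MIN])

    w_ns = {c.n for c in cand_w}
    c_ns = {c.n for c in cand_c}
    diagnostics = {
        "candidates_w": [(c.n, c.kind) for c in cand_w],
        "candidates_c": [(c.n, c.kind) for c in cand_c],
        "fallback": False,
    }
    common = sorted(w_ns & c_ns)
    if common:
        chosen = min(common, key=lambda n: (combined(n), n))
        diagnostics["rule"] = "common"
    elif w_ns | c_ns:
        chosen = min(sorted(w_ns | c_ns), key=lambda n: (combined(n), n))
        diagnostics["rule"] = "lowest_sum"
    else:
        chosen = int(profile.n_values[int(np.argmin(total))])
        diagnostics["rule"] = "fallback_argmin"
        diagnostics["fallback"] = True
    diagnostics["combined_profile"] = total.tolist()
    return int(chosen), diagnostics
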