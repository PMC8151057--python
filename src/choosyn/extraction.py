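"""Synergy extraction: ANLS-NMF per subgroup and cross-subgroup sorting.

Each 10-cycle envelope subgroup ``V`` (muscles x 10,000) is factorized as
``V ~ W @ C`` with non-negative ``W`` (muscles x n) and ``C`` (n x 10,000)
by alternating exact non-negative least-squares block updates (block
principal pivoting), restarted from several random initializations and
keeping the best.  Coefficients are then averaged over the 10 cycles to a
single 1000-sample profile, and synergies are matched across subgroups by
k-means clustering of the weight columns under cosine distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._nnls import fresh_state, nnls_bpp
from .errors import ClusteringDomainError, OrderExceedsMusclesError
from .preprocessing import SubgroupEnvelopes
from .selection_vaf import vaf

__all__ = [
    "NmfParams",
    "FactorizationResult",
    "SortedOrder",
    "SynergyStack",
    "nmf_anls",
    "average_coefficients",
    "extract_all",
    "sort_synergies",
    "build_synergy_stack",
    "cosine_kmeans",
]


@dataclass(frozen=True)
class NmfParams:
    """Stopping rules and restart policy of the alternating NNLS solver.

    ``tol_residual`` bounds the relative Frobenius residual
    ``||V - WC|| / ||V||``; ``tol_change`` bounds both the largest relative
    change of any factor entry and the relative residual improvement
    between successive iterations (whichever triggers first stops the run).
    ``decimate`` > 1 fits the factors on every k-th time sample (envelopes
    are 12 Hz low-passed, so they are heavily oversampled at 1000 samples
    per cycle) and then solves the full-resolution coefficients exactly,
    once, with the fitted weights held fixed.
    """

    max_iter: int = 1000
    reruns: int = 5
    tol_residual: float = 1e-6
    tol_change: float = 1e-6
    decimate: int = 1


@dataclass
class FactorizationResult:
    """Best-of-restarts NMF solution for one (subgroup, order) pair.

    ``W`` columns are normalized to unit Euclidean norm with the inverse
    scaling absorbed into the rows of ``C`` (NMF scale indeterminacy fix).
    ``residual`` is the Frobenius reconstruction error of the kept restart.
    """

    order_n: int
    subgroup_index: int
    W: np.ndarray
    C_full: np.ndarray
    C_avg: np.ndarray | None
    residual: float
    rerun_errors: list[float]
    vaf_percent: float | None = None


def _anls_single(V: np.ndarray, n: int, rng: np.random.Generator,
                 params: NmfParams) -> tuple[np.ndarray, np.ndarray, float]:
    m, t_len = V.shape
    W = rng.uniform(size=(m, n))
    Vt = np.ascontiguousarray(V.T)
    norm_v2 = float((V * V).sum())
    norm_v = np.sqrt(norm_v2)
    C, FC = fresh_state(n, t_len)
    Wt, FW = fresh_state(n, m)
    prev_res = np.inf
    prev_w = W
    prev_c = None
    for _ in range(params.max_iter):
        WtW = np.ascontiguousarray(W.T @ W)
        WtV = np.ascontiguousarray(W.T @ V)
        nnls_bpp(WtW, WtV, C, FC)
        CCt = np.ascontiguousarray(C @ C.T)
        CVt = np.ascontiguousarray(C @ Vt)
        nnls_bpp(CCt, CVt, Wt, FW)
        W = Wt.T
        res2 = norm_v2 - 2.0 * float(np.sum(CVt * Wt)) \
            + float(np.sum((W.T @ W) * CCt))
        res = np.sqrt(max(res2, 0.0)) / norm_v
        if res < params.tol_residual:
            break
        dw = np.abs(W - prev_w).max() / max(np.abs(prev_w).max(), 1e-300)
        dc = (np.abs(C - prev_c).max() / max(np.abs(prev_c).max(), 1e-300)
              if prev_c is not None else np.inf)
        if max(dw, dc) < params.tol_change:
            break
        if prev_res - res < params.tol_change * max(res, 1e-300):
            break
        prev_res = res
        prev_w = W.copy()
        prev_c = C.copy()
    return W, C.copy(), res * norm_v


def _solve_coefficients(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Exact NNLS solve of C given fixed W (used after decimated fits)."""
    n = W.shape[1]
    C, F = fresh_state(n, V.shape[1])
    nnls_bpp(np.ascontiguousarray(W.T @ W), np.ascontiguousarray(W.T @ V), C, F)
    return C


def nmf_anls(V: np.ndarray, order_n: int, seed: int = 0,
             params: NmfParams | None = None,
             subgroup_index: int = 0) -> FactorizationResult:
    """Best-of-restarts alternating-NNLS factorization of one subgroup.

    Restart ``r`` is initialized from ``default_rng(seed + r)``; the restart
    with the smallest Frobenius residual is returned.
    """
    params = params or NmfParams()
    V = np.asarray(V, dtype=float)
    m = V.shape[0]
    if order_n > m:
        raise OrderExceedsMusclesError(
            f"order_n={order_n} exceeds number of muscles m={m}")
    if order_n < 1:
        raise ValueError("order_n must be >= 1")
    if (V < 0).any():
        raise ValueError("input matrix must be non-negative")

    V_fit = V[:, ::params.decimate] if params.decimate > 1 else V
    best = None
    errors = []
    for r in range(params.reruns):
        W, C, _ = _anls_single(V_fit, order_n,
                               np.random.default_rng(seed + r), params)
        if params.decimate > 1:
            C = _solve_coefficients(V, W)
        err = float(np.linalg.norm(V - W @ C))
        errors.append(err)
        if best is None or err < best[2]:
            best = (W, C, err)
    W, C, err = best

    # unit-norm weight columns, compensating row scaling of C
    norms = np.linalg.norm(W, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    W = W / scale
    C = C * scale[:, None]
    c_avg = average_coefficients(C) if C.shape[1] == 10_000 else None
    return FactorizationResult(order_n=order_n, subgroup_index=subgroup_index,
                               W=W, C_full=C, C_avg=c_avg, residual=err,
                               rerun_errors=errors)


def average_coefficients(C_full: np.ndarray) -> np.ndarray:
    """Average a 10-cycle coefficient matrix over its 1000-sample windows."""
    n, t_len = C_full.shape
    if t_len != 10_000:
        raise ValueError(f"expected 10,000 samples, got {t_len}")
    return C_full.reshape(n, 10, 1000).mean(axis=1)


def extract_all(subs: SubgroupEnvelopes, n_range: tuple[int, int] = (1, 8),
                seed: int = 0,
                params: NmfParams | None = None) -> list[FactorizationResult]:
    """Factorize every subgroup at every candidate order, with VAF.

    The restart seed of each (subgroup, order) pair is derived
    deterministically from the master seed so the full sweep is
    reproducible.
    """
    params = params or NmfParams()
    n_lo, n_hi = n_range
    if n_lo < 1 or n_hi > subs.n_muscles:
        raise OrderExceedsMusclesError(
            f"n_range {n_range} outside [1, {subs.n_muscles}]")
    results = []
    for j, V in enumerate(subs.subgroups):
        for n in range(n_lo, n_hi + 1):
            sub_seed = int(np.random.SeedSequence(
                (seed, j, n)).generate_state(1)[0] % (2 ** 31))
            res = nmf_anls(V, n, seed=sub_seed, params=params, subgroup_index=j)
            res.vaf_percent = vaf(V, res.W @ res.C_full)
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# cosine k-means and cross-subgroup sorting
# ---------------------------------------------------------------------------

def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ClusteringDomainError("zero-norm vector in cosine computation")
    return X / norms


def cosine_kmeans(X: np.ndarray, k: int, seed: int = 0, replicas: int = 15,
                  max_iter: int = 100_000,
                  init_centroids: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means with distance 1 - cosine similarity.

    Centroids are arithmetic means of their (raw) members; cosine distance
    is scale-invariant so they are not re-normalized.  With
    ``init_centroids`` given, a single run starts from those centroids;
    otherwise ``replicas`` seeded random restarts keep the solution with
    the smallest total within-cluster distance.  Empty clusters are
    re-seeded with the point farthest from its current centroid.
    """
    X = np.asarray(X, dtype=float)
    n_pts = X.shape[0]
    if k > n_pts:
        raise ValueError("more clusters than points")
    Xu = _unit_rows(X)
    rng = np.random.default_rng(seed)
    best = None
    runs = 1 if init_centroids is not None else replicas
    for _ in range(runs):
        if init_centroids is not None:
            cents = np.array(init_centroids, dtype=float)
        else:
            cents = X[rng.choice(n_pts, size=k, replace=False)]
        labels = np.full(n_pts, -1)
        for _ in range(max_iter):
            cu = _unit_rows(cents)
            dist = 1.0 - Xu @ cu.T                 # (n_pts, k)
            new_labels = np.argmin(dist, axis=1)
            # empty-cluster repair: move the worst-fitting point, repeat
            # until every cluster is occupied
            while True:
                empties = [c for c in range(k) if not (new_labels == c).any()]
                if not empties:
                    break
                c = empties[0]
                movable = np.where(np.bincount(new_labels, minlength=k)
                                   [new_labels] > 1)[0]
                far = movable[np.argmax(dist[movable, new_labels[movable]])]
                new_labels[far] = c
                dist[far, :] = np.inf
                dist[far, c] = 0.0
            if (new_labels == labels).all():
                break
            labels = new_labels
            cents = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
        cu = _unit_rows(cents)
        inertia = float((1.0 - (Xu * cu[labels]).sum(axis=1)).sum())
        if best is None or inertia < best[2]:
            best = (labels.copy(), cents.copy(), inertia)
    return best


def _assign_one_to_one(W_cols: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Permutation mapping each synergy column to a distinct cluster.

    Exhaustive search over all permutations (n <= 8) minimizing the total
    cosine distance between columns and their assigned centroids.
    """
    n = W_cols.shape[1]
    cost = 1.0 - _unit_rows(W_cols.T) @ _unit_rows(centroids).T     # (n, n)
    perms = np.array(list(itertools.permutations(range(n))))
    totals = cost[np.arange(n)[None, :], perms].sum(axis=1)
    return perms[int(np.argmin(totals))]


@dataclass
class SortedOrder:
    """Synergies of one candidate order, matched across subgroups.

    ``weights[j][:, i]`` and ``coeffs[j][i]`` refer to the same synergy i
    in every subgroup j; centroids are arithmetic means over subgroups.
    """

    order_n: int
    weights: list[np.ndarray]          # per subgroup, (m, n)
    coeffs: list[np.ndarray]           # per subgroup, (n, 1000)
    centroid_w: np.ndarray             # (m, n)
    centroid_c: np.ndarray             # (n, 1000)


def sort_synergies(results: list[FactorizationResult], order_n: int,
                   seed: int = 0, replicas: int = 15,
                   max_iter: int = 100_000) -> SortedOrder:
    """Match one order's synergies across subgroups via cosine k-means.

    All subgroups' weight columns are pooled and clustered (k = order_n);
    within each subgroup, synergies are assigned one-to-one to clusters
    (ties and double occupancy resolved by the optimal assignment), and
    the averaged coefficients are re-ordered accordingly.
    """
    group = sorted((r for r in results if r.order_n == order_n),
                   key=lambda r: r.subgroup_index)
    if order_n < 2:
        raise ValueError("sorting requires order_n >= 2")
    if not group:
        raise ValueError(f"no factorization results at order {order_n}")
    pooled = np.concatenate([r.W.T for r in group], axis=0)    # (J*n, m)
    if (np.linalg.norm(pooled, axis=1) == 0).any():
        raise ClusteringDomainError("all-zero weight column cannot be sorted")
    _, centroids, _ = cosine_kmeans(pooled, order_n, seed=seed,
                                    replicas=replicas, max_iter=max_iter)
    weights, coeffs = [], []
    for r in group:
        perm = _assign_one_to_one(r.W, centroids)
        inv = np.empty(order_n, dtype=int)
        inv[perm] = np.arange(order_n)             # synergy placed at its cluster
        weights.append(r.W[:, inv])
        coeffs.append(r.C_avg[inv] if r.C_avg is not None
                      else average_coefficients(r.C_full)[inv])
    centroid_w = np.mean(weights, axis=0)
    centroid_c = np.mean(coeffs, axis=0)
    return SortedOrder(order_n=order_n, weights=weights, coeffs=coeffs,
                       centroid_w=centroid_w, centroid_c=centroid_c)


@dataclass
class SynergyStack:
    """Sorted synergies for orders 2..8 plus per-order VAF values."""

    orders: dict[int, SortedOrder] = field(default_factory=dict)
    vaf_per_subgroup: dict[int, list[float]] = field(default_factory=dict)

    @property
    def n_values(self) -> list[int]:
        return sorted(self.orders)


def build_synergy_stack(results: list[FactorizationResult],
                        seed: int = 0, replicas: int = 15) -> SynergyStack:
    """Sort every order >= 2 and collect the per-subgroup VAF table."""
    stack = SynergyStack()
    orders = sorted({r.order_n for r in results})
    for n in orders:
        group = sorted((r for r in results if r.order_n == n),
                       key=lambda r: r.subgroup_index)
        stack.vaf_per_subgroup[n] = [r.vaf_percent for r in group]
        if n >= 2:
            stack.orders[n] = sort_synergies(results, n, seed=seed,
                                             replicas=replicas)
    return stack
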