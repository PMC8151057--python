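"""Vectorized non-negative least squares via block principal pivoting.

Solves ``min ||A X - B||_F  s.t.  X >= 0`` column by column, given the
normal-equation products ``AtA = A.T @ A`` and ``AtB = A.T @ B``.  Columns
sharing the same passive set are solved together through a single Cholesky
factorization, which keeps the cost low for the many-column coefficient
update of the alternating NMF solver.  The passive-set matrix can be warm
started from a previous call, which collapses the pivoting to a single
refinement pass once the alternating iterations stabilize.

The exchange rule follows the full-exchange strategy with a backup
single-index rule (Kim & Park style) to guarantee finite termination.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nnls_bpp", "fresh_state"]


def fresh_state(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Allocate a cold-start solution/passive-set pair for ``nnls_bpp``.

    Starting all-passive means the first inner solve is the unconstrained
    least-squares solution, from which pivoting proceeds.
    """
    return np.zeros((n, k)), np.ones((n, k), dtype=np.bool_)


@njit(cache=True)
def nnls_bpp(AtA, AtB, X, F, max_outer=100):  # pragma: no cover - jitted
    """Block-principal-pivoting NNLS on normal equations, in place.

    Parameters
    ----------
    AtA : (n, n) float64, symmetric positive (semi-)definite.
    AtB : (n, K) float64.
    X : (n, K) float64, warm-start solution, overwritten with the result.
    F : (n, K) bool, warm-start passive sets, overwritten.
    """
    n, K = AtB.shape
    alpha = np.full(K, 3, np.int64)
    beta = np.full(K, n + 1, np.int64)
    stale = np.ones(K, np.bool_)
    tol = 1e-12

    codes = np.empty(K, np.int64)
    order = np.empty(K, np.int64)
    idx = np.empty(n, np.int64)
    L = np.zeros((n, n))
    y = np.empty(n)

    for _ in range(max_outer):
        # --- solve the passive-set least squares for stale columns,
        #     grouped by identical passive-set pattern ---
        cnt = 0
        for k in range(K):
            if stale[k]:
                c = 0
                for i in range(n):
                    if F[i, k]:
                        c |= 1 << i
                codes[cnt] = c
                order[cnt] = k
                cnt += 1
        if cnt > 0:
            so = np.argsort(codes[:cnt], kind="mergesort")
            prev_code = -1
            nf = 0
            for t in range(cnt):
                k = order[so[t]]
                c = codes[so[t]]
                if c == 0:
                    for i in range(n):
                        X[i, k] = 0.0
                    continue
                if c != prev_code:
                    nf = 0
                    for i in range(n):
                        if F[i, k]:
                            idx[nf] = i
                            nf += 1
                    # Cholesky of the masked Gram matrix; the tiny jitter
                    # floor guards rank-deficient passive sets.
                    for i in range(nf):
                        for j in range(i + 1):
                            s = AtA[idx[i], idx[j]]
                            for q in range(j):
                                s -= L[i, q] * L[j, q]
                            if i == j:
                                L[i, i] = np.sqrt(max(s, 1e-300))
                            else:
                                L[i, j] = s / L[j, j]
                    prev_code = c
                for i in range(nf):
                    s = AtB[idx[i], k]
                    for q in range(i):
                        s -= L[i, q] * y[q]
                    y[i] = s / L[i, i]
                for i in range(n):
                    X[i, k] = 0.0
                for i in range(nf - 1, -1, -1):
                    s = y[i]
                    for q in range(i + 1, nf):
                        s -= L[q, i] * X[idx[q], k]
                    X[idx[i], k] = s / L[i, i]
            for k in range(K):
                stale[k] = False

        # --- KKT check and pivoting ---
        Y = AtA @ X - AtB
        done = True
        for k in range(K):
            nbad = 0
            worst = -1
            for i in range(n):
                bad = (F[i, k] and X[i, k] < -tol) or (
                    (not F[i, k]) and Y[i, k] < -tol
                )
                if bad:
                    nbad += 1
                    worst = i
            if nbad == 0:
                continue
            done = False
            if nbad < beta[k]:
                beta[k] = nbad
                alpha[k] = 3
                flip_all = True
            elif alpha[k] >= 1:
                alpha[k] -= 1
                flip_all = True
            else:
                flip_all = False
            if flip_all:
                for i in range(n):
                    bad = (F[i, k] and X[i, k] < -tol) or (
                        (not F[i, k]) and Y[i, k] < -tol
                    )
                    if bad:
                        F[i, k] = not F[i, k]
            else:
                F[worst, k] = not F[worst, k]
            stale[k] = True
        if done:
            break

    for k in range(K):
        for i in range(n):
            if X[i, k] < 0.0:
                X[i, k] = 0.0
    return X
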