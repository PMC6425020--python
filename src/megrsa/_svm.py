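"""Linear max-margin (soft-margin SVM) solver for tiny pairwise problems.

The decoding stage solves millions of identically-shaped two-class problems
(a handful of pseudo-trials per class), so the dual QP is solved directly
with a compiled SMO loop instead of going through a general-purpose fitting
API.  The solver replicates the standard libsvm conventions: box constraint
0 <= alpha <= C, equality constraint sum(alpha * y) = 0, and the bias taken
as the mean KKT residual over free support vectors (midpoint of the feasible
interval when none is free).  Predictions use sign(decision) with decision
values <= 0 assigned to the negative class, so fully degenerate problems
score exactly chance on balanced test sets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_BOUND = 1e-9
# working tolerance on the dual variables; decision values agree with a
# tightly-converged solve (and with libsvm) to ~1e-5, far from any tie
_DEFAULT_TOL = 1e-6
_MAX_SWEEPS = 60


@njit(cache=False)
def _smo_solve(K, y, C, tol, max_sweeps, alpha, f):
    """Solve the dual SVM QP in place; returns the bias term.

    ``K`` is the train Gram matrix, ``y`` the +/-1 labels.  ``alpha`` and
    ``f`` (the cached margins ``f_i = sum_k alpha_k y_k K_ik``) are caller
    scratch buffers of length n.
    """
    n = K.shape[0]
    for i in range(n):
        alpha[i] = 0.0
        f[i] = 0.0
    for _ in range(max_sweeps):
        max_change = 0.0
        for i in range(n - 1):
            for j in range(i + 1, n):
                e_i = f[i] - y[i]
                e_j = f[j] - y[j]
                s = y[i] * y[j]
                if s < 0.0:
                    lo = max(0.0, alpha[j] - alpha[i])
                    hi = min(C, C + alpha[j] - alpha[i])
                else:
                    lo = max(0.0, alpha[i] + alpha[j] - C)
                    hi = min(C, alpha[i] + alpha[j])
                if hi - lo < 1e-14:
                    continue
                eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
                if eta > 1e-12:
                    aj = alpha[j] + y[j] * (e_i - e_j) / eta
                else:
                    # objective is linear along the constraint line
                    slope = y[j] * (e_i - e_j)
                    if slope > 0.0:
                        aj = hi
                    elif slope < 0.0:
                        aj = lo
                    else:
                        continue
                if aj > hi:
                    aj = hi
                elif aj < lo:
                    aj = lo
                dj = aj - alpha[j]
                adj = dj if dj > 0.0 else -dj
                if adj < 1e-14:
                    continue
                di = -s * dj
                for k in range(n):
                    f[k] += di * y[i] * K[i, k] + dj * y[j] * K[j, k]
                alpha[i] += di
                alpha[j] = aj
                if adj > max_change:
                    max_change = adj
        if max_change < tol:
            break
    # bias: free-SV average, else midpoint of the KKT-feasible interval
    b_sum = 0.0
    n_free = 0
    b_low = -1e300
    b_up = 1e300
    for i in range(n):
        r = y[i] - f[i]
        if _EPS_BOUND < alpha[i] < C - _EPS_BOUND:
            b_sum += r
            n_free += 1
        else:
            at_zero = alpha[i] <= _EPS_BOUND
            if (y[i] > 0.0 and at_zero) or (y[i] < 0.0 and not at_zero):
                if r > b_low:
                    b_low = r
            else:
                if r < b_up:
                    b_up = r
    if n_free > 0:
        return b_sum / n_free
    return 0.5 * (b_low + b_up)


@njit(cache=False)
def decode_pairs_kernel(G, pairs_a, pairs_b, n_splits, C, tol, max_sweeps):
    """Leave-one-split-out CV accuracy for every (timepoint, condition pair).

    ``G`` is the ``[T, M, M]`` Gram matrix of sub-averaged pseudo-trials with
    pseudo-trial index ``condition * n_splits + split``.  Returns accuracies
    ``[T, n_pairs]`` (fraction of the ``2 * n_splits`` held-out pseudo-trials
    classified correctly).
    """
    T = G.shape[0]
    P = pairs_a.shape[0]
    S = n_splits
    n = 2 * (S - 1)
    m = 2 * S
    acc = np.zeros((T, P))
    idx = np.empty(n, dtype=np.int64)
    rows = np.empty(m, dtype=np.int64)
    y = np.empty(n)
    L = np.empty((m, m))          # pair-local Gram (both conditions' splits)
    K = np.empty((n, n))
    alpha = np.empty(n)
    f = np.empty(n)
    for h in range(S - 1):
        y[h] = 1.0
        y[S - 1 + h] = -1.0
    for t in range(T):
        for p in range(P):
            a = pairs_a[p]
            b = pairs_b[p]
            for s in range(S):
                rows[s] = a * S + s
                rows[S + s] = b * S + s
            for u in range(m):
                ru = rows[u]
                for v in range(m):
                    L[u, v] = G[t, ru, rows[v]]
            correct = 0
            for fold in range(S):
                pos = 0
                for s in range(S):
                    if s != fold:
                        idx[pos] = s
                        pos += 1
                for s in range(S):
                    if s != fold:
                        idx[pos] = S + s
                        pos += 1
                for u in range(n):
                    for v in range(n):
                        K[u, v] = L[idx[u], idx[v]]
                bias = _smo_solve(K, y, C, tol, max_sweeps, alpha, f)
                dec_a = bias
                dec_b = bias
                for u in range(n):
                    coef = alpha[u] * y[u]
                    dec_a += coef * L[idx[u], fold]
                    dec_b += coef * L[idx[u], S + fold]
                if dec_a > 0.0:
                    correct += 1
                if dec_b <= 0.0:
                    correct += 1
            acc[t, p] = correct / (2.0 * S)
    return acc


@njit(cache=False)
def temporal_generalization_kernel(P_train, P_all, pairs_a, pairs_b, n_splits, C, tol, max_sweeps):
    """Train at one time, test the held-out split at every time.

    ``P_train`` is ``[M, d]`` (pseudo-trials at the training time),
    ``P_all`` is ``[T_test, M, d]``.  Returns mean accuracy ``[T_test]``
    over pairs, folds and the two held-out pseudo-trials.
    """
    T = P_all.shape[0]
    d = P_train.shape[1]
    P = pairs_a.shape[0]
    S = n_splits
    n = 2 * (S - 1)
    correct = np.zeros(T)
    idx = np.empty(n, dtype=np.int64)
    y = np.empty(n)
    K = np.empty((n, n))
    alpha = np.empty(n)
    f = np.empty(n)
    w = np.empty(d)
    for h in range(S - 1):
        y[h] = 1.0
        y[S - 1 + h] = -1.0
    for p in range(P):
        a = pairs_a[p]
        b = pairs_b[p]
        for fold in range(S):
            pos = 0
            for s in range(S):
                if s != fold:
                    idx[pos] = a * S + s
                    pos += 1
            for s in range(S):
                if s != fold:
                    idx[pos] = b * S + s
                    pos += 1
            for u in range(n):
                for v in range(n):
                    acc = 0.0
                    for q in range(d):
                        acc += P_train[idx[u], q] * P_train[idx[v], q]
                    K[u, v] = acc
            bias = _smo_solve(K, y, C, tol, max_sweeps, alpha, f)
            for q in range(d):
                w[q] = 0.0
            for u in range(n):
                coef = alpha[u] * y[u]
                for q in range(d):
                    w[q] += coef * P_train[idx[u], q]
            ta = a * S + fold
            tb = b * S + fold
            for t in range(T):
                dec_a = bias
                dec_b = bias
                for q in range(d):
                    dec_a += w[q] * P_all[t, ta, q]
                    dec_b += w[q] * P_all[t, tb, q]
                if dec_a > 0.0:
                    correct[t] += 1.0
                if dec_b <= 0.0:
                    correct[t] += 1.0
    return correct / (2.0 * S * P)


def solve_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Solve one linear SVM problem; returns ``(alpha, bias)``.

    ``X`` is ``[n_samples, n_features]``, ``y`` in {-1, +1}.  The decision
    value for a point ``x`` is ``sum_k alpha_k y_k <x_k, x> + bias``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = X @ X.T
    n = X.shape[0]
    alpha = np.empty(n)
    f = np.empty(n)
    bias = _smo_solve(K, y, float(C), _DEFAULT_TOL, _MAX_SWEEPS, alpha, f)
    return alpha, float(bias)
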