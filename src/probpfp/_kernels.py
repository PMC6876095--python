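"""Log-space dynamic-programming kernels, numba-compiled.

All recursions run in log space with an explicit log-sum-exp, so partition
functions and pair-HMM lattices neither overflow nor underflow for any
realistic sequence length.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG = -np.inf


@njit(cache=True)
def _lse2(a, b):
    if a == NEG:
        return b
    if b == NEG:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def _lse3(a, b, c):
    return _lse2(_lse2(a, b), c)


@njit(cache=True)
def pf_forward_kernel(S, go, ge):
    """Three-state affine partition function over prefixes.

    S[i,j] = s(x_{i+1}, y_{j+1}) / T; go, ge are open/extend scores over T.
    States: M emits a match column, X a gap-in-y column (consumes x),
    Y a gap-in-x column (consumes y).  Adjacent mutual gaps are allowed in
    both orders, and switching gap direction re-opens (pays `go`).
    Returns log-space (n+1, m+1) matrices (M, X, Y); cell (i, j) sums over
    alignments of x[1..i] with y[1..j] ending in that column type.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                M[i, j] = S[i - 1, j - 1] + _lse3(
                    M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
                )
            if i > 0:
                X[i, j] = _lse2(go + _lse2(M[i - 1, j], Y[i - 1, j]),
                                ge + X[i - 1, j])
            if j > 0:
                Y[i, j] = _lse2(go + _lse2(M[i, j - 1], X[i, j - 1]),
                                ge + Y[i, j - 1])
    return M, X, Y


@njit(cache=True)
def hmm_forward_kernel(Em, Ex, Ey, lpi, ltr):
    """Pair-HMM forward lattice (log space), no explicit end state.

    Em[i,j] = log p(x_{i+1}, y_{j+1}); Ex, Ey = log q over each sequence.
    lpi = log initial distribution (M, X, Y); ltr = log transition matrix
    with ltr[X, Y] = ltr[Y, X] = -inf (gap-direction switches forbidden).
    """
    n = Ex.shape[0]
    m = Ey.shape[0]
    fM = np.full((n + 1, m + 1), NEG)
    fX = np.full((n + 1, m + 1), NEG)
    fY = np.full((n + 1, m + 1), NEG)
    for i in range(n + 1):
        for j in range(m + 1):
            if i >= 1 and j >= 1:
                acc = _lse3(fM[i - 1, j - 1] + ltr[0, 0],
                            fX[i - 1, j - 1] + ltr[1, 0],
                            fY[i - 1, j - 1] + ltr[2, 0])
                if i == 1 and j == 1:
                    acc = _lse2(acc, lpi[0])
                fM[i, j] = Em[i - 1, j - 1] + acc
            if i >= 1:
                acc = _lse2(fM[i - 1, j] + ltr[0, 1], fX[i - 1, j] + ltr[1, 1])
                if i == 1 and j == 0:
                    acc = _lse2(acc, lpi[1])
                fX[i, j] = Ex[i - 1] + acc
            if j >= 1:
                acc = _lse2(fM[i, j - 1] + ltr[0, 2], fY[i, j - 1] + ltr[2, 2])
                if i == 0 and j == 1:
                    acc = _lse2(acc, lpi[2])
                fY[i, j] = Ey[j - 1] + acc
    return fM, fX, fY


@njit(cache=True)
def hmm_backward_kernel(Em, Ex, Ey, ltr):
    """Pair-HMM backward lattice: log P(emit the rest | state at (i, j))."""
    n = Ex.shape[0]
    m = Ey.shape[0]
    bM = np.full((n + 1, m + 1), NEG)
    bX = np.full((n + 1, m + 1), NEG)
    bY = np.full((n + 1, m + 1), NEG)
    bM[n, m] = 0.0
    bX[n, m] = 0.0
    bY[n, m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            tm = NEG
            tx = NEG
            ty = NEG
            if i < n and j < m:
                tm = Em[i, j] + bM[i + 1, j + 1]
            if i < n:
                tx = Ex[i] + bX[i + 1, j]
            if j < m:
                ty = Ey[j] + bY[i, j + 1]
            bM[i, j] = _lse3(ltr[0, 0] + tm, ltr[0, 1] + tx, ltr[0, 2] + ty)
            bX[i, j] = _lse2(ltr[1, 0] + tm, ltr[1, 1] + tx)
            bY[i, j] = _lse2(ltr[2, 0] + tm, ltr[2, 2] + ty)
    return bM, bX, bY


@njit(cache=True)
def mea_kernel(P):
    """Maximal-expected-accuracy DP table.

    A[i,j] = max(A[i-1,j-1] + P[i-1,j-1], A[i-1,j], A[i,j-1]),
    A[0,.] = A[.,0] = 0.  Also used for profile-profile alignment, where P
    is the weighted column-score matrix.
    """
    n, m = P.shape
    A = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = A[i - 1, j - 1] + P[i - 1, j - 1]
            if A[i - 1, j] > best:
                best = A[i - 1, j]
            if A[i, j - 1] > best:
                best = A[i, j - 1]
            A[i, j] = best
    return A
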