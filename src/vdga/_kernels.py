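"""Numba-jitted numeric kernels.

One affine-gap dynamic-programming kernel serves both pairwise and
profile-profile alignment (a pairwise alignment is the 1x1-profile case);
the WSPM kernel scores all row pairs of an alignment via their
gap-gap-deleted projections.  Pure-python oracles in the test suite verify
these kernels independently.

Gap-cost convention throughout: a run of n gap positions costs g + n*x, so
the DP uses open-first cost ``go = g + x`` and extension ``ge = x``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e30

#: traceback moves
DIAG, UP, LEFT = 0, 1, 2


@njit(cache=True)
def affine_dp(S, go, ge):  # pragma: no cover - exercised via wrappers
    """Global affine-gap DP over a column-pair score matrix S (La x Lb).

    Returns (score, moves) where moves is the traceback path encoded as
    0=diagonal, 1=up (gap in the second profile), 2=left (gap in the first).
    Ties are broken diagonal > up > left for determinism.
    """
    La, Lb = S.shape
    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)  # ends consuming a column of a (gap in b)
    Y = np.full((La + 1, Lb + 1), _NEG)  # ends consuming a column of b (gap in a)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, Lb + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]
            a = M[i - 1, j] + go
            b = X[i - 1, j] + ge
            c = Y[i - 1, j] + go
            X[i, j] = max(a, max(b, c))
            a = M[i, j - 1] + go
            b = Y[i, j - 1] + ge
            c = X[i, j - 1] + go
            Y[i, j] = max(a, max(b, c))

    moves = np.empty(La + Lb, dtype=np.int8)
    pos = La + Lb
    i, j = La, Lb
    m_, x_, y_ = M[i, j], X[i, j], Y[i, j]
    score = max(m_, max(x_, y_))
    if m_ >= x_ and m_ >= y_:
        s = 0
    elif x_ >= y_:
        s = 1
    else:
        s = 2
    while i > 0 or j > 0:
        if i == 0:
            s = 2
        elif j == 0:
            s = 1
        pos -= 1
        if s == 0:
            moves[pos] = DIAG
            m_, x_, y_ = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            if m_ >= x_ and m_ >= y_:
                s = 0
            elif x_ >= y_:
                s = 1
            else:
                s = 2
            i -= 1
            j -= 1
        elif s == 1:
            moves[pos] = UP
            t = X[i, j]
            if M[i - 1, j] + go == t:
                s = 0
            elif X[i - 1, j] + ge == t:
                s = 1
            else:
                s = 2
            i -= 1
        else:
            moves[pos] = LEFT
            t = Y[i, j]
            if M[i, j - 1] + go == t:
                s = 0
            elif Y[i, j - 1] + ge == t:
                s = 2
            else:
                s = 1
            j -= 1
    return score, moves[pos:]


@njit(cache=True)
def merge_profiles_kernel(A, B, Ca, Cb, M, go, ge, gap_byte):  # pragma: no cover
    """Align two profiles (byte matrices with per-column residue counts) and
    return the merged byte matrix, merged counts, and the DP score.

    The column-pair score is the mean cross-pair substitution score
    (gap-involving pairs score 0): S = Ca M Cb^T / (ka kb).
    """
    ka, La = A.shape
    kb, Lb = B.shape
    T = np.dot(Ca, M)  # (La, n_letters)
    S = np.dot(T, Cb.T) / (ka * kb)
    score, moves = affine_dp(S, go, ge)
    Lnew = moves.shape[0]
    out = np.full((ka + kb, Lnew), gap_byte, dtype=np.uint8)
    Cout = np.zeros((Lnew, M.shape[0]))
    ia = 0
    ib = 0
    for c in range(Lnew):
        mv = moves[c]
        if mv == DIAG:
            for r in range(ka):
                out[r, c] = A[r, ia]
            for r in range(kb):
                out[ka + r, c] = B[r, ib]
            for q in range(M.shape[0]):
                Cout[c, q] = Ca[ia, q] + Cb[ib, q]
            ia += 1
            ib += 1
        elif mv == UP:
            for r in range(ka):
                out[r, c] = A[r, ia]
            for q in range(M.shape[0]):
                Cout[c, q] = Ca[ia, q]
            ia += 1
        else:
            for r in range(kb):
                out[ka + r, c] = B[r, ib]
            for q in range(M.shape[0]):
                Cout[c, q] = Cb[ib, q]
            ib += 1
    return out, Cout, score


@njit(cache=True)
def wspm_kernel(mat, w, lut, g, x, gap_byte):  # pragma: no cover
    """Weighted sum-of-pairs over all row pairs of a byte matrix.

    For each unordered pair the gap-gap columns are skipped (projection);
    residue-residue columns add ``w_i*w_j*lut[a,b]`` to their original
    column's bucket; each maximal residue-vs-gap run of length n in the
    projection adds ``w_i*w_j*(g + n*x)`` to the gap total.
    """
    N, L = mat.shape
    per_col = np.zeros(L)
    gap_total = 0.0
    for i in range(N - 1):
        for j in range(i + 1, N):
            wij = w[i] * w[j]
            run = 0  # 0 none, 1 gap in row i, 2 gap in row j
            runlen = 0
            for col in range(L):
                a = mat[i, col]
                b = mat[j, col]
                ag = a == gap_byte
                bg = b == gap_byte
                if ag and bg:
                    continue
                if (not ag) and (not bg):
                    if run != 0:
                        gap_total += wij * (g + runlen * x)
                        run = 0
                        runlen = 0
                    per_col[col] += wij * lut[a, b]
                elif ag:
                    if run == 1:
                        runlen += 1
                    else:
                        if run == 2:
                            gap_total += wij * (g + runlen * x)
                        run = 1
                        runlen = 1
                else:
                    if run == 2:
                        runlen += 1
                    else:
                        if run == 1:
                            gap_total += wij * (g + runlen * x)
                        run = 2
                        runlen = 1
            if run != 0:
                gap_total += wij * (g + runlen * x)
    return per_col, gap_total
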