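"""Low-level dynamic-programming kernels (numba-compiled).

Both kernels operate on a precomputed position-specific score matrix so the
same code serves profile-vs-sequence scanning and profile-vs-profile merging.
Scores are floats in whatever unit the caller chose (bits for PSSM scans,
raw BLOSUM units for MSA construction); gap penalties are positive numbers.
"""
from __future__ import annotations

import numba
import numpy as np

__all__ = ["smith_waterman_score", "needleman_wunsch_ops"]

_NEG = -1e30


@numba.njit(cache=True, fastmath=False)
def smith_waterman_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score over a (rows x cols) match-score matrix.

    Affine gaps: opening a gap costs gap_open, each further step gap_extend.
    Returns 0.0 when no positive-scoring local alignment exists.
    """
    n, m = S.shape
    H = np.zeros(m + 1)
    F = np.full(m + 1, _NEG)
    best = 0.0
    for i in range(1, n + 1):
        diag = H[0]
        E = _NEG
        for j in range(1, m + 1):
            f = H[j] - gap_open
            fe = F[j] - gap_extend
            if fe > f:
                f = fe
            F[j] = f
            h = diag + S[i - 1, j - 1]
            if E > h:
                h = E
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            e = h - gap_open
            ee = E - gap_extend
            if ee > e:
                e = ee
            E = e
            if h > best:
                best = h
    return best


@numba.njit(cache=True, fastmath=False)
def needleman_wunsch_ops(S: np.ndarray, gap_open: float, gap_extend: float) -> np.ndarray:
    """Global affine-gap alignment path over a match-score matrix.

    Returns an int8 array of edit operations read 5'->3':
    0 = align row i with column j, 1 = gap in columns (consume a row),
    2 = gap in rows (consume a column). Ties prefer match, then row-gap:
    the tie-break is fixed so alignments are reproducible.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in columns (vertical)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in rows (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            p = M[i - 1, j - 1]
            q = X[i - 1, j - 1]
            r = Y[i - 1, j - 1]
            b = p
            if q > b:
                b = q
            if r > b:
                b = r
            M[i, j] = b + S[i - 1, j - 1]
            p = M[i - 1, j] - gap_open
            q = X[i - 1, j] - gap_extend
            X[i, j] = p if p >= q else q
            p = M[i, j - 1] - gap_open
            q = Y[i, j - 1] - gap_extend
            Y[i, j] = p if p >= q else q
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    # current layer: 0=M,1=X,2=Y
    layer = 0
    bestv = M[n, m]
    if X[n, m] > bestv:
        bestv = X[n, m]
        layer = 1
    if Y[n, m] > bestv:
        layer = 2
    while i > 0 or j > 0:
        if i == 0:
            ops[k] = 2
            k += 1
            j -= 1
            continue
        if j == 0:
            ops[k] = 1
            k += 1
            i -= 1
            continue
        if layer == 0:
            prev = M[i, j] - S[i - 1, j - 1]
            if abs(M[i - 1, j - 1] - prev) < 1e-9:
                nxt = 0
            elif abs(X[i - 1, j - 1] - prev) < 1e-9:
                nxt = 1
            else:
                nxt = 2
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            layer = nxt
        elif layer == 1:
            if abs(X[i, j] - (M[i - 1, j] - gap_open)) < 1e-9:
                nxt = 0
            else:
                nxt = 1
            ops[k] = 1
            k += 1
            i -= 1
            layer = nxt
        else:
            if abs(Y[i, j] - (M[i, j - 1] - gap_open)) < 1e-9:
                nxt = 0
            else:
                nxt = 2
            ops[k] = 2
            k += 1
            j -= 1
            layer = nxt
    return ops[:k][::-1].copy()
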