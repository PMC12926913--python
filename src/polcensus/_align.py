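"""Affine-gap Smith-Waterman of a position-specific score matrix vs a query.

The profile is a (columns x 21) score matrix (20 residues + X, in bits);
the DP is jit-compiled with numba.  Traceback pointers are returned so the
caller can recover the gap-aware column -> query-position mapping.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._refs import AA_INDEX

X_INDEX = 20


def encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, X_INDEX) for ch in seq], dtype=np.int64)


@njit(cache=True)
def _sw_profile(S, q, gap_open, gap_ext):
    m = S.shape[0]
    n = q.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), -1e30)
    F = np.full((m + 1, n + 1), -1e30)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 2
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 2
            diag = H[i - 1, j - 1] + S[i - 1, q[j - 1]]
            val = diag
            code = 1
            if E[i, j] > val:
                val = E[i, j]
                code = 2
            if F[i, j] > val:
                val = F[i, j]
                code = 3
            if val <= 0.0:
                val = 0.0
                code = 0
            H[i, j] = val
            ptrH[i, j] = code
            if val > best:
                best = val
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


def local_profile_align(S: np.ndarray, q: np.ndarray,
                        gap_open: float, gap_ext: float):
    """Best local alignment of profile `S` against encoded query `q`.

    Returns (score, pairs) where pairs is a list of (profile_column,
    query_position), both 1-based, for aligned (non-gap) positions in
    increasing order.
    """
    best, bi, bj, ptrH, ptrE, ptrF = _sw_profile(S, q, gap_open, gap_ext)
    pairs: list[tuple[int, int]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext = ptrE[i, j] == 2
            j -= 1
            state = "E" if ext else "H"
        else:
            ext = ptrF[i, j] == 2
            i -= 1
            state = "F" if ext else "H"
    pairs.reverse()
    return float(best), pairs
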