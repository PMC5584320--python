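"""Numba kernels for Smith-Waterman local alignment with affine gaps.

A gap of length k costs open + (k-1)*extend: the opening penalty is charged
on the first gap residue, the extension penalty on each additional one.
Sequences arrive as int8 index arrays into the scoring-matrix alphabet.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -10 ** 9


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_ext):
    """Optimal local alignment score (score only, linear memory)."""
    la, lb = a.shape[0], b.shape[0]
    h_row = np.zeros(lb + 1, dtype=np.int64)
    f_row = np.full(lb + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, la + 1):
        h_diag = h_row[0]
        h_left = 0
        e_left = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = max(h_left - gap_open, e_left - gap_ext)
            f = max(h_row[j] - gap_open, f_row[j] - gap_ext)
            h = h_diag + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = h_row[j]
            h_row[j] = h
            f_row[j] = f
            h_left = h
            e_left = e
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_align(a, b, sub, gap_open, gap_ext):
    """Full DP with traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_identical,
    alignment_length, mismatches, gap_opens); coordinates 1-based inclusive,
    all zeros when the optimal score is 0. The traced alignment ends at the
    first maximal cell in row-major order and the traceback prefers diagonal,
    then horizontal (gap in the query), then vertical moves.
    """
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    i, j = bi, bj
    n_ident = 0
    n_mismatch = 0
    n_cols = 0
    n_gap_opens = 0
    state = 0  # 0 = H, 1 = E (gap in query, move left), 2 = F (gap in subject, move up)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                n_cols += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            # one alignment column with a gap in the query, consuming b[j-1]
            n_cols += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                n_gap_opens += 1
                state = 0
            j -= 1
        else:
            # one alignment column with a gap in the subject, consuming a[i-1]
            n_cols += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                n_gap_opens += 1
                state = 0
            i -= 1
    return best, i + 1, bi, j + 1, bj, n_ident, n_cols, n_mismatch, n_gap_opens
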