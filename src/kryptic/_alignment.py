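"""Numba kernels: pairwise alignment and Markov-chain sequence sampling.

The alignment scoring scheme is deliberately minimal (match +1, mismatch
-1, gap -1, linear) so that an exhaustive oracle can reproduce it. Among
score-optimal alignments the one with the maximum number of matches is
chosen; terminal gap runs are excluded from the reported aligned columns.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# base codes: A=0 C=1 G=2 T=3 N=4 (N never matches anything, including N)
N_CODE = 4

GLOBAL = 0  # Needleman-Wunsch, terminal gaps penalized
LOCAL = 1  # Smith-Waterman, for extracting homologous regions


@njit(cache=False)
def nw_align(a: np.ndarray, b: np.ndarray, mode: int = 0):  # pragma: no cover - via wrapper
    """Pairwise alignment over uint8 code arrays.

    mode 0: global alignment with terminal gaps penalized like any other
    gap; terminal gap runs are excluded from the reported aligned columns.
    mode 1: local (maximal-scoring segment) alignment.

    Returns (matches, aligned_cols, a_start, a_end, b_start, b_end, score)
    with 0-based half-open coordinates of the aligned core.
    """
    n = a.shape[0]
    m = b.shape[0]
    local = mode == 1
    H = np.empty((n + 1, m + 1), np.int32)
    M = np.empty((n + 1, m + 1), np.int32)
    H[0, 0] = 0
    M[0, 0] = 0
    for j in range(1, m + 1):
        H[0, j] = 0 if local else -j
        M[0, j] = 0
    for i in range(1, n + 1):
        H[i, 0] = 0 if local else -i
        M[i, 0] = 0
    best_h = 0
    best_m = 0
    ei = n
    ej = m
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if (ai == b[j - 1] and ai < N_CODE and b[j - 1] < N_CODE) else -1
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] - 1
            left = H[i, j - 1] - 1
            h = diag
            if up > h:
                h = up
            if left > h:
                h = left
            if local and h < 0:
                H[i, j] = 0
                M[i, j] = 0
                continue
            mm = -1
            if diag == h:
                mm = M[i - 1, j - 1] + (1 if s == 1 else 0)
            if up == h and M[i - 1, j] > mm:
                mm = M[i - 1, j]
            if left == h and M[i, j - 1] > mm:
                mm = M[i, j - 1]
            H[i, j] = h
            M[i, j] = mm
            if local and (h > best_h or (h == best_h and mm > best_m)):
                best_h = h
                best_m = mm
                ei = i
                ej = j

    if not local:
        ei = n
        ej = m
    elif best_h == 0:  # no positive-scoring segment at all
        return 0, 0, 0, 0, 0, 0, 0

    # traceback, staying consistent with the max-matches table
    moves = np.empty(n + m, np.uint8)  # 0=diag 1=up 2=left, recorded end->start
    ci = np.empty(n + m, np.int64)
    cj = np.empty(n + m, np.int64)
    i = ei
    j = ej
    k = 0
    # gap moves are preferred on ties so that optional gap runs land at the
    # alignment ends, where they are trimmed: a fragment fully contained in
    # a longer sequence then scores ~100% identity rather than having its
    # length deficit counted against it
    while i > 0 or j > 0:
        if local and H[i, j] == 0:
            break
        took = False
        if i > 0 and (j == 0 or (H[i - 1, j] - 1 == H[i, j] and M[i - 1, j] == M[i, j])):
            moves[k] = 1
            ci[k] = i
            cj[k] = j
            i -= 1
            k += 1
            took = True
        if not took and j > 0 and (i == 0 or (H[i, j - 1] - 1 == H[i, j] and M[i, j - 1] == M[i, j])):
            moves[k] = 2
            ci[k] = i
            cj[k] = j
            j -= 1
            k += 1
            took = True
        if not took:
            moves[k] = 0
            ci[k] = i
            cj[k] = j
            i -= 1
            j -= 1
            k += 1

    # moves[k-1] is the first alignment column; trim terminal gap runs
    lo = k - 1
    while lo >= 0 and moves[lo] != 0:
        lo -= 1
    hi = 0
    while hi < k and moves[hi] != 0:
        hi += 1
    if lo < hi:  # no diagonal column at all (degenerate)
        return 0, 0, 0, 0, 0, 0, H[ei, ej]

    matches = 0
    for t in range(hi, lo + 1):
        if moves[t] == 0:
            ii = ci[t]
            jj = cj[t]
            if a[ii - 1] == b[jj - 1] and a[ii - 1] < N_CODE and b[jj - 1] < N_CODE:
                matches += 1
    aligned_cols = lo - hi + 1
    a_start = ci[lo] - 1
    b_start = cj[lo] - 1
    a_end = ci[hi]
    b_end = cj[hi]
    return matches, aligned_cols, a_start, a_end, b_start, b_end, H[ei, ej]


@njit(cache=False)
def markov_chain(transitions_cum: np.ndarray, start_state: np.int64, uniforms: np.ndarray) -> np.ndarray:
    """Sample a base sequence from an order-3 Markov chain.

    transitions_cum: (64, 4) cumulative probabilities per 3-mer state;
    uniforms: pre-drawn U(0,1) of the desired sequence length.
    """
    n = uniforms.shape[0]
    out = np.empty(n, np.uint8)
    state = start_state
    for t in range(n):
        u = uniforms[t]
        b = 0
        while b < 3 and u > transitions_cum[state, b]:
            b += 1
        out[t] = b
        state = (state * 4 + b) % 64
    return out
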