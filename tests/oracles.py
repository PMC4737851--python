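"""Independent brute-force oracles used to validate the fast primitives.

These are deliberately naive re-derivations (tuple-lexicographic DP,
all-window scans, rank-then-Pearson) kept free of any code under test.
"""
from __future__ import annotations

import numpy as np


def oracle_align(a: str, b: str):
    """Global alignment by lexicographic (score, matches) DP: match +1,
    mismatch -1, gap -1, N never matches. Returns (score, matches,
    aligned_cols) with terminal gap runs excluded from aligned_cols."""
    n, m = len(a), len(b)
    F = [[None] * (m + 1) for _ in range(n + 1)]
    F[0][0] = (0, 0)
    for i in range(1, n + 1):
        F[i][0] = (-i, 0)
    for j in range(1, m + 1):
        F[0][j] = (-j, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
            s = 1 if is_match else -1
            F[i][j] = max(
                (F[i - 1][j - 1][0] + s, F[i - 1][j - 1][1] + (1 if is_match else 0)),
                (F[i - 1][j][0] - 1, F[i - 1][j][1]),
                (F[i][j - 1][0] - 1, F[i][j - 1][1]),
            )
    # traceback any lex-optimal path; gap moves preferred on ties (the
    # canonical policy: optional gap runs are pushed to the alignment ends)
    moves = []
    i, j = n, m
    while i > 0 or j > 0:
        target = F[i][j]
        if i > 0 and (j == 0 or (F[i - 1][j][0] - 1, F[i - 1][j][1]) == target):
            moves.append("U")
            i -= 1
            continue
        if j > 0 and (i == 0 or (F[i][j - 1][0] - 1, F[i][j - 1][1]) == target):
            moves.append("L")
            j -= 1
            continue
        moves.append("D")
        i, j = i - 1, j - 1
    moves.reverse()
    first = next((k for k, mv in enumerate(moves) if mv == "D"), None)
    if first is None:
        return F[n][m][0], 0, 0
    last = max(k for k, mv in enumerate(moves) if mv == "D")
    return F[n][m][0], F[n][m][1], last - first + 1


def oracle_identity(a: str, b: str) -> float:
    score, matches, cols = oracle_align(a, b)
    return 100.0 * matches / cols if cols else 0.0


_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_scan(query: str, subject: str, max_mismatches: int):
    """All-window Hamming scan of query and its reverse complement against
    the subject; N always mismatches. Returns sorted (pos, strand, mm)."""
    hits = []
    for strand, q in (("+", query), ("-", query.translate(_COMP)[::-1])):
        for pos in range(len(subject) - len(q) + 1):
            window = subject[pos : pos + len(q)]
            mm = sum(
                1 for x, y in zip(q, window) if x != y or x == "N" or y == "N"
            )
            if mm <= max_mismatches:
                hits.append((pos, strand, mm))
    return sorted(hits)


def oracle_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (average ranks for ties) then Pearson."""

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_primer_best_site(primer_sets: list[set], target: str):
    """Minimum mismatch count of a degenerate primer (given as a list of
    per-position base sets, already oriented) over all windows of target."""
    q = len(primer_sets)
    best = None
    for pos in range(len(target) - q + 1):
        mm = sum(
            1 for k in range(q) if target[pos + k] not in primer_sets[k]
        )
        if best is None or mm < best:
            best = mm
    return best
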