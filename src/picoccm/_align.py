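"""Numba dynamic-programming kernels for local protein alignment.

Two kernels share the same three-state affine-gap recursion (match state M,
gap-in-target E consuming query, gap-in-query F consuming target):

* ``sw_kernel`` — pairwise Smith-Waterman under a substitution matrix.
* ``profile_kernel`` — query against a per-column log-odds profile.

A gap of length k costs ``gap_open + k * gap_extend`` (BLAST-style gap
existence + per-residue extension). Alignments end in the match state; the
best cell is chosen with a strict ``>`` while scanning (target_end,
query_end) in ascending lexicographic order, which makes the reported
alignment deterministic: ties resolve to the smallest (target_end, query_end).
"""
from __future__ import annotations

import numpy as np
from numba import njit

#: Alphabet of the packaged substitution matrices (BLOSUM62 without '*').
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
_X = _CODE["X"]


def encode(seq: str) -> np.ndarray:
    """Map an amino-acid string to integer codes; unknown residues become X."""
    return np.array([_CODE.get(c, _X) for c in seq.upper()], dtype=np.int64)


@njit(cache=False)
def sw_kernel(q, t, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    pm = np.zeros((m + 1, n + 1), dtype=np.int8)
    pe = np.zeros((m + 1, n + 1), dtype=np.int8)
    pf = np.zeros((m + 1, n + 1), dtype=np.int8)
    go = gap_open + gap_extend

    best = NEG
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # E: gap in target, consumes q[j-1]
            open_e = M[i, j - 1] - go
            ext_e = E[i, j - 1] - gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                pe[i, j] = 1
            else:
                E[i, j] = ext_e
                pe[i, j] = 2
            # F: gap in query, consumes t[i-1]
            open_f = M[i - 1, j] - go
            ext_f = F[i - 1, j] - gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                pf[i, j] = 1
            else:
                F[i, j] = ext_f
                pf[i, j] = 3
            # M: align q[j-1] with t[i-1]
            prev = 0.0
            ptr = 0
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
                ptr = 1
            if E[i - 1, j - 1] > prev:
                prev = E[i - 1, j - 1]
                ptr = 2
            if F[i - 1, j - 1] > prev:
                prev = F[i - 1, j - 1]
                ptr = 3
            s = sub[t[i - 1], q[j - 1]]
            M[i, j] = s + prev
            pm[i, j] = ptr
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j

    # traceback from (bi, bj) in state M
    matches = 0
    columns = 0
    q_cols = 0
    i = bi
    j = bj
    state = 1  # 1 = M, 2 = E, 3 = F
    q_start = bj
    t_start = bi
    while True:
        if state == 1:
            columns += 1
            q_cols += 1
            if t[i - 1] == q[j - 1]:
                matches += 1
            nxt = pm[i, j]
            i -= 1
            j -= 1
            q_start = j
            t_start = i
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            columns += 1
            q_cols += 1
            nxt = pe[i, j]
            j -= 1
            q_start = j
            state = nxt
        else:
            columns += 1
            nxt = pf[i, j]
            i -= 1
            t_start = i
            state = nxt

    return best, q_start, bj, t_start, bi, matches, columns, q_cols


@njit(cache=False)
def profile_kernel(q, prof, gap_open, gap_extend):  # pragma: no cover - jitted
    """Local alignment of query codes against profile ``prof`` (C x 23 bits).

    Returns (score, profile_cols_covered, query_cols, q_start, q_end,
    p_start, p_end).
    """
    n = q.shape[0]
    C = prof.shape[0]
    NEG = -1e30
    M = np.full((C + 1, n + 1), NEG)
    E = np.full((C + 1, n + 1), NEG)
    F = np.full((C + 1, n + 1), NEG)
    pm = np.zeros((C + 1, n + 1), dtype=np.int8)
    pe = np.zeros((C + 1, n + 1), dtype=np.int8)
    pf = np.zeros((C + 1, n + 1), dtype=np.int8)
    go = gap_open + gap_extend

    best = NEG
    bc = 0
    bj = 0
    for c in range(1, C + 1):
        for j in range(1, n + 1):
            open_e = M[c, j - 1] - go
            ext_e = E[c, j - 1] - gap_extend
            if open_e >= ext_e:
                E[c, j] = open_e
                pe[c, j] = 1
            else:
                E[c, j] = ext_e
                pe[c, j] = 2
            open_f = M[c - 1, j] - go
            ext_f = F[c - 1, j] - gap_extend
            if open_f >= ext_f:
                F[c, j] = open_f
                pf[c, j] = 1
            else:
                F[c, j] = ext_f
                pf[c, j] = 3
            prev = 0.0
            ptr = 0
            if M[c - 1, j - 1] > prev:
                prev = M[c - 1, j - 1]
                ptr = 1
            if E[c - 1, j - 1] > prev:
                prev = E[c - 1, j - 1]
                ptr = 2
            if F[c - 1, j - 1] > prev:
                prev = F[c - 1, j - 1]
                ptr = 3
            M[c, j] = prof[c - 1, q[j - 1]] + prev
            pm[c, j] = ptr
            if M[c, j] > best:
                best = M[c, j]
                bc = c
                bj = j

    covered = 0
    q_cols = 0
    c = bc
    j = bj
    state = 1
    q_start = bj
    p_start = bc
    while True:
        if state == 1:
            covered += 1
            q_cols += 1
            nxt = pm[c, j]
            c -= 1
            j -= 1
            q_start = j
            p_start = c
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            q_cols += 1
            nxt = pe[c, j]
            j -= 1
            q_start = j
            state = nxt
        else:
            covered += 1
            nxt = pf[c, j]
            c -= 1
            p_start = c
            state = nxt

    return best, covered, q_cols, q_start, bj, p_start, bc
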