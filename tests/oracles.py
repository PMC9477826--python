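"""Independent reference implementations used only to check the package.

These are written for clarity, not speed, and deliberately share no code
with ``picoccm``: a plain-Python exhaustive affine-gap local-alignment DP,
set-arithmetic dissimilarity formulas, and closed-form binomial tails.
"""
from __future__ import annotations

import math

NEG = -1e30


def sw_oracle(query: str, target: str, sub, gap_open: float, gap_extend: float):
    """Exhaustive three-state local alignment DP over two short proteins.

    Returns (score, identity_pct, coverage_pct, aln_length). A gap of
    length k costs ``gap_open + k * gap_extend``. Tie conventions match the
    statements under test: best cell is the first maximum in ascending
    (target_end, query_end) order; within a cell, the match state is
    preferred over gap-in-target over gap-in-query, and opening a gap is
    preferred over extending at equal score.
    """
    n, m = len(query), len(target)
    go = gap_open + gap_extend

    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(M[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(M[i - 1][j] - go, F[i - 1][j] - gap_extend)
            prev = max(0.0, M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            M[i][j] = sub[target[i - 1]][query[j - 1]] + prev

    best, bi, bj = NEG, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j

    # traceback with the same preference order as the forward pass
    i, j, state = bi, bj, "M"
    matches = columns = q_cols = 0
    while True:
        if state == "M":
            columns += 1
            q_cols += 1
            if target[i - 1] == query[j - 1]:
                matches += 1
            prev = max(0.0, M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            i, j = i - 1, j - 1
            if prev == 0.0 and not (M[i][j] > 0 or E[i][j] > 0 or F[i][j] > 0):
                break
            if M[i][j] == prev:
                state = "M"
            elif E[i][j] == prev:
                state = "E"
            elif F[i][j] == prev:
                state = "F"
            else:
                break  # alignment started here
        elif state == "E":
            columns += 1
            q_cols += 1
            came_open = M[i][j - 1] - go
            came_ext = E[i][j - 1] - gap_extend
            state = "M" if came_open >= came_ext else "E"
            j -= 1
        else:
            columns += 1
            came_open = M[i - 1][j] - go
            came_ext = F[i - 1][j] - gap_extend
            state = "M" if came_open >= came_ext else "F"
            i -= 1
    return best, 100.0 * matches / columns, 100.0 * q_cols / n, columns


def kulczynski_oracle(x, y) -> float:
    """Direct evaluation of the binary Kulczynski dissimilarity."""
    a = sum(1 for u, v in zip(x, y) if u and v)
    b = sum(1 for u, v in zip(x, y) if u and not v)
    c = sum(1 for u, v in zip(x, y) if not u and v)
    if a + b == 0 and a + c == 0:
        return 0.0
    if a + b == 0 or a + c == 0:
        return 1.0
    return 1.0 - 0.5 * (a / (a + b) + a / (a + c))


def bray_curtis_oracle(x, y) -> float:
    num = sum(abs(u - v) for u, v in zip(x, y))
    den = sum(u + v for u, v in zip(x, y))
    return 0.0 if den == 0 else num / den


def binom_cdf(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))
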