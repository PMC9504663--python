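"""Independent brute-force oracles used only by the tests.

Each oracle is a deliberately naive implementation, independent of the
package's code paths: full dynamic-programming alignments and exhaustive
subset enumeration at tiny problem sizes.
"""

from __future__ import annotations

from itertools import combinations


def needleman_wunsch_identity(a: str, b: str,
                              match: int = 1, mismatch: int = -1,
                              gap: int = -2) -> float:
    """Percent identity of the optimal global alignment (full DP + traceback),
    identity counted over aligned columns including gaps."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            row[j] = max(diag, prev[j] + gap, row[j - 1] + gap)
    # traceback counting matches and columns
    i, j, matches, columns = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return 100.0 * matches / columns


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -1,
                   gap: int = -2):
    """Optimal local alignment of a (query) vs b (subject): full DP.

    Returns (score, identity_pct, aln_columns, b_start, b_end); all-zero
    matrix returns (0, 0.0, 0, 0, 0).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = max(
                0,
                prev[j - 1] + (match if ai == b[j - 1] else mismatch),
                prev[j] + gap,
                row[j - 1] + gap,
            )
            row[j] = s
            if s > best:
                best, bi, bj = s, i, j
    if best == 0:
        return 0, 0.0, 0, 0, 0
    i, j, matches, columns = bi, bj, 0, 0
    while i > 0 and j > 0 and H[i][j] > 0:
        if H[i][j] == H[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return best, 100.0 * matches / columns, columns, j, bj


def enumerate_local_hits(query: str, subject: str, *,
                         identity_gt: float, length_gt: int,
                         max_hits: int = 10):
    """Waterman-Eggert-style suboptimal hit enumeration.

    Repeatedly takes the optimal local alignment and masks its subject span
    with a non-matching symbol, until no alignment passes the thresholds.
    Returns (b_start, b_end) subject intervals of the passing hits.
    """
    sub = list(subject)
    hits = []
    for _ in range(max_hits):
        score, ident, cols, b_lo, b_hi = smith_waterman(query, "".join(sub))
        if score == 0 or cols <= length_gt or ident <= identity_gt:
            # also stop when remaining alignments cannot pass: a shorter or
            # less similar best alignment implies no further passing hit
            break
        hits.append((b_lo, b_hi))
        for j in range(b_lo, b_hi):
            sub[j] = "X"
    return hits


def brute_force_min_removal(order_a: list, order_b: list) -> int:
    """Minimum removals so the remaining orders are identical, by explicit
    subset enumeration over kept markers (largest kept set first)."""
    rank_a = {m: i for i, m in enumerate(order_a)}
    seq = [rank_a[m] for m in order_b]
    n = len(seq)
    for keep in range(n, 0, -1):
        for idx in combinations(range(n), keep):
            vals = [seq[i] for i in idx]
            if all(vals[i] < vals[i + 1] for i in range(len(vals) - 1)):
                return n - keep
    return n
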