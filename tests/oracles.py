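"""Independent reference implementations used as test oracles.

Deliberately written with different algorithms/loop orders than the package:
segment enumeration instead of a running-sum scan, recursive memoised DPs
instead of iterative table fills.  They are slow and only run on tiny
instances.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(100_000)


def brute_maxss(scores) -> tuple[float, tuple[int, int]]:
    """Max-scoring subsequence by O(n^2) enumeration of every segment
    (empty segment included), ties to smallest start then smallest end."""
    best, bounds = 0.0, (0, 0)
    n = len(scores)
    for i in range(n):
        tot = 0.0
        for j in range(i, n):
            tot += float(scores[j])
            if tot > best:
                best, bounds = tot, (i, j + 1)
    return best, bounds


def brute_best_ungapped(read, ref) -> float:
    """Best ungapped local alignment score over every window offset and both
    strands, via prefix-sum segment enumeration (vectorised over offsets)."""
    best = 0.0
    L = len(read)
    for strand in "+-":
        prof = read if strand == "+" else read.reverse_complement()
        code = np.asarray(ref.code_with_tail(L))
        win = np.lib.stride_tricks.sliding_window_view(code, L)[: ref.padded_length]
        series = prof.pssm[np.arange(L)[None, :], win]
        P = np.concatenate(
            [np.zeros((len(win), 1)), np.cumsum(series, axis=1)], axis=1
        )
        # segment (i, j] score = P[:, j] - P[:, i] for j >= i
        D = P[:, None, :] - P[:, :, None]
        iu = np.triu(np.ones((L + 1, L + 1), dtype=bool))
        best = max(best, float(D[:, iu].max()), 0.0)
    return best


def oracle_fit_linear(pssm: np.ndarray, rcode: np.ndarray, gap: float) -> float:
    """Fitting-alignment score (read end-to-end, free region end gaps),
    linear gap model, by recursive memoised DP."""
    n, m = pssm.shape[0], len(rcode)

    @lru_cache(maxsize=None)
    def H(i: int, j: int) -> float:
        if i == 0:
            return 0.0
        if j == 0:
            return i * gap
        return max(
            H(i - 1, j - 1) + pssm[i - 1, rcode[j - 1]],
            H(i - 1, j) + gap,
            H(i, j - 1) + gap,
        )

    return max(H(n, j) for j in range(m + 1))


def oracle_fit_affine(
    pssm: np.ndarray, rcode: np.ndarray, gap_open: float, gap_ext: float
) -> float:
    """Fitting-alignment score, affine gaps (open + (k-1)*extend), recursive
    Gotoh with memoised states."""
    n, m = pssm.shape[0], len(rcode)
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def V(i: int, j: int, state: str) -> float:
        # best score of aligning read[:i] against region[:j] ending in state
        if state == "M":
            if i == 0 or j == 0:
                return 0.0 if i == 0 else NEG
            sub = pssm[i - 1, rcode[j - 1]]
            return max(V(i - 1, j - 1, s) for s in "MXY") + sub
        if state == "X":  # gap in region, consumes read
            if i == 0:
                return NEG
            return max(
                max(V(i - 1, j, s) for s in "MXY") + gap_open,
                V(i - 1, j, "X") + gap_ext,
            )
        # state Y: gap in read, consumes region
        if j == 0 or i == 0:
            # i == 0: leading region positions are free, covered by M base case
            return NEG
        return max(
            max(V(i, j - 1, s) for s in "MXY") + gap_open,
            V(i, j - 1, "Y") + gap_ext,
        )

    best = NEG
    for j in range(m + 1):
        for s in "MXY":
            v = V(n, j, s)
            if v > best:
                best = v
    return best
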