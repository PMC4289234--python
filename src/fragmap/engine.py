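"""Phase-1 candidate scoring: maximum scoring subsequence over genome windows.

For every window offset s of the (padded) genome, the read induces a series
of substitution scores ``pssm[i, genome[s + i]]``.  The maximum scoring
subsequence (the contiguous segment with maximal sum, empty segment allowed
at score 0) of that series is the best ungapped local alignment of the read
at that offset.  Fragment f owns the windows starting inside it; those
windows are allowed to read into the following fragments so that reads
spanning a fragment junction are still fully scored.

The scan over all offsets is the hot loop of the mapper and is JIT-compiled
with numba; a vectorised NumPy fallback produces identical scores.  The fast
mode scores only every other read position (stride 2), halving the work per
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .reads import ReadProfile
from .reference import ReferenceIndex

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


STRANDS = ("+", "-")


def max_scoring_subsequence(scores: Sequence[float]) -> tuple[float, tuple[int, int]]:
    """Maximum scoring subsequence of a real series.

    Returns ``(score, (start, end))`` with a half-open interval.  The empty
    segment is allowed, so the score is never negative (all-negative input
    gives ``(0.0, (0, 0))``).  Ties are broken by smallest start, then
    smallest end.
    """
    best = 0.0
    bounds = (0, 0)
    run = 0.0
    run_start = 0
    for j, v in enumerate(scores):
        run += float(v)
        if run > best:
            best = run
            bounds = (run_start, j + 1)
        elif run < 0.0:
            run = 0.0
            run_start = j + 1
    return best, bounds


@njit(cache=True)
def _window_best_numba(code, pssm, read_len, stride, n_windows, out):  # pragma: no cover
    # Kadane per window.  The running-sum update is written with ternaries so
    # LLVM emits maxsd instead of data-dependent branches (the reset/record
    # branches are essentially random, and mispredictions dominate the loop
    # otherwise), and four windows are interleaved in scalar registers to
    # cover the floating-point latency chain.
    s0 = 0
    while s0 + 4 <= n_windows:
        r0 = r1 = r2 = r3 = 0.0
        b0 = b1 = b2 = b3 = 0.0
        for i in range(0, read_len, stride):
            row = pssm[i]
            t0 = r0 + row[code[s0 + i]]
            t1 = r1 + row[code[s0 + 1 + i]]
            t2 = r2 + row[code[s0 + 2 + i]]
            t3 = r3 + row[code[s0 + 3 + i]]
            r0 = t0 if t0 > 0.0 else 0.0
            r1 = t1 if t1 > 0.0 else 0.0
            r2 = t2 if t2 > 0.0 else 0.0
            r3 = t3 if t3 > 0.0 else 0.0
            b0 = b0 if b0 > r0 else r0
            b1 = b1 if b1 > r1 else r1
            b2 = b2 if b2 > r2 else r2
            b3 = b3 if b3 > r3 else r3
        out[s0] = b0
        out[s0 + 1] = b1
        out[s0 + 2] = b2
        out[s0 + 3] = b3
        s0 += 4
    for s in range(s0, n_windows):
        run = 0.0
        best = 0.0
        for i in range(0, read_len, stride):
            r = run + pssm[i, code[s + i]]
            run = r if r > 0.0 else 0.0
            best = best if best > run else run
        out[s] = best


def _window_best_numpy(code, pssm, read_len, stride, n_windows, out, block=16384):
    scored = np.arange(0, read_len, stride)
    for lo in range(0, n_windows, block):
        hi = min(lo + block, n_windows)
        win = np.lib.stride_tricks.sliding_window_view(
            code[lo : hi + read_len - 1], read_len
        )[: hi - lo]
        series = pssm[scored[None, :], win[:, scored]]
        run = np.zeros(hi - lo)
        best = np.zeros(hi - lo)
        for k in range(series.shape[1]):
            run = np.maximum(run + series[:, k], 0.0)
            np.maximum(best, run, out=best)
        out[lo:hi] = best


def window_best_scores(
    pssm: np.ndarray,
    code_ext: np.ndarray,
    n_windows: int,
    stride: int = 1,
    use_numba: bool = HAVE_NUMBA,
) -> np.ndarray:
    """Best maxss score of the read at every window offset ``0..n_windows-1``.

    *code_ext* must extend at least ``read_len`` codes past ``n_windows`` (the
    N tail supplied by :meth:`ReferenceIndex.code_with_tail`).
    """
    read_len = pssm.shape[0]
    if stride not in (1, 2):
        raise ParameterError(f"stride must be 1 or 2, got {stride}")
    out = np.empty(n_windows, dtype=np.float64)
    impl = _window_best_numba if use_numba else _window_best_numpy
    impl(code_ext, pssm, read_len, stride, n_windows, out)
    return out


def fragment_best(
    window_scores: np.ndarray, fragment_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce per-window scores to per-fragment (best score, window offset).

    The window array length must be a multiple of F (the padded genome
    length).  Ties within a fragment resolve to the smallest offset.
    """
    F = fragment_length
    nf = len(window_scores) // F
    grid = window_scores.reshape(nf, F)
    best = grid.max(axis=1)
    offs = grid.argmax(axis=1) + np.arange(nf, dtype=np.int64) * F
    return best, offs


@dataclass(frozen=True)
class FragmentHit:
    """Best ungapped placement of a read within one fragment's windows.

    ``subseq_bounds`` is a half-open interval into the list of scored read
    positions (all positions at stride 1; positions 0, 2, 4, ... at stride
    2); it is ``None`` when the bulk scan skipped bound recovery.
    """

    ref: str
    fragment_id: int
    strand: str
    window_offset: int
    score: float
    subseq_bounds: tuple[int, int] | None = None


def window_series(
    profile: ReadProfile, ref: ReferenceIndex, offset: int, stride: int = 1
) -> np.ndarray:
    """Substitution-score series of *profile* at genome window *offset*."""
    code = ref.code_with_tail(len(profile))
    scored = np.arange(0, len(profile), stride)
    return profile.pssm[scored, code[offset + scored]]


def scan_fragment(
    read: ReadProfile,
    ref: ReferenceIndex,
    fragment_id: int,
    strand: str = "+",
    stride: int = 1,
) -> FragmentHit:
    """Best window of one fragment for one strand (reference implementation).

    Slides the read over every window start inside the fragment; windows
    overflow into the following fragments (junction handling) and truncate at
    the padded genome end.  Ties break to the smallest window offset.
    """
    if not 0 <= fragment_id < ref.num_fragments:
        raise IndexError(f"fragment {fragment_id} out of range")
    prof = read if strand == "+" else read.reverse_complement()
    F = ref.fragment_length
    best_score, best_off, best_bounds = 0.0, fragment_id * F, (0, 0)
    for s in range(fragment_id * F, (fragment_id + 1) * F):
        score, bounds = max_scoring_subsequence(window_series(prof, ref, s, stride))
        if score > best_score:
            best_score, best_off, best_bounds = score, s, bounds
    return FragmentHit(ref.name, fragment_id, strand, best_off, best_score, best_bounds)


def scan_all(
    read: ReadProfile,
    refs: ReferenceIndex | Sequence[ReferenceIndex],
    stride: int = 1,
    strands: Sequence[str] = STRANDS,
    with_bounds: bool = True,
) -> list[FragmentHit]:
    """One :class:`FragmentHit` per (reference, fragment, strand).

    Order is deterministic: references in input order, fragment id ascending,
    strand ``+`` before ``-``.  The scan is embarrassingly parallel over
    fragments; results do not depend on execution order.
    """
    if isinstance(refs, ReferenceIndex):
        refs = [refs]
    profiles = {"+": read}
    if "-" in strands:
        profiles["-"] = read.reverse_complement()
    hits: list[FragmentHit] = []
    for ref in refs:
        per_strand = {}
        for strand in strands:
            prof = profiles[strand]
            ws = window_best_scores(
                prof.pssm, ref.code_with_tail(len(read)), ref.padded_length, stride
            )
            per_strand[strand] = fragment_best(ws, ref.fragment_length)
        for f in range(ref.num_fragments):
            for strand in strands:
                scores, offs = per_strand[strand]
                bounds = None
                if with_bounds:
                    series = window_series(profiles[strand], ref, int(offs[f]), stride)
                    _, bounds = max_scoring_subsequence(series)
                hits.append(
                    FragmentHit(
                        ref.name, f, strand, int(offs[f]), float(scores[f]), bounds
                    )
                )
    return hits


def capacity_max_read_length(shared_bytes: int) -> int:
    """Largest read length (multiple of 16) fitting the on-chip score table.

    The table stores, for every read position plus a 16-slot look-ahead
    apron, one float per genome character: ``(L + 16) * 4 * 5`` bytes.  A
    49152-byte budget therefore caps reads at 2432 bp.
    """
    if shared_bytes < 320:
        raise ParameterError(
            f"shared memory budget {shared_bytes} below the 320-byte minimum"
        )
    return (shared_bytes // 20 - 16) // 16 * 16
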