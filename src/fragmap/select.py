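"""Reduce fragment hits to a mapping decision with a repeat-aware ratio filter.

A read is considered mapped only when the best fragment clearly beats the
runner-up: the mapping quality is ``-100 * log2(second/best)`` and the read
is accepted when that exceeds the threshold (default ``-100 * log2(0.9)``,
i.e. the second-best/best score ratio is below 0.9).  A near-tie between two
distant fragments signals a repeat and is rejected as a likely false
positive.

Because windows owned by fragment f may overflow into f+1, immediately
adjacent fragments on the same strand can score the same genomic placement;
they are excluded from the runner-up search so a junction read is not
mistaken for a repeat (exclusion radius configurable, default 1 fragment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import FragmentHit
from .errors import FragmapError

MAPQ_CAP = 254.0  # SAM ceiling; 255 is reserved for "unavailable"
DEFAULT_RATIO_THRESHOLD = 0.9


def default_mapq_threshold(ratio_threshold: float = DEFAULT_RATIO_THRESHOLD) -> float:
    """Exact mapq threshold equivalent to the ratio cut (15.2003... for 0.9)."""
    return mapq_from_ratio(ratio_threshold)


def mapq_from_ratio(ratio: float, cap: float = MAPQ_CAP) -> float:
    """Mapping quality ``-100 * log2(ratio)``, capped at 254.

    *ratio* is the second-best/best fragment score ratio, interpreted as the
    probability that the placement is wrong.  ratio 0 (no competing
    fragment) gives the cap; ratio 1 gives 0.
    """
    if ratio > 1.0 or ratio < 0.0:
        raise FragmapError(
            f"score ratio {ratio} outside [0, 1]: best/second ordering violated"
        )
    if ratio == 0.0:
        return cap
    return min(cap, -100.0 * math.log2(ratio))


@dataclass(frozen=True)
class MappingDecision:
    """Outcome of the candidate-selection phase for one read."""

    best: FragmentHit
    second: FragmentHit | None
    ratio: float
    mapq_real: float
    accepted: bool


def _hit_key(hit: FragmentHit) -> tuple:
    # deterministic tie-break: reference name, fragment id, '+' before '-'
    return (hit.ref, hit.fragment_id, 0 if hit.strand == "+" else 1)


def _is_excluded(hit: FragmentHit, best: FragmentHit, radius: int) -> bool:
    return (
        hit.ref == best.ref
        and hit.strand == best.strand
        and abs(hit.fragment_id - best.fragment_id) <= radius
    )


def decide(
    hits: Sequence[FragmentHit],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    mapq_threshold: float | None = None,
    exclusion_radius: int = 1,
) -> MappingDecision:
    """Pick best and second-best fragments and apply the ratio filter.

    The decision is invariant under permutation of *hits*.  A best score of
    zero or less means nothing aligned: rejected with mapq 0.  When no
    eligible runner-up has positive score the ratio is taken as 0 and the
    mapping quality caps at 254.
    """
    if not hits:
        raise FragmapError("decide() requires at least one fragment hit")
    if mapq_threshold is None:
        mapq_threshold = default_mapq_threshold(ratio_threshold)
    best = min(hits, key=lambda h: (-h.score, _hit_key(h)))
    if best.score <= 0.0:
        return MappingDecision(best, None, 1.0, 0.0, False)
    eligible = [
        h for h in hits if h.score > 0.0 and not _is_excluded(h, best, exclusion_radius)
    ]
    second = min(eligible, key=lambda h: (-h.score, _hit_key(h))) if eligible else None
    ratio = second.score / best.score if second is not None else 0.0
    mapq = mapq_from_ratio(ratio)
    return MappingDecision(best, second, ratio, mapq, mapq > mapq_threshold)


def decide_from_scans(
    scans: Sequence[tuple[str, str, np.ndarray, np.ndarray]],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    mapq_threshold: float | None = None,
    exclusion_radius: int = 1,
) -> MappingDecision:
    """Array fast path of :func:`decide` used by the mapping pipeline.

    *scans* holds ``(ref_name, strand, fragment_scores, fragment_offsets)``
    tuples as produced by the phase-1 scan.  Produces the same decision as
    building every :class:`FragmentHit` and calling :func:`decide`.
    """
    if mapq_threshold is None:
        mapq_threshold = default_mapq_threshold(ratio_threshold)

    names = sorted({name for name, _, _, _ in scans})
    name_rank = {n: i for i, n in enumerate(names)}
    strand_rank = {"+": 0, "-": 1}

    all_scores = np.concatenate([s for _, _, s, _ in scans])
    parts = []
    pos = 0
    for name, strand, scores, offs in scans:
        parts.append((name, strand, pos, pos + len(scores), scores, offs))
        pos += len(scores)

    def locate(flat_idx: int) -> FragmentHit:
        for name, strand, lo, hi, scores, offs in parts:
            if lo <= flat_idx < hi:
                f = flat_idx - lo
                return FragmentHit(
                    name, f, strand, int(offs[f]), float(scores[f]), None
                )
        raise IndexError(flat_idx)

    def pick(indices: np.ndarray) -> FragmentHit:
        # smallest (ref, fragment, strand) among score ties
        cands = [locate(int(i)) for i in indices]
        return min(
            cands,
            key=lambda h: (name_rank[h.ref], h.fragment_id, strand_rank[h.strand]),
        )

    best_score = float(all_scores.max())
    best = pick(np.flatnonzero(all_scores == best_score))
    if best.score <= 0.0:
        return MappingDecision(best, None, 1.0, 0.0, False)

    masked = all_scores.copy()
    for name, strand, lo, hi, scores, offs in parts:
        if name == best.ref and strand == best.strand:
            f0 = max(0, best.fragment_id - exclusion_radius)
            f1 = min(hi - lo, best.fragment_id + exclusion_radius + 1)
            masked[lo + f0 : lo + f1] = -np.inf
    second_score = float(masked.max())
    second = (
        pick(np.flatnonzero(masked == second_score)) if second_score > 0.0 else None
    )
    ratio = second.score / best.score if second is not None else 0.0
    mapq = mapq_from_ratio(ratio)
    return MappingDecision(best, second, ratio, mapq, mapq > mapq_threshold)
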