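"""End-to-end mapping pipeline: scan, decide, align, emit.

:class:`Mapper` ties the two phases together for a set of reference
sequences.  Per read: build the quality-weighted PSSM, scan every fragment
on both strands with the maximum-scoring-subsequence kernel, apply the
best/second-best ratio filter, then (if accepted) run the fitting alignment
on the region spanning rightward from the winning fragment and emit a SAM
record.  The fragment scan is order-independent, so any partitioning of
fragments across workers yields identical output; this implementation scans
fragments as one vectorised block per strand.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .align import DEFAULT_REGION_SLACK, fit_align, select_region
from .engine import window_best_scores, fragment_best
from .errors import ParameterError
from .reads import DEFAULT_MATCH, DEFAULT_MISMATCH, ReadProfile
from .reference import ReferenceIndex, default_fragment_length, fragment_genome
from .samio import FLAG_REVERSE, SamRecord
from .select import (
    DEFAULT_RATIO_THRESHOLD,
    MappingDecision,
    decide_from_scans,
    default_mapq_threshold,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable parameters of a mapping run.

    ``fragment_length=None`` picks the genome-size default (48 below 50 Mbp,
    4800 above).  ``mapq_threshold=None`` derives the exact equivalent of the
    ratio threshold (15.2003... for ratio 0.9), so the ratio rule and the
    mapq rule agree; setting it explicitly (e.g. 62 for stringent runs)
    overrides the ratio rule.
    """

    fragment_length: int | None = None
    match: float = DEFAULT_MATCH
    mismatch: float = DEFAULT_MISMATCH
    gap_open: float = -26.0
    gap_extend: float = -1.0
    gap_model: str = "linear"
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    mapq_threshold: float | None = None
    fast: bool = False
    strands: str = "both"
    workers: int = 1
    seed: int | None = None
    region_slack: int = DEFAULT_REGION_SLACK
    exclusion_radius: int = 1
    phred_offset: int = 33
    local: bool = False

    def __post_init__(self) -> None:
        if self.strands not in ("both", "forward"):
            raise ParameterError(f"strands must be 'both' or 'forward', got {self.strands!r}")
        if not self.match > 0 > self.mismatch:
            raise ParameterError("require match > 0 > mismatch")

    @property
    def stride(self) -> int:
        return 2 if self.fast else 1

    @property
    def strand_list(self) -> tuple[str, ...]:
        return ("+", "-") if self.strands == "both" else ("+",)

    def resolved_mapq_threshold(self) -> float:
        if self.mapq_threshold is not None:
            return self.mapq_threshold
        return default_mapq_threshold(self.ratio_threshold)

    def describe(self) -> str:
        """Compact key=value serialisation echoed into the SAM @PG line."""
        d = dataclasses.asdict(self)
        return " ".join(f"{k}={v}" for k, v in sorted(d.items()))


class Mapper:
    """Maps reads against a set of reference sequences."""

    def __init__(
        self, refs: ReferenceIndex | Sequence[ReferenceIndex], config: RunConfig | None = None
    ):
        if isinstance(refs, ReferenceIndex):
            refs = [refs]
        self.config = config or RunConfig()
        total = sum(r.length for r in refs)
        F = self.config.fragment_length or default_fragment_length(total)
        self.refs = [
            r if r.fragment_length == F else fragment_genome(r, F) for r in refs
        ]
        self.fragment_length = F
        self._by_name = {r.name: r for r in self.refs}
        if len(self._by_name) != len(self.refs):
            raise ParameterError("duplicate reference sequence names")

    def scan(self, read: ReadProfile) -> list[tuple[str, str, np.ndarray, np.ndarray]]:
        """Phase 1: per-fragment best scores/offsets for every (ref, strand)."""
        cfg = self.config
        profiles = {"+": read}
        if "-" in cfg.strand_list:
            profiles["-"] = read.reverse_complement()
        scans = []
        for ref in self.refs:
            for strand in cfg.strand_list:
                prof = profiles[strand]
                ws = window_best_scores(
                    prof.pssm,
                    ref.code_with_tail(len(read)),
                    ref.padded_length,
                    cfg.stride,
                )
                scores, offs = fragment_best(ws, ref.fragment_length)
                scans.append((ref.name, strand, scores, offs))
        return scans

    def map_read(self, read: ReadProfile) -> tuple[SamRecord, MappingDecision]:
        """Full two-phase mapping of one read."""
        cfg = self.config
        scans = self.scan(read)
        decision = decide_from_scans(
            scans,
            ratio_threshold=cfg.ratio_threshold,
            mapq_threshold=cfg.mapq_threshold,
            exclusion_radius=cfg.exclusion_radius,
        )
        logger.debug(
            "read=%s best=%s:%d%s score=%.3f second=%.3f ratio=%.4f mapq=%.2f accepted=%s",
            read.id,
            decision.best.ref,
            decision.best.fragment_id,
            decision.best.strand,
            decision.best.score,
            decision.second.score if decision.second else 0.0,
            decision.ratio,
            decision.mapq_real,
            decision.accepted,
        )
        if not decision.accepted:
            rec = SamRecord.unmapped(read.id, read.seq, read.qual_string())
            return rec, decision

        ref = self._by_name[decision.best.ref]
        region, region_start = select_region(decision, ref, len(read), cfg.region_slack)
        prof = read if decision.best.strand == "+" else read.reverse_complement()
        aln = fit_align(
            prof,
            region,
            gap_model=cfg.gap_model,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            region_start=region_start,
            strand=decision.best.strand,
            local=cfg.local,
        )
        flag = FLAG_REVERSE if decision.best.strand == "-" else 0
        mapq_int = int(min(decision.mapq_real, 254.0) + 0.5)
        rec = SamRecord(
            qname=read.id,
            flag=flag,
            rname=ref.name,
            pos=aln.pos + 1,
            mapq=mapq_int,
            cigar=aln.cigar,
            seq=prof.seq,
            qual=prof.qual_string(),
            tags={
                "AS": int(round(aln.score)),
                "ZR": round(decision.ratio, 6),
                "ZQ": round(decision.mapq_real, 4),
            },
        )
        return rec, decision

    def map_reads(self, reads: Iterable[ReadProfile]) -> Iterator[SamRecord]:
        for read in reads:
            rec, _ = self.map_read(read)
            yield rec
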