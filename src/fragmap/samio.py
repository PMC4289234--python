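"""SAM input/output via pysam.

Mapped reads carry the integer MAPQ (rounded, capped at 254) plus tags
preserving what the integer loses: AS:i (alignment score), ZR:f (the
second-best/best score ratio) and ZQ:f (the real-valued mapping quality;
the accept threshold 15.2 is fractional while SAM MAPQ is integral).
Reverse-strand records store the reverse-complemented sequence with POS at
its leftmost aligned base, per SAM convention.  Reading back is minimal:
just enough to pull unmapped or discordant reads for rescue re-mapping and
to evaluate predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from ._version import __version__
from .reference import ReferenceIndex

logger = logging.getLogger(__name__)

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10

DEFAULT_PAIR_DISTANCE = 500


@dataclass
class SamRecord:
    """One SAM alignment line (subset of fields this mapper uses)."""

    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0  # 1-based; 0 for unmapped
    mapq: int = 0
    cigar: str = "*"
    seq: str = "*"
    qual: str = "*"
    tags: dict = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def pos0(self) -> int:
        """0-based position (mapped records only)."""
        return self.pos - 1

    @classmethod
    def unmapped(cls, qname: str, seq: str, qual: str, flag_extra: int = 0) -> "SamRecord":
        return cls(qname, FLAG_UNMAPPED | flag_extra, "*", 0, 0, "*", seq, qual)


def _build_header(
    references: Sequence[ReferenceIndex | tuple[str, int]], command_line: str | None
) -> dict:
    sq = []
    for ref in references:
        if isinstance(ref, ReferenceIndex):
            sq.append({"SN": ref.name, "LN": ref.length})
        else:
            sq.append({"SN": ref[0], "LN": int(ref[1])})
    pg = {"ID": "fragmap", "PN": "fragmap", "VN": __version__}
    if command_line:
        pg["CL"] = command_line
    return {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq, "PG": [pg]}


_TAG_TYPES = {"AS": "i", "ZR": "f", "ZQ": "f", "NM": "i"}


class SamWriter:
    """Streaming SAM writer; use as a context manager."""

    def __init__(
        self,
        path: str | Path,
        references: Sequence[ReferenceIndex | tuple[str, int]],
        command_line: str | None = None,
    ):
        header = _build_header(references, command_line)
        self._file = pysam.AlignmentFile(str(path), "w", header=header)
        self._tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        self.n_written = 0

    def write(self, rec: SamRecord) -> None:
        seg = pysam.AlignedSegment(self._file.header)
        seg.query_name = rec.qname
        seg.flag = rec.flag
        if rec.is_unmapped:
            seg.reference_id = -1
            seg.reference_start = -1
            seg.mapping_quality = 0
        else:
            seg.reference_id = self._tid[rec.rname]
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = rec.mapq
            seg.cigarstring = rec.cigar
        if rec.seq != "*":
            seg.query_sequence = rec.seq
            if rec.qual != "*":
                seg.query_qualities = pysam.qualitystring_to_array(rec.qual)
        if rec.tags:
            seg.set_tags(
                [(k, v, _TAG_TYPES.get(k, "Z")) for k, v in rec.tags.items()]
            )
        self._file.write(seg)
        self.n_written += 1

    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "SamWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_sam(
    records: Iterable[SamRecord],
    references: Sequence[ReferenceIndex | tuple[str, int]],
    path: str | Path,
    command_line: str | None = None,
) -> int:
    """Write *records* (input order preserved); returns the record count."""
    with SamWriter(path, references, command_line) as w:
        for rec in records:
            w.write(rec)
        return w.n_written


def _segment_to_record(seg: pysam.AlignedSegment) -> SamRecord:
    qual = "*"
    if seg.query_qualities is not None:
        qual = pysam.qualities_to_qualitystring(seg.query_qualities)
    return SamRecord(
        qname=seg.query_name,
        flag=seg.flag,
        rname=seg.reference_name if seg.reference_id >= 0 else "*",
        pos=(seg.reference_start + 1) if seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=seg.cigarstring or "*",
        seq=seg.query_sequence or "*",
        qual=qual,
        tags=dict(seg.get_tags()),
    )


def read_sam(path: str | Path) -> Iterator[SamRecord]:
    """Iterate over a SAM file as :class:`SamRecord` objects."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            yield _segment_to_record(seg)


def read_unmapped(
    path: str | Path,
    paired: bool = False,
    max_dist: int = DEFAULT_PAIR_DISTANCE,
) -> list[SamRecord]:
    """Reads needing rescue: unmapped records, plus (in paired mode) both
    mates of discordant pairs — mapped to different references or at least
    *max_dist* bp apart.

    Records without a stored sequence cannot be re-mapped and are skipped
    with a logged warning.
    """
    records = list(read_sam(path))
    skipped = sum(1 for r in records if r.seq == "*")
    if skipped:
        logger.warning("read_unmapped: skipped %d records with no sequence", skipped)
    records = [r for r in records if r.seq != "*"]
    needy = [r for r in records if r.is_unmapped]
    if paired:
        by_name: dict[str, list[SamRecord]] = {}
        for r in records:
            if r.flag & FLAG_PAIRED:
                by_name.setdefault(r.qname, []).append(r)
        for mates in by_name.values():
            mapped = [m for m in mates if not m.is_unmapped]
            if len(mapped) != 2:
                continue
            a, b = mapped
            discordant = a.rname != b.rname or abs(a.pos - b.pos) >= max_dist
            if discordant:
                needy.extend(mapped)
    return needy
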