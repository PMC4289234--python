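"""Read handling: FASTQ parsing and per-read position-specific scoring.

Both phases of the mapper score a read base against a genome character
through a position-specific scoring matrix (PSSM) built from the base-call
qualities.  With x = 1 - 10**(-q/10) the probability that position i was
called correctly, a match at position i scores ``match * x`` and any
mismatch scores ``mismatch * x``; a position with q = 0 is uninformative and
contributes nothing.  Any comparison involving N (in the read or in the
genome) scores as a mismatch.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .errors import FastqParseError, ParameterError
from .reference import encode, reverse_complement, sanitize

DEFAULT_MATCH = 5.0
DEFAULT_MISMATCH = -4.0

# column permutation that complements the genome-character axis of a PSSM
_COMPLEMENT_COLS = np.array([3, 2, 1, 0, 4])


def phred_to_prob(q):
    """Probability that a base call with phred score *q* is correct.

    ``x = 1 - 10**(-q/10)``; accepts scalars or arrays.
    """
    return 1.0 - 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def build_pssm(
    seq: str,
    quals: np.ndarray,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
) -> np.ndarray:
    """Quality-weighted scoring table, shape ``(len(seq), 5)``, columns ACGTN.

    Row i holds the score of aligning read position i against each genome
    character.  The N column is always ``mismatch * x``, and a read-N row is
    all ``mismatch * x``: N never rewards an alignment, which keeps the
    N-padded genome tail from extending a maximum-scoring subsequence.
    """
    if not match > 0 > mismatch:
        raise ParameterError(
            f"require match > 0 > mismatch, got match={match} mismatch={mismatch}"
        )
    x = phred_to_prob(quals)
    codes = encode(seq)
    pssm = np.repeat((mismatch * x)[:, None], 5, axis=1)
    known = codes < 4
    pssm[known, codes[known]] = match * x[known]
    return np.ascontiguousarray(pssm)


@dataclass
class ReadProfile:
    """A read with base qualities and its position-specific scoring table."""

    id: str
    seq: str
    quals: np.ndarray
    match: float = DEFAULT_MATCH
    mismatch: float = DEFAULT_MISMATCH

    def __post_init__(self) -> None:
        self.seq = sanitize(self.seq)
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.seq) != len(self.quals):
            raise FastqParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if len(self.seq) == 0:
            raise FastqParseError(f"read {self.id!r}: empty sequence")
        if np.any(self.quals < 0):
            raise FastqParseError(f"read {self.id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.seq)

    @cached_property
    def pssm(self) -> np.ndarray:
        return build_pssm(self.seq, self.quals, self.match, self.mismatch)

    @cached_property
    def code(self) -> np.ndarray:
        return encode(self.seq)

    def qual_string(self, offset: int = 33) -> str:
        return "".join(chr(int(q) + offset) for q in self.quals)

    def reverse_complement(self) -> "ReadProfile":
        """Profile of the reverse-complemented read.

        The PSSM transforms by reversing the position axis and complementing
        the genome-character axis, so it is derived rather than rebuilt.
        """
        rc = ReadProfile(
            self.id,
            reverse_complement(self.seq),
            self.quals[::-1].copy(),
            self.match,
            self.mismatch,
        )
        rc.__dict__["pssm"] = np.ascontiguousarray(self.pssm[::-1][:, _COMPLEMENT_COLS])
        return rc

    @classmethod
    def from_strings(
        cls,
        id: str,
        seq: str,
        qual: str,
        phred_offset: int = 33,
        match: float = DEFAULT_MATCH,
        mismatch: float = DEFAULT_MISMATCH,
    ) -> "ReadProfile":
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
        quals -= phred_offset
        return cls(id, seq, quals, match, mismatch)


def load_fastq(
    path: str | Path,
    phred_offset: int = 33,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    max_length: int | None = None,
) -> Iterator[ReadProfile]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Reads of heterogeneous lengths are accepted in one file; there is no need
    to declare a read length.  *max_length* optionally rejects longer reads.
    phred+33 by default; pass ``phred_offset=64`` for old Illumina scaling.
    """
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    if phred_offset not in (33, 64):
        raise ParameterError(f"unsupported phred offset {phred_offset}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        parser = SeqIO.parse(fh, fmt)
        n = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ after record {n}: {exc}"
                ) from exc
            n += 1
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
            if max_length is not None and len(rec.seq) > max_length:
                raise FastqParseError(
                    f"read {rec.id!r} length {len(rec.seq)} exceeds cap {max_length}"
                )
            yield ReadProfile(rec.id, str(rec.seq), quals, match, mismatch)
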