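"""Reference genome handling: FASTA loading and fixed-length fragmentation.

The candidate-search phase scores a read against every disjoint fragment of
the genome, so each reference sequence is held in memory padded with N to an
exact multiple of the fragment length.  N scores as a mismatch at every read
position, so the pad can never extend a maximum-scoring subsequence and the
padded tail is inert.

Coordinates are 0-based half-open everywhere in this package; conversion to
1-based happens only at SAM emission.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .errors import FastaParseError, ParameterError

#: default fragment length for genomes below/above 50 Mbp
SMALL_GENOME_FRAGMENT = 48
LARGE_GENOME_FRAGMENT = 4800
LARGE_GENOME_CUTOFF = 50_000_000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase and collapse everything outside {A,C,G,T,N} (ambiguity codes,
# stray characters) to N; the scoring model only defines these five symbols
_SANITIZE = bytes(
    c if c in b"ACGTN" else ord("N")
    for c in (bytes([i]).upper()[0] for i in range(256))
)

# base encoding used by the scoring kernels: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
BASE_ORDER = "ACGTN"


def sanitize(seq: str) -> str:
    """Uppercase *seq* and map any non-ACGTN character to N."""
    return seq.encode("ascii", errors="replace").translate(_SANITIZE).decode()


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceIndex:
    """One reference sequence partitioned into fixed-length fragments.

    Parameters
    ----------
    name
        Sequence identifier (FASTA header word).
    seq
        Nucleotide string; sanitised to uppercase {A,C,G,T,N} on construction.
    fragment_length
        Fragment size F in bp.  Fragment ``i`` covers the half-open interval
        ``[i*F, (i+1)*F)`` of the padded sequence; the last fragment is padded
        with N.
    """

    name: str
    seq: str
    fragment_length: int = SMALL_GENOME_FRAGMENT
    _code_ext: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ParameterError(
                f"fragment length must be >= 1, got {self.fragment_length}"
            )
        self.seq = sanitize(self.seq)

    @property
    def length(self) -> int:
        """Sequence length in bp before padding."""
        return len(self.seq)

    @property
    def num_fragments(self) -> int:
        return -(-self.length // self.fragment_length)

    @property
    def padded_length(self) -> int:
        return self.num_fragments * self.fragment_length

    @cached_property
    def padded_seq(self) -> str:
        return self.seq + "N" * (self.padded_length - self.length)

    @cached_property
    def code(self) -> np.ndarray:
        """int8 codes of the padded sequence."""
        return encode(self.padded_seq)

    def code_with_tail(self, tail: int) -> np.ndarray:
        """Padded codes followed by at least *tail* extra N codes.

        Scan windows starting near the end of the genome run off the padded
        sequence; the extra N tail lets the scoring kernels read past the end
        without branching.  N scores negatively at every read position, so a
        maximum-scoring subsequence never benefits from the tail and the
        result equals scoring the truncated window.
        """
        have = 0 if self._code_ext is None else len(self._code_ext) - self.padded_length
        if have < tail:
            self._code_ext = np.concatenate(
                [self.code, np.full(tail, 4, dtype=np.int8)]
            )
        return self._code_ext[: self.padded_length + tail]

    def fragment(self, i: int) -> str:
        """Return fragment *i* of the padded sequence."""
        if not 0 <= i < self.num_fragments:
            raise IndexError(f"fragment {i} out of range [0, {self.num_fragments})")
        F = self.fragment_length
        return self.padded_seq[i * F : (i + 1) * F]

    def fragments(self) -> list[str]:
        return [self.fragment(i) for i in range(self.num_fragments)]

    def fragment_start(self, i: int) -> int:
        return i * self.fragment_length

    def extract_region(self, fragment_id: int, min_len: int) -> tuple[str, int]:
        """Genome region starting at *fragment_id*, extended rightward in
        whole fragments until its length is at least *min_len* (truncated at
        the padded genome end).

        Returns ``(region, genomic_start)`` with a 0-based start.
        """
        if not 0 <= fragment_id < self.num_fragments:
            raise IndexError(
                f"fragment {fragment_id} out of range [0, {self.num_fragments})"
            )
        F = self.fragment_length
        start = fragment_id * F
        n_frag = -(-min_len // F)
        end = min(start + n_frag * F, self.padded_length)
        return self.padded_seq[start:end], start


def fragment_genome(ref: ReferenceIndex, fragment_length: int) -> ReferenceIndex:
    """Return a copy of *ref* re-partitioned with a new fragment length."""
    if fragment_length < 1:
        raise ParameterError(f"fragment length must be >= 1, got {fragment_length}")
    return ReferenceIndex(ref.name, ref.seq, fragment_length)


def default_fragment_length(total_bp: int) -> int:
    """Default F: 48 for genomes under 50 Mbp, 4800 otherwise."""
    return SMALL_GENOME_FRAGMENT if total_bp < LARGE_GENOME_CUTOFF else LARGE_GENOME_FRAGMENT


def load_fasta(
    path: str | Path, fragment_length: int | None = None
) -> list[ReferenceIndex]:
    """Load a (possibly gzipped) FASTA file as a list of :class:`ReferenceIndex`.

    Each entry is fragmented independently; when *fragment_length* is None the
    default is chosen from the total genome size (48 below 50 Mbp, 4800 above).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        text = fh.read()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:30]!r}"
                )
            break
    else:
        raise FastaParseError(f"{path}: empty FASTA file")
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    if fragment_length is None:
        fragment_length = default_fragment_length(sum(len(s) for _, s in records))
    return [ReferenceIndex(name, seq, fragment_length) for name, seq in records]
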