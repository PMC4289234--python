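"""Synthetic divergent-read generator with ground-truth alignments.

Emulates the benchmark conditions the mapper is designed for: reads drawn
uniformly from a reference (both strands), carrying i.i.d. substitutions at
a chosen divergence rate (a substituted base is always different from the
original, so divergence 0.1 means 10% mismatches on average, on top of
sequencing error), optionally one indel per read of length uniform on
1..max_indel (default 30), placed with equal probability as an insertion in
the read or a deletion of genome bases.  Every read comes with a truth
record (0-based start on the forward genome, strand, SAM-style CIGAR) so
mapping accuracy can be scored exactly.

Base qualities default to a constant Q30; a per-position phred profile can
be supplied to mimic machine decay curves.  All randomness flows from one
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import parse_cigar
from .errors import ParameterError
from .reference import ReferenceIndex, reverse_complement

DEFAULT_READ_LENGTH = 251
DEFAULT_MAX_INDEL = 30
DEFAULT_P_INDEL = 0.5
DEFAULT_QUALITY = 30
DEFAULT_INSERT_SIZE = 250
DEFAULT_INSERT_SD = 25

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.

    ``pos0``/``cigar`` follow SAM convention: forward-genome orientation,
    with the read sequence stored reverse-complemented for '-' strand reads.
    ``sub_positions`` are the substituted positions in forward-read
    orientation (used by the consistency check, not written to disk).
    """

    read_id: str
    chrom: str
    pos0: int
    strand: str
    cigar: str
    sub_positions: tuple[int, ...] = ()

    def genome_span(self) -> int:
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MD")


@dataclass(frozen=True)
class SimRead:
    id: str
    seq: str
    quals: np.ndarray


def simulate_genome(length: int, seed: int | np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T string, deterministic under *seed*."""
    if length < 1:
        raise ParameterError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(
    read_codes: np.ndarray, sub_rate: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute bases i.i.d. at *sub_rate*; new base always differs."""
    mask = rng.random(len(read_codes)) < sub_rate
    idx = np.flatnonzero(mask)
    if len(idx):
        shift = rng.integers(1, 4, size=len(idx))
        read_codes = read_codes.copy()
        read_codes[idx] = (read_codes[idx] + shift) % 4
    return read_codes, idx


def simulate_reads(
    ref: ReferenceIndex | str,
    n: int,
    read_len: int = DEFAULT_READ_LENGTH,
    sub_rate: float = 0.1,
    with_gaps: bool = False,
    p_indel: float = DEFAULT_P_INDEL,
    max_indel: int = DEFAULT_MAX_INDEL,
    quality: int | Sequence[int] = DEFAULT_QUALITY,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "sim",
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Simulate *n* divergent reads with truth records.

    Start positions are uniform (leaving room for the largest indel), strand
    uniform.  With ``with_gaps`` each read carries one indel with probability
    *p_indel*: signed length uniform on +-[1, max_indel]; positive = bases
    inserted into the read, negative = genome bases deleted.  All reads have
    exactly *read_len* bases.
    """
    genome = ref.seq if isinstance(ref, ReferenceIndex) else ref
    chrom = ref.name if isinstance(ref, ReferenceIndex) else "sim"
    if not 0 <= sub_rate < 1:
        raise ParameterError(f"sub_rate must be in [0, 1), got {sub_rate}")
    if read_len > len(genome):
        raise ParameterError(
            f"read length {read_len} exceeds genome length {len(genome)}"
        )
    if max_indel < 1 or max_indel >= read_len:
        raise ParameterError(f"max_indel must be in [1, read_len), got {max_indel}")
    rng = np.random.default_rng(seed)
    gcode = np.frombuffer(genome.encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    gcode = code_of[gcode]

    quals = _quality_array(quality, read_len)
    max_start = len(genome) - read_len - (max_indel if with_gaps else 0)
    if max_start < 0:
        raise ParameterError("genome too short for read length plus indel allowance")

    reads: list[SimRead] = []
    truths: list[TruthRecord] = []
    for k in range(n):
        pos = int(rng.integers(0, max_start + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        indel = 0
        if with_gaps and rng.random() < p_indel:
            size = int(rng.integers(1, max_indel + 1))
            indel = size if rng.random() < 0.5 else -size

        if indel == 0:
            codes = gcode[pos : pos + read_len]
            cigar = f"{read_len}M"
        elif indel < 0:  # deletion: genome bases missing from the read
            d = -indel
            t = int(rng.integers(1, read_len))
            codes = np.concatenate(
                [gcode[pos : pos + t], gcode[pos + t + d : pos + t + d + read_len - t]]
            )
            cigar = f"{t}M{d}D{read_len - t}M"
        else:  # insertion: novel bases inside the read
            ins = indel
            t = int(rng.integers(1, read_len - ins))
            novel = rng.integers(0, 4, size=ins)
            codes = np.concatenate(
                [gcode[pos : pos + t], novel, gcode[pos + t : pos + read_len - ins]]
            )
            cigar = f"{t}M{ins}I{read_len - ins - t}M"

        codes, subs = _mutate(codes, sub_rate, rng)
        fwd_read = _BASES[codes].tobytes().decode()
        seq = fwd_read if strand == "+" else reverse_complement(fwd_read)
        rid = f"{id_prefix}_{k}"
        reads.append(SimRead(rid, seq, quals.copy()))
        truths.append(
            TruthRecord(rid, chrom, pos, strand, cigar, tuple(int(i) for i in subs))
        )
    return reads, truths


def _quality_array(quality: int | Sequence[int], read_len: int) -> np.ndarray:
    if np.isscalar(quality):
        return np.full(read_len, int(quality), dtype=np.int64)
    profile = np.asarray(quality, dtype=np.int64)
    if len(profile) < read_len:
        raise ParameterError(
            f"quality profile length {len(profile)} shorter than read length {read_len}"
        )
    return profile[:read_len].copy()


def load_quality_profile(path: str | Path) -> np.ndarray:
    """Per-position phred profile from a one-column plain-text table."""
    return np.loadtxt(path, dtype=np.int64, ndmin=1)


def verify_truth(truth: TruthRecord, read_seq: str, genome: str) -> bool:
    """Check that replaying the truth CIGAR reconstructs the read from the
    genome up to the planted substitutions (and inserted bases)."""
    fwd = read_seq if truth.strand == "+" else reverse_complement(read_seq)
    subs = set(truth.sub_positions)
    i, g = 0, truth.pos0
    for n, op in parse_cigar(truth.cigar):
        if op == "M":
            for _ in range(n):
                if i not in subs and fwd[i] != genome[g]:
                    return False
                if i in subs and fwd[i] == genome[g]:
                    return False
                i += 1
                g += 1
        elif op == "I":
            i += n
        elif op == "D":
            g += n
        else:
            return False
    return i == len(fwd)


def simulate_read_pairs(
    ref: ReferenceIndex | str,
    n_pairs: int,
    read_len: int = 101,
    sub_rate: float = 0.0,
    insert_size: int = DEFAULT_INSERT_SIZE,
    insert_sd: int = DEFAULT_INSERT_SD,
    quality: int = DEFAULT_QUALITY,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "pair",
) -> tuple[list[SimRead], list[TruthRecord], list[int]]:
    """Minimal paired-end simulation (fixed insert +- sd) for rescue-mode
    tests.  Returns reads interleaved R1/R2, truths, and pair flags."""
    genome = ref.seq if isinstance(ref, ReferenceIndex) else ref
    chrom = ref.name if isinstance(ref, ReferenceIndex) else "sim"
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    truths: list[TruthRecord] = []
    flags: list[int] = []
    quals = np.full(read_len, quality, dtype=np.int64)
    for k in range(n_pairs):
        insert = max(2 * read_len, int(round(rng.normal(insert_size, insert_sd))))
        pos = int(rng.integers(0, len(genome) - insert + 1))
        r1 = genome[pos : pos + read_len]
        r2_start = pos + insert - read_len
        r2 = reverse_complement(genome[r2_start : r2_start + read_len])
        rid = f"{id_prefix}_{k}"
        reads.append(SimRead(rid, r1, quals.copy()))
        truths.append(TruthRecord(rid, chrom, pos, "+", f"{read_len}M"))
        flags.append(0x1 | 0x40)
        reads.append(SimRead(rid, r2, quals.copy()))
        truths.append(TruthRecord(rid, chrom, r2_start, "-", f"{read_len}M"))
        flags.append(0x1 | 0x80)
    return reads, truths, flags


def reads_to_fastq(reads: Sequence[SimRead], path: str | Path, offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """Truth table as TSV: read_id, chrom, pos0, strand, cigar."""
    df = pd.DataFrame(
        [(t.read_id, t.chrom, t.pos0, t.strand, t.cigar) for t in truths],
        columns=["read_id", "chrom", "pos0", "strand", "cigar"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    return {
        row.read_id: TruthRecord(
            row.read_id, row.chrom, int(row.pos0), row.strand, row.cigar
        )
        for row in df.itertuples(index=False)
    }
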