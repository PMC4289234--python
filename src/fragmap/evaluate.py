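"""Score mapped reads against simulation truth.

Two correctness criteria are supported:

* basewise — a prediction is correct when at least one read base lands on
  the same genome coordinate as in the true alignment (same reference
  sequence and strand; both CIGARs are expanded to per-base coordinates,
  with I/S consuming no genome and D consuming genome only).
* fragmentwise — the coarser criterion for fragment-level output: the
  predicted fragment index must lie within one of ``floor(true_pos / F)``.

A summary partitions the read set into correct / incorrect / rejected
(unmapped) with percentages that sum to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .align import parse_cigar
from .errors import EvaluationError
from .samio import SamRecord, read_sam
from .simulate import TruthRecord


def expand_to_genome(pos0: int, cigar: str) -> np.ndarray:
    """Genome coordinate of every read base (SAM orientation); -1 where the
    base aligns to no genome position (I/S)."""
    coords: list[int] = []
    g = pos0
    for n, op in parse_cigar(cigar):
        if op == "M":
            coords.extend(range(g, g + n))
            g += n
        elif op in ("I", "S"):
            coords.extend([-1] * n)
        elif op in ("D", "N"):
            g += n
        else:
            raise EvaluationError(f"unsupported CIGAR op {op!r} in {cigar!r}")
    return np.asarray(coords, dtype=np.int64)


def read_correct_basewise(pred: SamRecord, truth: TruthRecord) -> bool:
    """At least one read base on the same genome coordinate as the truth.

    Strict about strand and reference sequence: a placement on the wrong
    strand or chromosome is never correct.
    """
    if pred.is_unmapped:
        raise EvaluationError(f"read {pred.qname!r}: cannot score an unmapped record")
    if pred.rname != truth.chrom:
        return False
    if ("-" if pred.is_reverse else "+") != truth.strand:
        return False
    a = expand_to_genome(pred.pos0, pred.cigar)
    b = expand_to_genome(truth.pos0, truth.cigar)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    return bool(np.any((a == b) & (a >= 0)))


def read_correct_fragmentwise(pred_fragment: int, truth_pos: int, F: int) -> bool:
    """Fragment-level criterion: |pred_fragment - floor(truth_pos/F)| <= 1."""
    if F < 1:
        raise EvaluationError(f"fragment length must be >= 1, got {F}")
    return abs(pred_fragment - truth_pos // F) <= 1


@dataclass(frozen=True)
class EvalSummary:
    """Partition of a read set into correct / incorrect / rejected."""

    n_total: int
    n_correct: int
    n_incorrect: int
    n_rejected: int

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    @property
    def pct_incorrect(self) -> float:
        return 100.0 * self.n_incorrect / self.n_total

    @property
    def pct_rejected(self) -> float:
        return 100.0 * self.n_rejected / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "n_rejected": self.n_rejected,
            "pct_correct": self.pct_correct,
            "pct_incorrect": self.pct_incorrect,
            "pct_rejected": self.pct_rejected,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def __str__(self) -> str:
        return (
            f"total {self.n_total}: "
            f"{self.pct_correct:.1f}% correct, "
            f"{self.pct_incorrect:.1f}% incorrect, "
            f"{self.pct_rejected:.1f}% rejected"
        )


def summarize(
    preds: Iterable[SamRecord] | str | Path,
    truths: Mapping[str, TruthRecord],
    criterion: str = "basewise",
    fragment_length: int | None = None,
) -> EvalSummary:
    """Score predictions (records or a SAM path) against *truths*.

    Rejected = unmapped records.  Every prediction must have a truth entry
    and read ids must be unique.
    """
    if isinstance(preds, (str, Path)):
        preds = read_sam(preds)
    if criterion not in ("basewise", "fragmentwise"):
        raise EvaluationError(f"unknown criterion {criterion!r}")
    if criterion == "fragmentwise" and not fragment_length:
        raise EvaluationError("fragmentwise criterion requires fragment_length")
    seen: set[str] = set()
    n_correct = n_incorrect = n_rejected = 0
    for rec in preds:
        if rec.qname in seen:
            raise EvaluationError(f"duplicate read id {rec.qname!r}")
        seen.add(rec.qname)
        if rec.qname not in truths:
            raise EvaluationError(f"no truth record for read {rec.qname!r}")
        truth = truths[rec.qname]
        if rec.is_unmapped:
            n_rejected += 1
        elif criterion == "basewise":
            if read_correct_basewise(rec, truth):
                n_correct += 1
            else:
                n_incorrect += 1
        else:
            ok = rec.rname == truth.chrom and read_correct_fragmentwise(
                rec.pos0 // fragment_length, truth.pos0, fragment_length
            )
            if ok:
                n_correct += 1
            else:
                n_incorrect += 1
    n_total = n_correct + n_incorrect + n_rejected
    if n_total == 0:
        raise EvaluationError("no predictions to summarize")
    return EvalSummary(n_total, n_correct, n_incorrect, n_rejected)
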