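"""Simulate-map-evaluate workflows used by the CLI, tests and benchmarks."""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import EvalSummary, summarize
from .pipeline import Mapper, RunConfig
from .reads import ReadProfile
from .reference import ReferenceIndex
from .simulate import SimRead, TruthRecord, simulate_genome, simulate_reads


def profiles_from_sim(
    reads: list[SimRead], match: float = 5.0, mismatch: float = -4.0
) -> list[ReadProfile]:
    return [ReadProfile(r.id, r.seq, r.quals, match, mismatch) for r in reads]


@dataclass
class ExperimentResult:
    summary: EvalSummary
    truths: list[TruthRecord]
    n_reads: int


def accuracy_experiment(
    seed: int,
    genome_length: int = 100_000,
    n_reads: int = 2000,
    read_length: int = 251,
    sub_rate: float = 0.1,
    with_gaps: bool = False,
    quality: int = 30,
    config: RunConfig | None = None,
    criterion: str = "basewise",
) -> ExperimentResult:
    """Simulate a random genome and divergent reads, map them with the
    two-phase pipeline, and score with the chosen correctness criterion.

    The genome derives from *seed* and the reads from *seed* + 1, so runs
    with and without gaps share the same genome.
    """
    config = config or RunConfig()
    genome = simulate_genome(genome_length, seed)
    ref = ReferenceIndex("sim", genome, config.fragment_length or 48)
    sim_reads, truths = simulate_reads(
        ref,
        n_reads,
        read_len=read_length,
        sub_rate=sub_rate,
        with_gaps=with_gaps,
        quality=quality,
        seed=seed + 1,
    )
    mapper = Mapper(ref, config)
    records = list(
        mapper.map_reads(profiles_from_sim(sim_reads, config.match, config.mismatch))
    )
    truth_map = {t.read_id: t for t in truths}
    summary = summarize(
        records, truth_map, criterion, fragment_length=mapper.fragment_length
    )
    return ExperimentResult(summary, truths, n_reads)
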