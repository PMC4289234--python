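# fragmap

A two-phase mapper for **divergent short reads** — reads that differ from
the reference by 10–30% substitutions plus indels up to ~30 bp, the regime
where hash-table and Burrows-Wheeler mappers reject most reads. It targets
the same niche as exhaustive Smith-Waterman realignment (ancient DNA,
cross-species mapping, rescue of reads a fast primary mapper left
unmapped), at a fraction of the cost.

## Method

**Phase 1 — candidate search.** The genome is partitioned into disjoint
fragments of fixed length *F* (default 48 for genomes under 50 Mbp, 4800
above), the last fragment padded with N. For every window offset *s* of a
fragment (windows may overflow into the next fragments, so junction-spanning
reads are fully scored) the read induces a substitution-score series

    x_i = pssm[i, genome[s + i]],    pssm[i, g] = match·x  or  mismatch·x,

where `x = 1 − 10^(−q_i/10)` is the base-call correctness probability from
the phred score, match = 5 and mismatch = −4. The **maximum scoring
subsequence** of that series — the contiguous segment with maximal sum,
found in linear time — is the best *ungapped* local alignment of the read
at that offset. Each fragment keeps its best window; the scan over all
fragments and both strands is embarrassingly parallel and runs as a
vectorised JIT kernel.

**Ratio filter and mapping quality.** With best and second-best fragment
scores (immediate neighbours of the winner excluded — junction overflow is
not a repeat), `p = second/best` is treated as the probability the placement
is wrong and

    MAPQ = −100 · log₂ p,

capped at 254. A read is mapped only if MAPQ exceeds −100·log₂ 0.9 ≈ 15.2,
i.e. the ratio is below 0.9 — near-ties between distant fragments signal a
repeat and are rejected rather than guessed.

**Phase 2 — gapped alignment.** The read is aligned end-to-end to the
region spanning rightward from the winning fragment (length ≥ max(F, read
length) + F + 30) with a fitting dynamic program: leading/trailing region
positions are gap-free, substitutions come from the same PSSM, gaps cost
−26 per column (or affine −26/−1). The traceback yields position and CIGAR
for the SAM record; the real-valued MAPQ and score ratio are preserved in
`ZQ`/`ZR` tags.

A `--fast` mode scores every other read position in phase 1; a rescue mode
re-maps reads (or discordant pairs, ≥500 bp apart) that another mapper's
SAM left unmapped. The package also bundles the divergence **simulator**
(substitutions at a set rate, one ±1–30 bp indel per read with probability
0.5, truth CIGARs) and the two **evaluation criteria** used to score it:
basewise (at least one read base on the true genome coordinate) and
fragment-level (predicted fragment within ±1 of the true one).

## Worked example

```bash
fragmap simulate --genome-length 100000 --seed 1 --genome-out g.fa \
    -n 2000 --read-length 251 --sub-rate 0.1 \
    --out-fastq reads.fq --out-truth truth.tsv
fragmap map g.fa reads.fq -o out.sam
fragmap evaluate truth.tsv out.sam
```

which prints

```
total 2000: 100.0% correct, 0.0% incorrect, 0.0% rejected
```

— at 10% divergence every simulated read is placed on its true locus
(uniform-random genomes contain no repeats, so the ratio filter rejects
nothing; on real genomes repeat-ambiguous reads are rejected instead of
misplaced). The same pipeline is available as a library:

```python
import fragmap as fm
res = fm.accuracy_experiment(seed=1, sub_rate=0.1, with_gaps=True)
print(res.summary)        # total 2000: 100.0% correct, ...
```

Other subcommands: `fragmap rescue primary.sam genome.fa -o rescued.sam
[--paired]` re-maps rejected reads behind any primary mapper, and
`fragmap capacity 49152` prints the largest read length (a multiple of 16)
whose scoring profile fits a given on-chip memory budget — `2432` for the
49152-byte budget of the GPU generation the scan kernel's memory layout was
designed around.

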