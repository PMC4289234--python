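# Methods

## The mapping model

fragmap treats short-read mapping as two separable problems: *where* in the
genome a read belongs (candidate search) and *how* it aligns there (gapped
alignment). The split assumes a read has one dominant locus; multi-mapping
output is out of scope by design — ambiguity is detected and rejected
instead (see the ratio filter).

### Candidate search by maximum scoring subsequence

The reference is held padded with N to a multiple of the fragment length
F, and fragment *i* owns the windows starting in `[iF, (i+1)F)`. A window
is the read laid ungapped on the genome at one offset; its score series is
read position *i* against genome character `g` through a per-read
position-specific scoring matrix

    pssm[i, g] = match · x_i   if g equals the read base,
                 mismatch · x_i otherwise,      x_i = 1 − 10^(−q_i / 10),

with match = 5, mismatch = −4 (score units are arbitrary; only ratios and
orderings matter downstream). The maximum scoring subsequence of the series
— empty segment allowed, so scores are never negative — is the best
ungapped local alignment at that offset. Windows overflow past the owning
fragment's right edge (junction handling) and truncate at the padded end;
because any comparison involving N scores `mismatch · x`, the N pad and the
N tail can never extend a winning segment, which is why padding is inert. A
base with q = 0 contributes nothing anywhere: positions the sequencer had
no confidence in cannot drive a placement.

Strands: the reverse strand is scanned by reverse-complementing the read
profile (the PSSM reverses its position axis and permutes its character
axis) against the forward genome; the spelled-out contract is that a read
equal to the reverse complement of a genome substring scores exactly what
the substring scores forward. Whether the original scan covered both
strands was not documented; scanning both is the only behaviour consistent
with mapping real libraries, and `strands=forward` is available for
single-strand protocols.

The fast mode (stride 2) scores read positions 0, 2, 4, … only. It halves
the work per window but is *not* guaranteed to preserve the ranking of
fragments; the invariant that does hold (and is tested) is that the stride-2
score series is the even-index subsequence of the stride-1 series.

### Ratio filter and mapping quality

Let `best` and `second` be the two top fragment scores, where the runner-up
search excludes the winner and its immediate neighbours on the same strand
(radius 1, configurable): windows owned by adjacent fragments can describe
the *same* genomic placement across a junction, and counting that as a
repeat would wrongly reject junction reads. The placement-error probability
is estimated as `p = second / best` and

    MAPQ = −100 · log₂ p   (capped at 254; 255 is reserved in SAM),

so p = 0.9 gives 15.2003… and a clean placement with no positive runner-up
gives the cap. A read is accepted iff MAPQ exceeds the threshold; the
default threshold is stored as the *exact* value −100·log₂(ratio threshold)
so the MAPQ rule and the ratio rule (`ratio < 0.9`) coincide to the last
bit, with the printed 15.2 being a rounding. Raising the threshold (e.g. to
62 for contamination-sensitive ancient-DNA work) monotonically shrinks the
accepted set. A best score ≤ 0 (nothing aligned anywhere, e.g. an all-N
read) is rejected with MAPQ 0.

### Gapped alignment

Phase 2 aligns the read end-to-end to the region starting at the winning
fragment and extending rightward in whole fragments until it covers
`max(F, read length) + F + 30` bp (truncated at the genome end): the true
start can sit anywhere inside the winning fragment, and a deletion up to
the 30 bp indel allowance lengthens the genomic footprint. The dynamic
program is a fitting alignment — leading and trailing *region* columns are
free, read gaps are charged — because charging the unavoidable region
overhang (a 251-bp read in a ≥329-bp region) at −26 per column would swamp
any signal; a strict global alignment is not a meaningful reading of this
geometry. Two gap models: linear (−26 per gap column, the default) and
affine (open −26, extend −1, matching the configuration used by
Smith-Waterman baselines in this problem setting). Substitution scores come
from the same PSSM as phase 1, so base qualities inform both phases.

Determinism: traceback tie precedence is diagonal > up (read gap, CIGAR I)
> left (region gap, CIGAR D); the end column is the first maximum of the
final row; phase-1 ties break to the smallest (reference, fragment id,
strand `+` first) and, within a fragment, the smallest window offset. Equal
inputs therefore give byte-identical SAM, which the suite asserts; the @PG
header line carries the serialised configuration and deliberately no
timestamp.

An optional local mode (Smith-Waterman inside the region, soft-clipped read
ends) exists for exploratory use and is off by default: the evaluation
criteria and the accuracy claims all refer to end-to-end alignment.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| fragment length F | 48 (<50 Mbp) / 4800 | bp | the sizes used for bacterial-scale vs mammalian-scale references; smaller F sharpens localisation, larger F cuts the candidate count |
| match / mismatch | 5 / −4 | score | optimised for accuracy on 251-bp reads in the original study |
| gap (linear) | −26 | score/column | a gap must beat ~6 mismatches to open |
| gap open/extend (affine) | −26 / −1 | score | the Smith-Waterman baseline configuration |
| ratio threshold | 0.9 | — | empirical repeat/unique boundary; equivalent MAPQ 15.2 |
| MAPQ cap | 254 | — | SAM integer ceiling |
| runner-up exclusion radius | 1 | fragments | junction overflow reaches one fragment |
| region slack | 30 | bp | largest simulated indel |
| max read length calculator | (L+16)·4·5 bytes | — | profile bytes per read for the on-chip memory of the GPU generation the scan was designed for; 49152 B → 2432 bp |

## The simulator, and what passing tests show

`simulate_reads` emulates a divergence benchmark: uniform start and strand;
substitutions i.i.d. at the requested rate with the new base always
different (so rate 0.1 means 10% mismatches on top of sequencing error);
optionally one indel per read (probability 0.5, signed length uniform on
±[1, 30], insertion bases drawn uniformly, deletions removing genome
bases, all reads kept at constant length); constant Q30 qualities by
default, or a per-position phred profile. Truth records carry SAM-style
(pos, strand, CIGAR) and the suite checks round-trip consistency for every
simulated read. A minimal paired-end generator (insert 250 ± 25) exists to
exercise the rescue path.

What it does **not** emulate: realistic quality decay and miscalls (Q30 is
clean), repeat structure (an i.i.d. uniform genome has essentially none),
multiple indels per read, and coverage or GC biases. Consequences worth
stating plainly: on a uniform-random 100-kbp genome the full pipeline
places ~100% of 251-bp reads correctly at 10% divergence with or without
indels, with nothing rejected — there are no repeats for the ratio filter
to reject and no quality noise to erode scores. The published benchmark on
the real *E. coli* genome reports 96% / 93.1% with a few percent rejected;
the gap is the genome's repeat content and the realistic error model, not
the mapping algorithm, and the suite demonstrates the rejection mechanism
directly on genomes with planted duplications. Passing tests therefore
validate the machinery (scoring, selection, alignment, calibration), not a
claim about any particular real genome.

## Numerical and scale choices

* Scores are float64 throughout; score-equality assertions use 1e−9
  tolerances, and integer-valued test fixtures use saturating qualities
  (q = 600 makes x exactly 1.0 in float64) so worked examples are exact.
* The window scan is a numba kernel — branchless Kadane with four windows
  interleaved in registers (data-dependent branches mispredict ~50% and
  dominate otherwise) — with a chunked NumPy fallback asserted equal to it.
  The fitting DP is numba too; the affine traceback keeps separate
  open/extend provenance per gap state.
* Benchmarks in tests and in `scripts/acceptance.py` use a 100-kbp genome
  and 2,000 reads (≈3 minutes end to end on one CPU); property suites
  compare against brute-force oracles (segment enumeration, recursive
  memoised DPs) on hundreds of small random instances.
* The `workers` setting is accepted for interface compatibility; the scan
  already processes all fragments of a strand as one vectorised block, and
  the contract — asserted by the suite through the object-path/array-path
  equivalence — is that results are independent of how fragments would be
  partitioned across workers.
* Degenerate inputs: empty FASTA/FASTQ records, all-N reads, q = 0
  positions, fragment ids out of range, regions truncated at the genome
  end, and reads longer than the genome all have defined behaviour and
  tests.

## Known limitations

* One reported placement per read; no multi-mapping or split alignment.
* The runner-up exclusion radius and the exact mismatch quality weighting
  (`mismatch · x`, symmetric with the match rule) are design choices where
  the original description is silent or truncated; both are configurable
  and documented rather than hidden.
* Rescue mode re-maps reads independently; it does not use the mate as an
  anchor.
* The scan cost is linear in genome size per read; mammalian-scale
  references want the large-F default and the fast mode, and remain
  expensive relative to hash-based mappers on low-divergence reads — this
  tool is for the reads those mappers reject.
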