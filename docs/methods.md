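# Methods

## The read model

A rolling-circle-amplified library yields cDNA molecules of the form
`(adaptor + insert)^k`: `k` tandem repeats of a fixed ligation adaptor
(20–110 nt in practice; 24 nt by default here) interleaved with copies of
one short insert (a ribosome-protected fragment or synthetic spike-in,
15–40 nt). Nanopore sequencing reports one such molecule per read, with a
raw per-base error high enough (~10%) that a single insert copy is
unusable, but `k` noisy copies of the same insert allow an accurate
consensus.

Four read artifacts occur:

- **reverse** — the first-strand cDNA; adaptor copies appear
  reverse-complemented. The dominant, full-length class.
- **forward** — second-strand copies primed at internal sites; same
  orientation as the adaptor, systematically shorter and less reliable
  for quantification.
- **fused** — two independent molecules reported as one read (the second
  molecule entered the pore immediately after the first). The junction
  retains a sequencing-adaptor remnant. These must be split or they would
  be counted once instead of twice and could merge different inserts.
- **hairpin** — the exposed cDNA 3′ end folds back and primes
  second-strand synthesis, so the read continues into its own reverse
  complement with *no* remnant at the junction. Both halves carry the
  same insert, so hairpin reads are deliberately kept whole: the mirror
  half doubles the usable repeat count.

## Pipeline stages and the choices behind them

**Adaptor scanning.** The full adaptor is aligned semiglobally (free
end-gaps on the read only) on both strands; the best hit above the
identity floor (default 0.70) is accepted and the flanking segments are
scanned recursively. This greedy mask-and-rescan guarantees
non-overlapping, deterministically ordered hits. Scoring is unit
(+1 match / −1 mismatch / −1 gap, linear gaps): at 24-nt query scale
affine gaps add nothing, and unit scoring keeps the engine checkable
against a brute-force DP oracle. `N` never matches anything, a
conservative reading of basecaller ambiguity. Ties are resolved by the
smallest end coordinate among maximal-scoring ends plus a fixed traceback
preference (diagonal, deletion, insertion), making all outputs
byte-reproducible. For end-to-end (global) alignments the reported count
vector is canonicalised to the co-optimal alignment with the most matched
columns, which is symmetric in the two sequences.

**Classification.** Fewer than two adaptor hits → *unclassified*. Any
internal sequencing-adaptor remnant → *fused* (remnant presence is direct
fusion evidence regardless of orientation); remnants within 5 nt of
either read end are trimming leftovers and never count. Otherwise a
strand flip → *hairpin*, uniform `+` → *forward*, uniform `−` →
*reverse*. Fused reads are split at each internal remnant midpoint with
the remnant span excised, so the children plus the excised spans exactly
reconstruct the parent; children are re-annotated independently.

**Insert extraction.** Each gap between consecutive same-strand hits — and
the two terminal gaps — is a candidate insert; candidates outside
[15, 40] nt are dropped, which also removes most truncated terminal
copies. The gap at a hairpin junction (flanking hits on opposite strands)
is never extracted. Minus-strand inserts are reverse-complemented so all
retained inserts share the canonical (reference-sense) orientation; this
is why the consensus of a read and of its reverse complement are
identical.

**Two-pass MSA and consensus.** The inserts of one read are progressively
aligned: the medoid insert (highest total pairwise score; ties by input
index) seeds a profile, and the remaining inserts join by decreasing
score to the medoid. Profile columns score an incoming base by the mean
per-row match/mismatch score (gap rows contribute the gap penalty), so
profile and gap scores stay on the same ±1 scale. Rows whose mean
pairwise identity (identical non-gap columns over columns where either
row is non-gap) falls below 0.70 are removed — the cutoff for this
removal step is a package choice, exposed in `FilterConfig` — and the
survivors are re-aligned from scratch. The consensus is per-column
plurality: a strict gap plurality omits the column, base ties break in
the fixed order A<C<G<T, and `N` counts toward coverage but never beats a
concrete base. An MSA aligner is deliberately in-house: at ≤40 nt × ≤~25
rows, exact pairwise DP plus profile merging is fast and dependency-free,
and keeps the whole pipeline deterministic.

**QC filters.** Defaults are the Ribo-seq thresholds: ≥3 inserts,
≥4 adaptors, consensus ≥20 nt, insert length 15–40 nt. The first failing
rule in the fixed order `no_adaptor → too_few_adaptors → too_few_inserts
→ low_quality_inserts → consensus_too_short → unclassified` becomes the
single discard tag, so the discard taxonomy partitions the discarded
reads.

**Accuracy.** `accuracy = (L − (mismatches + indels)) / L × 100`, where
the counts come from a *minimum-edit* global alignment of the consensus
to the reference and `L` is the number of alignment columns. Using a
minimum-edit alignment makes `mismatches + indels` exactly the edit
distance (the test suite verifies this against two independent oracles),
removing any dependence on aligner scoring conventions.

**Quantification.** Only passing reverse and hairpin records are counted;
forward reads are emitted in the consensus FASTA (flagged by class) but
never counted, because fragmented second-strand copies would double-count
and bias abundances. A consensus is assigned to the best-identity
reference (either orientation) when identity ≥ 0.80 — consensus error is
far below 20%, so the threshold is generous; it is exposed as a
parameter. The recovery fit regresses `log10(count + 0.5)` on `log10`
input proportion: a spike-in spanning two orders of magnitude would
otherwise let the largest class dominate a linear-scale R². The
pseudocount keeps zero-count classes finite and is configurable.

## The simulator

`SimParams` defaults encode the study conditions: read length
~ Normal(550, 80) nt (the observed read-length peak set by reverse-
transcriptase processivity), a 24-nt adaptor, 30-nt inserts, class
fractions forward 0.20 / reverse 0.55 / fused 0.10 / hairpin 0.15 (the
true artifact proportions are not published; these are plausible
round numbers, config-exposed), and a 10% total error model
(5% substitution / 2.5% insertion / 2.5% deletion, an R9.4-era
basecalling figure; also config-exposed). Forward reads are shortened by
a fragmentation factor U(0.3, 0.8), encoding "shorter and less abundant"
qualitatively. The adaptor and sequencing-adaptor ("remnant") defaults
are synthetic sequences designed for this package, not any vendor's
oligos.

Simplifications, and what passing tests therefore do and do not show:

- Reads contain *whole* repeat units (forward truncation is also to unit
  boundaries, with a two-unit floor so every read stays classifiable).
  Real reads truncate anywhere; at the default error rates the indel
  process produces ragged ends anyway. This choice makes the zero-error
  limit exact — classification, per-read insert counts and consensus all
  match truth bit-for-bit — which is the property the test suite pins.
- Errors are i.i.d. per base; real nanopore error is homopolymer- and
  context-dependent. Consensus accuracy on real data will be somewhat
  worse at a given nominal error rate.
- A fused read joins two molecules carrying the *same* insert, keeping
  one truth record per read well-defined. Splitting correctness is
  exercised structurally (base conservation, child counting), not across
  different inserts.
- Qualities are constant placeholders; the pipeline ignores qualities by
  design (redundancy, not base quality, drives the consensus).

## Numerical and degenerate-input conventions

- All coordinates are 0-based half-open on the read as stored.
- Reads shorter than the adaptor yield no hits; a semiglobal optimum that
  consumes no target base (identity 0) is never accepted as a hit.
- MSA requires ≥2 inserts; fewer signals `too_few_inserts`. Fewer than 2
  surviving rows after the identity filter signals `low_quality_inserts`.
- Profile-DP traceback compares float sums built from identical operand
  sequences, so tie resolution is exact and platform-stable.
- Empty FASTQ input is not an error: the pipeline writes valid empty
  outputs and reports zero units.

## Problem sizes

The bundled acceptance script simulates 20,000 reads for the spike-in
recovery target, 1,000 reads (≥5 repeats each) for the consensus-accuracy
target and 2,000 reads for the repeat-yield target; the test suite runs
scaled-down versions of the same computations (6,000 / 400 / 600 reads)
with identical thresholds.

## Known limitations

- Single ligation adaptor per scan is the optimised path; adaptor pools
  are supported (best hit across the pool per segment) but demultiplexing
  statistics per adaptor are not reported.
- No polishing against a reference and no quality-weighted consensus.
- Downstream analyses (genome alignment, P-site calling, enrichment) are
  out of scope; the consensus FASTA is the hand-off point.
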