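# Methods

## Gene models and coordinates

Genes are ordered lists of exon intervals in **transcript orientation**:
exon 1 is the 5′-most exon of the mRNA, so for a minus-strand gene it is the
genomically last interval and its sequence is the reverse complement of the
genomic slice. Internally all coordinates are 0-based half-open; GFF3 I/O is
1-based inclusive (reading via `gffutils`, with an in-memory database).
`N` bases are carried through verbatim and never match anything during
alignment, themselves included.

## The junction library

For each gene with exons $e_1 \dots e_n$ the library holds one sequence per
ordered exon pair $(i,j)$, $i<j$: the last `flank` bases of $e_i$
concatenated with the first `flank` bases of $e_j$, clipped at exon
boundaries when an exon is shorter than the flank. The breakpoint offset
(bases contributed by the upstream exon) is stored with each junction.

**Flank default = 149 bp (read length − 1).** Any read that overlaps a
junction breakpoint at all is then fully contained in the junction sequence,
so the read-filtering step never loses junction-spanning reads. A tighter
flank of `read_length − min_overlap` (142 bp) suffices for *counting* —
breakpoint coverage below `min_overlap` never supports a junction anyway —
but drops reads overlapping a junction by 1–7 bases at the filtering stage,
which is why the wider flank is the default. The flank is a parameter
everywhere.

## Alignment

A deliberately minimal, fully specified aligner: exact seeds of
`seed_length` (default 20) bases anchored at every read offset, looked up in
a k-mer index of the reference set; every candidate (reference, diagonal) is
verified by ungapped full-read comparison allowing `max_mismatches`
(default 2) mismatches; both orientations are tried; indels are not modeled
(the read simulator introduces none). Because a read of length $L$ with $m$
mismatches contains an exact run of at least $(L-m)/(m+1)$ bases, the seed
step is lossless whenever $L \ge (m+1)k + m$ — satisfied with room to spare
at $L=150$, $k=20$, $m=2$ — so the seeded aligner provably equals an
exhaustive all-offsets scan, and the test suite verifies that equality
against an independently written sliding-window Hamming oracle.

## Counting and calling rules

A read supports junction $(i,j)$ iff it aligns to that junction sequence and
covers at least `min_overlap` (default 8) bases on each side of the
breakpoint. If a read supports several junctions, only those at the minimal
mismatch count are kept; remaining ties go to the ambiguity policy —
default **discard and tally** (fractional assignment is available as
`count_all`). Mates are processed independently, but a fragment can
contribute at most one count to any single junction (both mates spanning the
same junction count once).

Calling: the canonical transcript requires every consecutive junction at
`min_support` (default 3) reads; each supported skip junction $(i,j)$,
$j>i+1$, yields a transcript retaining exons $1..i, j..n$ provided its
flanking consecutive junctions $(i-1,i)$ and $(j,j+1)$ (where they exist)
are also supported. Phasing of several co-occurring skip events is not
identifiable from junction evidence alone; each is reported as a single-skip
transcript and the call is flagged ambiguous. The automated `min_support`
rule stands in for manual inspection of junction hits; 3 reads is a
deliberately permissive floor that the ~20× junction coverage of the demo
clears by two orders of magnitude.

Quantification divides each called transcript's mean count over the
junctions *unique* to it (within the called set) by the number of examined
reads, in CPM. For the canonical + ΔEx2Ex3 pair the unique sets are
{(1,2),(2,3),(3,4)} and {(1,4)}; the shared (4,5) junction is excluded.

**Known bias.** Junction-spanning positions are a fixed window per junction
(read length − 2·min_overlap + 1), while a transcript's total fragment
positions scale as $L - F + 1$ (fragment length $F$), so per-junction counts
scale as $a_t \cdot L_t/(L_t-F+1)$: the shorter isoform (633 bp) is
over-counted relative to the canonical (1104 bp) by ~×1.2 at the default
$F=200$, giving an expected estimated ratio of ≈ 8.4 for a true 10:1
mixture. This sits comfortably within the ±30 % recovery band the tests
assert and is documented rather than corrected — the estimator is the plain
junction-count ratio the screen motivates. Junctions adjacent to short
terminal exons (e.g. (4,5) with a 120-bp exon 5) are additionally
under-counted by end effects; they are excluded from quantification by the
unique-junction rule in the two-transcript case anyway.

## Synthetic fixture

Exon lengths of the Dmrt1-like gene default to [354, 241, 230, 159, 120] bp
— a free choice constrained only by the two fixed totals (canonical 1104 bp;
exons 2+3 sum to 471 bp so the skip product is 633 bp). Introns are a
uniform 500 bp, scaffolds carry 200 bp of random padding, and every gene
sits on its own scaffold (which makes sub-genome extraction a simple
scaffold subset). Two Dmrt paralogs (3–5 exons, independent uniform-random
sequences, the first on the minus strand) provide junction-specificity
probes with zero homology by construction — adequate for testing that the
screen never credits Dmrt1 junctions with paralog reads, though weaker than
real paralogy, where conserved domains produce near-identical stretches; the
mismatch threshold and ambiguity policy are the controls that matter there.
A 3-exon housekeeping gene (1060 bp mRNA) serves as normalizer.

## Expression scenario

Defaults encode the qualitative thermal pattern: canonical FPT gonad
abundance 10 units at every stage, MPT fold change 1, 1, 1, 4, 8 across
stages 9, 12, 15, 19, 22; the skipping isoform tracks the canonical at one
tenth everywhere; the normalizer is 30 units in every cell. Tissue mixing
models what was sampled: `gonad_fraction` 0.02 (trunk) at stage 9, 0.1
(adrenal–kidney–gonad complex) at 12/15, 1.0 (isolated gonads) at 19/22,
with monomorphic AK expression (5 / 0.5 / 30 units per transcript), so the
observable fold change shrinks toward 1 as the gonad fraction falls — the
masking effect. Twelve embryos per stage × temperature (the qPCR arm's
sampling depth), per-embryo lognormal biological noise (σ = 0.4 on the
natural-log scale, ≈ 40 % CV), and a shared lognormal loading factor
(σ = 0.3) that reference-gene normalization must cancel.

Read simulation: fragments of Normal(200, 30) bp (clipped to
[read length, transcript length]) at uniform positions, transcript of origin
drawn ∝ abundance × length, 150-bp pairs, i.i.d. substitution errors
(default 0.001), constant placeholder qualities. No indels, quality decay,
PCR duplicates or GC bias — so passing tests demonstrate the logic of the
screen, not robustness to real library artifacts.

qPCR simulation: $Cq = c_0 - \log_E(\text{abundance}) + \mathcal N(0, 0.1)$
per technical replicate (duplicates), per-assay efficiencies 1.95 / 1.90 /
2.00 and unit-input intercepts 24 / 26 / 22 cycles; an 8-point 1:5 dilution
series per assay from the pooled stock, also in duplicate. Zero abundance is
recorded as a missing Cq ("no amplification"), which the QC step discards.

## qPCR analysis decisions

"Deviation" of technical duplicates is interpreted as the range (max−min),
discarded when **strictly** greater than 0.5 cycles; the CV criterion
(≥ 10 %) is applied to Cq values directly, with a switch for linear-scale
CV. Replicates are summarized by the arithmetic mean Cq before Pfaffl. The
Pfaffl calibrator is the per-assay mean Cq of the pooled standard at a fixed
mid-curve dilution step (default step 3) — stable, present on every plate,
and cancelling in any between-group comparison.

## Statistics decisions

- ANOVA is two-way fixed-effects with interaction (temperature, stage) on
  natural-log expression, Type-II sums of squares (balanced designs make
  Type I/II/III coincide). A constant response returns F = 0, p = 1 for
  every term rather than 0/0.
- Post hoc tests are Welch (unequal-variance) t-tests on log expression,
  per stage, α = 0.05, deliberately without multiplicity correction; a
  Bonferroni-style correction is easy to apply downstream but is off by
  default to match the plain per-stage α procedure. Note the cost: with
  three true-null stages, the chance that *some* null stage reaches p < 0.05
  is ≈ 1 − 0.95³ ≈ 14 % per experiment, which is why seed-ensemble checks in
  the tests bound the false-positive rate per stage rather than jointly.
- Fold changes are reported in log2 units; swapping temperature labels
  negates them exactly.
- The RNA-seq differential-expression path is a Welch t-test on
  log2(CPM+1); a negative-binomial count GLM is intentionally out of scope —
  the junction screen is the contribution under test, and the package's own
  qPCR statistics are t-test based. Output tables carry the test name.
- The canonical/isoform ratio analysis computes per-sample ratios (samples
  with a zero denominator excluded and logged), cell means per stage ×
  temperature, and per-stage Welch t-tests on the log ratio. Because both
  transcripts share every per-sample factor, normalizer and loading effects
  cancel exactly in the ratio.

## Problem sizes

The shipped analyses and tests use 50,000 read pairs for the discovery demo
(junction coverage ≈ 7,000× consecutive, ≈ 850 skip), 20,000 pairs per seed
× 10 seeds for ratio recovery, 60-seed ensembles for the stage-pattern
checks and 300 for standard-curve R², sizes chosen so the full suite runs
in about two minutes while every stochastic assertion retains a comfortable
margin (e.g. ratio-recovery SD ≈ 5 % against a ±30 % band).

## Limitations

- No spliced alignment or discovery of splice sites outside annotated exon
  boundaries; no indel tolerance; transcript assembly is out of scope.
- Junction evidence cannot phase multiple co-occurring skips into full
  transcripts; such calls are junction-level and flagged.
- Paralog divergence in the fixture is total, which understates the
  specificity challenge of recently duplicated families.
- The qPCR noise model has no plate, pipetting-gradient or inhibitor
  effects; QC thresholds are exercised mostly by the tails of well-behaved
  noise.
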