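# Methods

This note documents the models, procedures and numerical choices behind
`asmappraise`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Coordinate and sequence conventions

All coordinates are 0-based half-open. Sequences are normalised on input to
{A, C, G, T, N}; IUPAC ambiguity codes become N (counted and logged) so that
real assemblies parse without manual cleaning. PSL and BED use this
convention natively; GFF3 is converted on read. Scaffolds are decomposed
into contigs at N-runs of ≥ `gap_threshold` bases (default 10 bp, a common
contig-splitting convention; there is no universal standard, so it is
configurable) and shorter N-runs remain inside contigs. Decomposition is
lossless: contigs plus recorded gaps reconstruct every scaffold exactly.

## Alignment engine

The pipeline's alignments come from a seed-and-extend engine:

1. **Index** — every k-mer (default k = 12) of every target is stored in a
   sorted code/position array; k-mers containing N are excluded. Minus-strand
   matches are found by reverse-complementing the query, not by canonical
   k-mers.
2. **Seeding and chaining** — query k-mers are sampled at a stride (default
   4), looked up by binary search, and hits are grouped into co-linear
   clusters: same target, diagonal within `band_width` of its neighbour, and
   consecutive seeds no more than `max_chain_gap` (2 kbp) apart in the query.
   K-mers occurring more than `max_seed_hits` (64) times are skipped, which
   is what bounds work inside high-copy repeats.
3. **Banded extension** — each cluster is extended by local (Smith–Waterman
   style) dynamic programming with affine gaps, restricted to a diagonal
   band covering the cluster ± `band_width`, over a window extending at most
   `max_extension` (2 kbp) past the outer seeds. Scoring defaults are
   match +1, mismatch −3, gap open −5, gap extend −2 (a gap of length g
   costs `gap_open + g·gap_extend`); these behave like classical nucleotide
   aligners on ≥ 90%-identity genomic DNA. When the band and window cover
   the whole problem, the reported score is exactly the unrestricted
   full-matrix optimum — the test suite asserts this equality against an
   independent full-DP implementation on hundreds of planted-mutation pairs.
4. **Normalisation** — indels are left-shifted through homopolymers (a gap
   run moves left while the preceding column is a match whose base equals
   the gap's last base). This is score-preserving and makes discrepancy
   positions reproducible across equivalent optimal alignments.

Identity is `matches / (matches + mismatches + gap bases on both sides)`.
Alignments are filtered by per-stage identity/length cutoffs and ~contained
duplicates (adjacent clusters rediscovering one another) are suppressed.
`best_alignment` breaks score ties deterministically by more matches, then
lexicographically smallest target id, then smallest target start.

The seed-and-extend premise bounds the engine's domain: a true alignment
with no exact k-mer seed (identity far below ~90%, or queries of a few tens
of bases) is invisible to it. The stage cutoffs used by the pipeline all sit
at ≥ 90% identity, inside that domain. External alignments (BLAT PSL) can be
substituted wholesale at every stage.

## Accuracy model

Contigs are aligned to the trusted set; each trusted base is attributed to
its best-scoring covering alignment, so repeat-induced overlapping
alignments never double-count an event. The three rates share one
denominator — aligned trusted bases — which keeps them commensurable; the
alternative (total trusted bases) is recoverable as
`rate × aligned / total`. Indels are counted in bases by default (a 2-bp gap
contributes 2); per-event counting is available
(`tally_discrepancies(..., indel_unit="events")`). Coverage is the union of
aligned trusted spans over total trusted bases. Per-base attribution
requires the column-level events the internal aligner records; PSL input
carries only aggregate counts, so overlapping PSL alignments are tallied
whole with a warning.

## Mis-assembly detection

The paper-scale procedure is: align contigs to a chromosome-labelled
reference, keep uniquely aligned segments, and count contigs with segments
of at least the size cutoff on two or more chromosomes. Two points were
genuinely open and are settled here as follows:

* **Uniqueness** — a segment is unique when its score is at least
  `uniqueness_ratio` (default 1.1) times every other alignment overlapping
  at least half of its query span. Both numbers are configurable.
* **Normalisation** — only the ingredients of the normalisation (event count
  N and mean scaffold length L) are well defined externally; the formula
  used here is `N · C / L` with C a scale constant shared across the
  assemblies being compared, defaulting to the smallest mean scaffold length
  among them, so the most fragmented assembly keeps its raw count. This
  choice is deliberately prominent: any monotone alternative can be obtained
  by substituting C.

Same-chromosome segments more than 1 Mbp apart or in inconsistent order are
reported as intrachromosomal events but excluded from the cross-chromosome
counts by default. Event counts are monotone non-increasing in the size
cutoff by construction, and the test suite checks this on every synthetic
run.

## Pair classification

A pair is proper iff both ends map to one scaffold, on opposite strands
with the leftmost end on plus, and the outer distance lies within
`insert_mean · (1 ± tolerance)` (default tolerance 0.3, a common
proper-pair convention). Failures take the first matching label in the
fixed order both_unmapped, one_end_unmapped, cross_scaffold,
discordant_orientation, discordant_distance, so every pair gets exactly one
label.

## Novel sequence

Contigs are tiled with 1-kbp chunks; a contig's sub-kbp tail is absorbed
into its final chunk (so chunks are 1000–1999 bp) rather than searched
separately, and whole contigs shorter than 1 kbp are searched as one piece.
After aligning chunks to the reference at ≥ 90% identity, the aligned
sub-intervals of each chunk are subtracted (any qualifying hit masks; not
only the best) and remaining runs strictly longer than 50 bp are putative
novel segments. Screening against a contaminant or annotation FASTA
relabels segments aligning at ≥ 98% identity over ≥ 200 bp. Shared novel
sequence between two assemblies is reported in both directions (a→b and
b→a totals differ in general); the single-number convention is their
minimum. GC content is G+C over A+C+G+T with N excluded from the
denominator.

## Gene representation

Transcript base coverage follows the chunked best-hit procedure: each
chunk's single best alignment to the unspliced transcript set is kept if it
exceeds 95% identity (strictly) over ≥ 100 bp; covered bases are the union
of retained aligned transcript intervals, pooled over all transcripts.
cDNA completeness aligns whole cDNAs to assembly scaffolds at ≥ 90%
identity and asks whether the best alignment's aligned *query* bases reach
90/50/20% of the cDNA length — query bases because the cutoff is a fraction
of cDNA length. Gene fragmentation counts distinct scaffolds whose aligned
reference span intersects a gene locus. Transcripts are modelled as
genomic-interval sequences (unspliced), so no spliced alignment is needed.

## Synthetic data and what passing tests mean

`generate_genome` samples i.i.d. bases at a target GC (default 41.6%),
plants one exact-copy repeat family (default 10% of the genome in 500-bp
units), and places one gene locus per ~50 kbp (1–2 kbp, avoiding repeats),
with transcripts extracted verbatim. `corrupt_assembly` then:

* applies per-base substitutions/insertions/deletions at the specified
  rates, with the deletion probability multiplied (default 3×) inside
  homopolymers ≥ 4 bp — the flowgram-platform error signature. Indel events
  are single-base, matching the per-base rate semantics; adjacent events
  form longer runs naturally, and the accuracy module counts bases either
  way;
* fragments each chromosome into contigs with lengths uniform in
  [0.5, 1.5] × L₀ where L₀ = target N50 / 1.118 (the length-weighted median
  of that family), giving realized N50s within ±20% of target; the truth
  bases between consecutive contigs (200–800 bp) are cut out and represented
  as N-runs of the true gap length, so scaffold-relative distances are
  preserved and trusted coverage is realistically below 100%;
* builds misjoined contigs from pairs of 25–40 kbp arms on different
  chromosomes, contaminant contigs from a bundled synthetic foreign genome
  at 50% GC (the E. coli stand-in), and 1-kbp novel inserts at 54.2% GC
  placed inside ordinary contigs and absent from the emitted reference.

Every event is recorded in a `TruthLedger` with truth and assembly
coordinates, and all randomness comes from one seeded generator per
operation (identical spec + seed ⇒ byte-identical FASTA).

The generator reproduces the *statistical* structure of draft assemblies,
not their mechanism: errors are i.i.d. (no coverage-dependent error
clustering), repeats are exact copies of a single family (no repeat
hierarchy or divergence), there is no heterozygosity, and reads are
error-free. Passing recovery tests therefore demonstrate that the metrics
measure what they claim on data with known truth — they do not certify
behaviour on repeat structures or error processes the generator does not
model.

Two expectations are deliberately conservative. The expected proper-pair
fraction counts a read as unmappable if it lies outside any contig or
retains fewer than 24 non-repeat bases (such reads have no unambiguous
placement), so the measured fraction is checked against a lower bound.
And planted-versus-recovered coverage is asserted on repeat-free genomes,
because on repeat-rich genomes trusted bases inside repeats are genuinely
alignable from elsewhere in the assembly even when their local context is
missing — an inherent property of the metric, visible as a fraction of a
percentage point of extra coverage.

## Validation harness and problem sizes

`asmappraise.recovery.run_recovery` closes the loop for one seed: generate,
corrupt, appraise with every module, and compare with the ledger. The
default study conditions are a 5 Mbp genome over 4 chromosomes, error rates
2×10⁻⁴ / 5×10⁻⁵ / 1×10⁻⁴ (sub/ins/del, 3× homopolymer bias), N50 targets
20 kbp / 100 kbp, 5 misjoins, 2% contaminant contigs, 50 × 1 kbp novel
inserts, 12 × 40 kbp trusted clones (~10% of the genome, enough aligned
bases for the 3-standard-error rate checks to have power) and 10,000
simulated 2-kbp pairs. One run takes well under a minute on a single core;
the acceptance script and the acceptance tests both execute ten seeded
runs. Pipeline stages use a narrower DP band (16) than the aligner default
(64) because planted indels are single-base; the oracle-equivalence tests
use a full-width band.

## Known limitations

* No spliced or translated alignment; transcripts must be unspliced.
* Mis-assembly breakpoints are reported at alignment-segment resolution,
  not refined to the base.
* The novel-sequence procedure attributes unaligned flanks shorter than the
  alignment length cutoff to novelty; at insert boundaries this can
  slightly overshoot the planted total (observed ~1–2%).
* The engine targets desk-scale comparisons (megabases); genome-scale
  mapping interoperates via PSL from external aligners rather than being
  performed internally.
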