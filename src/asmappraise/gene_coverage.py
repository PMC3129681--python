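"""Gene representation metrics: transcript base coverage, cDNA completeness
at length-fraction cutoffs, and per-gene scaffold fragmentation.

Transcript coverage follows the chunked best-hit procedure: assembly chunks
are aligned to unspliced transcripts, only the single best alignment per
chunk is kept, alignments below the identity/length cutoff (default strictly
>95% identity over >=100 bp) are dropped, and the covered transcript bases
are the union of the retained aligned intervals. cDNA completeness instead
aligns full cDNAs to assembly scaffolds and asks whether the best alignment
covers a given fraction of the cDNA's length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import PairwiseAlignment, interval_total
from .aligner import best_alignment
from .io_formats import GenomicInterval, SequenceRecord


@dataclass
class TranscriptCoverage:
    transcript_id: str
    length: int
    covered_bases: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.length


@dataclass
class CompletenessCurve:
    cutoffs: list[float]
    counts: list[int]
    total: int

    @property
    def fractions(self) -> list[float]:
        return [c / self.total for c in self.counts]


def _best_per_query(alignments: list[PairwiseAlignment]) -> list[PairwiseAlignment]:
    by_query: dict[str, list[PairwiseAlignment]] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    return [best_alignment(v) for v in by_query.values()]


def transcript_base_coverage(
    chunk_alignments: list[PairwiseAlignment],
    transcripts: list[SequenceRecord],
    min_identity: float = 0.95,
    min_align_length: int = 100,
) -> tuple[float, list[TranscriptCoverage]]:
    """Pooled percent of transcript bases covered, plus per-transcript detail.

    Queries are assembly chunks, targets transcripts; only each chunk's best
    alignment counts, and it must exceed min_identity (strictly) over at
    least min_align_length aligned columns.
    """
    retained = [
        a
        for a in _best_per_query(chunk_alignments)
        if a is not None
        and a.identity > min_identity
        and a.aligned_columns >= min_align_length
    ]
    by_transcript: dict[str, list[tuple[int, int]]] = {}
    for a in retained:
        by_transcript.setdefault(a.target_id, []).extend(a.target_block_intervals())
    per: list[TranscriptCoverage] = []
    total_len = total_cov = 0
    for t in transcripts:
        covered = interval_total(by_transcript.get(t.id, []))
        covered = min(covered, len(t.sequence))
        per.append(TranscriptCoverage(t.id, len(t.sequence), covered))
        total_len += len(t.sequence)
        total_cov += covered
    if total_len == 0:
        raise ValueError("transcript set is empty")
    return 100.0 * total_cov / total_len, per


def cdna_completeness(
    cdna_alignments: list[PairwiseAlignment],
    cdnas: list[SequenceRecord],
    min_identity: float = 0.90,
    length_cutoffs: tuple[float, ...] = (0.9, 0.5, 0.2),
) -> CompletenessCurve:
    """Count cDNAs whose best alignment to the assembly covers at least each
    length-fraction cutoff of the cDNA (aligned query bases, not target)."""
    best = {a.query_id: a for a in _best_per_query(cdna_alignments) if a is not None}
    counts = []
    for cutoff in length_cutoffs:
        n = 0
        for c in cdnas:
            a = best.get(c.id)
            if a is None or a.identity < min_identity:
                continue
            aligned_q = sum(ln for _q, _t, ln in a.blocks)
            if aligned_q >= cutoff * len(c.sequence):
                n += 1
        counts.append(n)
    return CompletenessCurve(list(length_cutoffs), counts, len(cdnas))


def gene_fragmentation(
    locus: GenomicInterval,
    scaffold_alignments: list[PairwiseAlignment],
    reference_lengths: dict[str, int] | None = None,
) -> int:
    """Number of distinct scaffolds whose aligned reference span intersects
    the gene locus (queries are assembly scaffolds, targets chromosomes)."""
    if locus.start < 0 or locus.end <= locus.start:
        raise ValueError(f"invalid locus interval {locus}")
    chrom_len = None
    if reference_lengths is not None:
        if locus.chrom not in reference_lengths:
            raise ValueError(f"locus chromosome {locus.chrom!r} not in reference")
        chrom_len = reference_lengths[locus.chrom]
    else:
        sizes = {a.target_id: a.target_size for a in scaffold_alignments}
        chrom_len = sizes.get(locus.chrom)
    if chrom_len is not None and locus.end > chrom_len:
        raise ValueError(f"locus {locus} extends beyond chromosome end {chrom_len}")
    scaffolds = {
        a.query_id
        for a in scaffold_alignments
        if a.target_id == locus.chrom
        and a.target_start < locus.end
        and a.target_end > locus.start
    }
    return len(scaffolds)
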