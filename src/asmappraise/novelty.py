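"""Novel-sequence estimation by chunked alignment.

Contigs are broken into 1-kbp non-overlapping segments (a sub-kbp tail is
searched as part of the penultimate segment, i.e. the final segment is
extended); segments are aligned to the comparison reference, aligned
sub-intervals are subtracted, and remaining runs strictly longer than 50 bp
are putative novel sequence. Putative segments can then be screened against
a contaminant (or annotation) sequence set, shared between assemblies, and
summarised by GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .alignment import PairwiseAlignment, subtract_intervals
from .aligner import AlignerParams, align_pairwise, build_index
from .io_formats import ScaffoldedAssembly, SequenceRecord


@dataclass
class ChunkSegment:
    contig_id: str
    start: int  # contig coordinates, 0-based half-open
    end: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}"

    @property
    def record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.sequence)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class NovelSegment:
    origin: ChunkSegment
    start: int  # contig coordinates of the unmapped run
    end: int
    sequence: str
    gc: float
    status: str = "putative_novel"  # putative_novel | contaminant | annotated_known

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.origin.contig_id}|{self.start}-{self.end}"


def chunk_contigs(assembly: ScaffoldedAssembly, chunk_size: int = 1000) -> list[ChunkSegment]:
    """Tile every contig with non-overlapping chunk_size segments; the final
    segment absorbs any sub-chunk tail, and contigs shorter than chunk_size
    yield a single whole-contig segment."""
    if chunk_size < 100:
        raise ValueError("chunk_size must be >= 100")
    out: list[ChunkSegment] = []
    for contig in assembly.contigs:
        m = len(contig)
        seq = contig.sequence
        if m <= chunk_size:
            out.append(ChunkSegment(contig.id, 0, m, seq))
            continue
        n_seg = m // chunk_size
        for i in range(n_seg):
            s = i * chunk_size
            e = (i + 1) * chunk_size if i < n_seg - 1 else m
            out.append(ChunkSegment(contig.id, s, e, seq[s:e]))
    return out


def find_unmapped_segments(
    segments: list[ChunkSegment],
    reference_alignments: list[PairwiseAlignment],
    min_identity: float = 0.90,
    min_novel_length: int = 50,
) -> list[NovelSegment]:
    """Subtract reference-aligned sub-intervals from each chunk; runs strictly
    longer than min_novel_length become putative novel segments."""
    by_query: dict[str, list[tuple[int, int]]] = {}
    for a in reference_alignments:
        if a.identity >= min_identity:
            by_query.setdefault(a.query_id, []).extend(a.query_block_intervals_plus())
    out: list[NovelSegment] = []
    for seg in segments:
        covered = by_query.get(seg.id, [])
        for s, e in subtract_intervals((0, len(seg)), covered):
            if e - s > min_novel_length:
                subseq = seg.sequence[s:e]
                out.append(
                    NovelSegment(
                        origin=seg,
                        start=seg.start + s,
                        end=seg.start + e,
                        sequence=subseq,
                        gc=_gc_or_nan(subseq),
                    )
                )
    return out


@dataclass
class ScreenResult:
    segments: list[NovelSegment]  # all inputs, relabelled where matched
    matched_bases: int
    total_bases: int
    by_source: dict[str, int]  # matched bases per contaminant sequence

    @property
    def matched_fraction(self) -> float:
        return self.matched_bases / self.total_bases if self.total_bases else 0.0


def screen_contamination(
    novel: list[NovelSegment],
    contaminant_db: list[SequenceRecord],
    min_identity: float = 0.98,
    min_length: int = 200,
    label: str = "contaminant",
    params: AlignerParams | None = None,
) -> ScreenResult:
    """Relabel putative novel segments matching a contaminant/annotation set.

    A segment is relabelled when it aligns to any database sequence at
    >= min_identity over >= min_length aligned columns. The same routine
    screens against a known-sequence FASTA with ``label="annotated_known"``.
    """
    if not contaminant_db:
        raise ValueError("contaminant_db must be non-empty")
    params = params or AlignerParams(
        min_identity=min_identity, min_align_length=min_length, min_chain_seeds=1
    )
    params = replace(params, min_identity=min_identity, min_align_length=min_length)
    index = build_index(contaminant_db, params.k)
    out: list[NovelSegment] = []
    matched_bases = 0
    total = 0
    by_source: dict[str, int] = {}
    for seg in novel:
        total += seg.length
        if seg.status != "putative_novel":
            out.append(seg)
            continue
        hits = align_pairwise(SequenceRecord(seg.id, seg.sequence), index, params)
        if hits:
            matched_bases += seg.length
            by_source[hits[0].target_id] = by_source.get(hits[0].target_id, 0) + seg.length
            out.append(replace(seg, status=label))
        else:
            out.append(seg)
    return ScreenResult(out, matched_bases, total, by_source)


@dataclass
class SharedNovelSummary:
    a_total: int
    b_total: int
    a_shared: int
    b_shared: int

    @property
    def a_exclusive(self) -> int:
        return self.a_total - self.a_shared

    @property
    def b_exclusive(self) -> int:
        return self.b_total - self.b_shared

    @property
    def shared(self) -> int:
        """Single shared-bases figure: the intersection convention (the
        smaller of the two directional totals)."""
        return min(self.a_shared, self.b_shared)


def _directional_shared(
    source: list[NovelSegment],
    targets: list[NovelSegment],
    min_identity: float,
    params: AlignerParams,
) -> int:
    if not targets:
        return 0
    index = build_index(
        [SequenceRecord(s.id, s.sequence) for s in targets], params.k
    )
    shared = 0
    for seg in source:
        if align_pairwise(SequenceRecord(seg.id, seg.sequence), index, params):
            shared += seg.length
    return shared


def shared_novel(
    set_a: list[NovelSegment],
    set_b: list[NovelSegment],
    min_identity: float = 0.90,
    params: AlignerParams | None = None,
) -> SharedNovelSummary:
    """Bases of each novel set with an alignment to the other set, reported in
    both directions (the two directional totals generally differ)."""
    params = params or AlignerParams(min_chain_seeds=1, min_align_length=50)
    params = replace(params, min_identity=min_identity)
    a = [s for s in set_a if s.status == "putative_novel"]
    b = [s for s in set_b if s.status == "putative_novel"]
    return SharedNovelSummary(
        a_total=sum(s.length for s in a),
        b_total=sum(s.length for s in b),
        a_shared=_directional_shared(a, b, min_identity, params),
        b_shared=_directional_shared(b, a, min_identity, params),
    )


def _gc_or_nan(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def gc_content(sequences: str | Iterable[str]) -> float:
    """Percent G+C over A+C+G+T, pooled across sequences; N is excluded from
    the denominator. All-N input is an error."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = acgt = 0
    for seq in sequences:
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("gc_content of sequence(s) with no A/C/G/T bases")
    return 100.0 * gc / acgt
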