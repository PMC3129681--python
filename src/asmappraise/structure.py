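"""Structural appraisal: split-contig mis-assemblies, length normalisation,
and paired-end concordance classification.

A split-contig mis-assembly is a single contig whose *uniquely aligned*
segments place its parts on two different reference chromosomes, each segment
at least a size cutoff long — evidence of an incorrect join. Uniqueness is
operationalised as the best alignment scoring at least ``uniqueness_ratio``
times any other alignment that substantially overlaps the same contig
segment. Event counts are normalised across assemblies of different
contiguity as N * C / L, with L the assembly's mean scaffold length and C a
shared scale constant (by convention the smallest mean scaffold length among
the assemblies compared, so that assembly keeps its raw count).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .alignment import PairwiseAlignment


class PairClass(str, Enum):
    PROPER = "proper"
    DISCORDANT_ORIENTATION = "discordant_orientation"
    DISCORDANT_DISTANCE = "discordant_distance"
    ONE_END_UNMAPPED = "one_end_unmapped"
    BOTH_UNMAPPED = "both_unmapped"
    CROSS_SCAFFOLD = "cross_scaffold"


@dataclass
class Placement:
    chromosome: str
    target_interval: tuple[int, int]
    query_interval: tuple[int, int]
    identity: float
    aligned_length: int


@dataclass
class MisassemblyEvent:
    contig_id: str
    placements: list[Placement]
    intrachromosomal: bool = False

    @property
    def min_segment_length(self) -> int:
        return min(p.aligned_length for p in self.placements)

    @property
    def chromosomes(self) -> set[str]:
        return {p.chromosome for p in self.placements}


@dataclass
class NormalizationParams:
    N: int
    mean_scaffold_length: float
    scale_constant: float

    def __post_init__(self) -> None:
        if self.mean_scaffold_length <= 0 or self.scale_constant <= 0:
            raise ValueError("lengths for normalization must be positive")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def unique_alignments(
    alignments: list[PairwiseAlignment],
    uniqueness_ratio: float = 1.1,
    overlap_fraction: float = 0.5,
) -> list[PairwiseAlignment]:
    """Alignments of one contig whose score beats every competing alignment
    overlapping >= overlap_fraction of their query span by uniqueness_ratio."""
    out = []
    for a in alignments:
        span = (a.query_start, a.query_end)
        width = span[1] - span[0]
        unique = True
        for b in alignments:
            if b is a:
                continue
            if _overlap(span, (b.query_start, b.query_end)) >= overlap_fraction * width:
                if a.score < uniqueness_ratio * b.score:
                    unique = False
                    break
        if unique:
            out.append(a)
    return out


def detect_split_contigs(
    alignments: list[PairwiseAlignment],
    size_cutoff: int,
    uniqueness_ratio: float = 1.1,
    overlap_fraction: float = 0.5,
    include_intra: bool = False,
    intra_distance: int = 1_000_000,
) -> list[MisassemblyEvent]:
    """One event per contig with unique aligned segments of >= size_cutoff
    bases on two or more chromosomes.

    Same-chromosome segments more than ``intra_distance`` apart, or aligned in
    inconsistent order, are reported as intrachromosomal events only when
    ``include_intra`` is set (they are excluded from cross-chromosome counts).
    """
    by_contig: dict[str, list[PairwiseAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.query_id, []).append(a)

    events: list[MisassemblyEvent] = []
    for contig_id in sorted(by_contig):
        unique = unique_alignments(by_contig[contig_id], uniqueness_ratio, overlap_fraction)
        segments = [a for a in unique if a.aligned_columns >= size_cutoff]
        if len(segments) < 2:
            continue
        placements = [
            Placement(
                a.target_id,
                a.target_span,
                (a.query_start, a.query_end),
                a.identity,
                a.aligned_columns,
            )
            for a in sorted(segments, key=lambda a: a.query_start)
        ]
        chroms = {p.chromosome for p in placements}
        if len(chroms) >= 2:
            events.append(MisassemblyEvent(contig_id, placements))
        elif include_intra:
            # single chromosome: flag distant or out-of-order placements
            tpos = [p.target_interval for p in placements]
            distant = any(
                abs(b[0] - a[1]) > intra_distance for a, b in zip(tpos, tpos[1:])
            )
            strands = {
                a.strand for a in segments
            }
            increasing = all(b[0] >= a[0] for a, b in zip(tpos, tpos[1:]))
            decreasing = all(b[0] <= a[0] for a, b in zip(tpos, tpos[1:]))
            disordered = not (increasing or decreasing) or len(strands) > 1
            if distant or disordered:
                events.append(MisassemblyEvent(contig_id, placements, intrachromosomal=True))
    return events


def normalize_event_count(params: NormalizationParams) -> float:
    """N * (C / L): raw event count rescaled by mean scaffold length."""
    return params.N * params.scale_constant / params.mean_scaffold_length


def classify_pair(
    end1: PairwiseAlignment | None,
    end2: PairwiseAlignment | None,
    insert_mean: int,
    insert_tolerance: float = 0.3,
) -> PairClass:
    """Classify a read pair from the best alignments of its two ends.

    Proper means: both ends on one scaffold, opposite strands with the
    leftmost end on plus, and outer distance within
    insert_mean * (1 +/- insert_tolerance). Failures are reported in the
    fixed precedence order both_unmapped, one_end_unmapped, cross_scaffold,
    discordant_orientation, discordant_distance.
    """
    if insert_mean <= 0:
        raise ValueError("insert_mean must be positive")
    if not 0.0 < insert_tolerance < 1.0:
        raise ValueError("insert_tolerance must be in (0, 1)")
    if end1 is None and end2 is None:
        return PairClass.BOTH_UNMAPPED
    if end1 is None or end2 is None:
        return PairClass.ONE_END_UNMAPPED
    if end1.target_id != end2.target_id:
        return PairClass.CROSS_SCAFFOLD
    left, right = sorted((end1, end2), key=lambda a: a.target_start)
    if {end1.strand, end2.strand} != {"+", "-"} or left.strand != "+":
        return PairClass.DISCORDANT_ORIENTATION
    outer = right.target_end - left.target_start
    lo = insert_mean * (1 - insert_tolerance)
    hi = insert_mean * (1 + insert_tolerance)
    if not lo <= outer <= hi:
        return PairClass.DISCORDANT_DISTANCE
    return PairClass.PROPER


@dataclass
class ConcordanceSummary:
    counts: dict[PairClass, int]
    total: int

    @property
    def proper_fraction(self) -> float:
        return self.counts.get(PairClass.PROPER, 0) / self.total


def concordance_summary(pairs: list[PairClass]) -> ConcordanceSummary:
    if not pairs:
        raise ValueError("no pairs to summarise")
    counts = Counter(pairs)
    return ConcordanceSummary({c: counts.get(c, 0) for c in PairClass}, len(pairs))
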