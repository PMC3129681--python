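"""Contiguity statistics: N50 and friends for contigs and scaffolds.

The N50 of a length set is the largest length L such that sequences of length
>= L together contain at least 50% of the total bases; ``n_statistic``
generalises the fraction. Contig statistics exclude contigs at or below a
minimum length (default 100 bp, strictly greater-than retained); scaffold
statistics are unfiltered and scaffold lengths include internal N gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import ScaffoldedAssembly


def n_statistic(lengths: Iterable[int], fraction: float = 0.5) -> int:
    """Largest L such that lengths >= L hold at least ``fraction`` of all bases."""
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("n_statistic of an empty length collection")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if any(l < 1 for l in lens):
        raise ValueError("lengths must be >= 1")
    threshold = fraction * sum(lens)
    running = 0
    for l in lens:
        running += l
        if running >= threshold:
            return l
    return lens[-1]  # unreachable; fraction < 1 guarantees a crossing


@dataclass
class AssemblyStats:
    total_contig_bases: int
    total_scaffold_bases: int
    contig_count: int
    scaffold_count: int
    n50_contig: int
    n50_scaffold: int
    mean_scaffold_length: float
    min_length: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def assembly_stats(assembly: ScaffoldedAssembly, min_length: int = 100) -> AssemblyStats:
    """Table-style contiguity summary of a decomposed assembly.

    Contigs of length <= min_length are excluded from every contig statistic
    ("greater than 100 bp" read strictly); scaffolds are never filtered.
    """
    contig_lens = [l for l in assembly.contig_lengths() if l > min_length]
    if not contig_lens:
        raise ValueError(f"no contigs longer than {min_length} bp")
    scaffold_lens = assembly.scaffold_lengths()
    return AssemblyStats(
        total_contig_bases=sum(contig_lens),
        total_scaffold_bases=sum(scaffold_lens),
        contig_count=len(contig_lens),
        scaffold_count=len(scaffold_lens),
        n50_contig=n_statistic(contig_lens, 0.5),
        n50_scaffold=n_statistic(scaffold_lens, 0.5),
        mean_scaffold_length=sum(scaffold_lens) / len(scaffold_lens),
        min_length=min_length,
    )
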