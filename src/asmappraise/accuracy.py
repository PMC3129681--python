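"""Base-level accuracy versus trusted reference sequences.

Assembly contigs are aligned to a trusted set (finished-clone analogues) and
per-base discrepancies are tallied: substitution events, deletion bases
(present in the trusted sequence, absent from the assembly) and insertion
bases (present in the assembly, absent from the trusted sequence). Rates are
reported per aligned trusted base, which keeps the three rates commensurable.

Where alignments overlap on the trusted sequence (repeat-induced
multi-alignments), each trusted base is attributed to its best-scoring
covering alignment so no discrepancy is counted twice. This per-base
attribution requires the column-level events our aligner records; alignments
imported from PSL (which carry only aggregate counts) are tallied whole, so
overlapping PSL input can double-count and is warned about.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

from .alignment import (
    PairwiseAlignment,
    interval_total,
    merge_intervals,
    subtract_intervals,
)
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class DiscrepancyTally:
    substitutions: int = 0
    deletion_bases: int = 0
    insertion_bases: int = 0
    aligned_reference_bases: int = 0
    covered_reference_bases: int = 0
    total_reference_bases: int = 0

    def __add__(self, other: "DiscrepancyTally") -> "DiscrepancyTally":
        return DiscrepancyTally(
            *(getattr(self, f) + getattr(other, f) for f in self.__dataclass_fields__)
        )


def _point_in(intervals: list[tuple[int, int]], pos: int) -> bool:
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def _clip_total(intervals: list[tuple[int, int]], s: int, e: int) -> int:
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def tally_discrepancies(
    alignments: list[PairwiseAlignment],
    trusted: list[SequenceRecord],
    indel_unit: str = "bases",
) -> DiscrepancyTally:
    """Tally discrepancies of assembly-vs-trusted alignments.

    Alignments must have trusted sequences as targets. Overlapping alignments
    to the same trusted region are resolved per base in favour of the
    higher-scoring alignment. Indels are counted in bases (a 2-bp gap
    contributes 2) by default; ``indel_unit="events"`` counts gap openings
    instead (requires column events).
    """
    if indel_unit not in ("bases", "events"):
        raise ValueError("indel_unit must be 'bases' or 'events'")
    trusted_lengths = {t.id: len(t.sequence) for t in trusted}
    for a in alignments:
        if a.target_id not in trusted_lengths:
            raise ValueError(f"alignment targets unknown trusted sequence {a.target_id!r}")

    tally = DiscrepancyTally(total_reference_bases=sum(trusted_lengths.values()))
    by_target: dict[str, list[PairwiseAlignment]] = {}
    for a in alignments:
        by_target.setdefault(a.target_id, []).append(a)

    for target_id, alns in by_target.items():
        alns.sort(key=lambda a: (-a.score, -a.matches, a.target_start))
        covered: list[tuple[int, int]] = []
        for a in alns:
            owned = subtract_intervals(a.target_span, covered)
            if a.events is None:
                if owned != [a.target_span]:
                    logger.warning(
                        "alignment %s->%s lacks column events; overlapping "
                        "regions may be double-counted", a.query_id, target_id,
                    )
                tally.substitutions += a.mismatches
                tally.deletion_bases += a.query_gap_bases
                tally.insertion_bases += a.target_gap_bases
                tally.aligned_reference_bases += _clip_total(
                    [(ts, ts + ln) for _qs, ts, ln in a.blocks], *a.target_span
                )
            else:
                for ev in a.events:
                    if ev.kind == "sub" and _point_in(owned, ev.tpos):
                        tally.substitutions += 1
                    elif ev.kind == "del":
                        clipped = _clip_total(owned, ev.tpos, ev.tpos + ev.length)
                        if clipped:
                            tally.deletion_bases += 1 if indel_unit == "events" else clipped
                    elif ev.kind == "ins" and _point_in(owned, ev.tpos):
                        tally.insertion_bases += 1 if indel_unit == "events" else ev.length
                for _qs, ts, ln in a.blocks:
                    tally.aligned_reference_bases += _clip_total(owned, ts, ts + ln)
            covered = merge_intervals(covered + [a.target_span])
        tally.covered_reference_bases += interval_total(covered)
    return tally


def discrepancy_rates(tally: DiscrepancyTally) -> tuple[float, float, float]:
    """(substitution, deletion, insertion) rates as percentages of aligned
    trusted-reference bases."""
    if tally.aligned_reference_bases <= 0:
        raise ValueError("no aligned reference bases; rates undefined")
    denom = tally.aligned_reference_bases
    return (
        100.0 * tally.substitutions / denom,
        100.0 * tally.deletion_bases / denom,
        100.0 * tally.insertion_bases / denom,
    )


def reference_coverage(tally: DiscrepancyTally) -> float:
    """Percent of trusted-reference bases covered by at least one alignment."""
    if tally.total_reference_bases <= 0:
        raise ValueError("no trusted reference bases")
    return 100.0 * tally.covered_reference_bases / tally.total_reference_bases
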