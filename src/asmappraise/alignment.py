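"""Block-structured pairwise alignments, the currency of every downstream metric.

An alignment pairs a *query* (usually an assembly contig, scaffold, or 1-kbp
chunk) with a *target* (a trusted clone, reference chromosome, or transcript).
Blocks are ungapped segments; gap bases between blocks are classified from the
point of view of the query-as-assembly convention:

* ``target_gap_bases`` -- bases present in the query but absent from the
  target (*insertions* when the query is the assembly);
* ``query_gap_bases`` -- bases present in the target but absent from the
  query (*deletions* when the query is the assembly).

For minus-strand alignments, block query coordinates are expressed in the
reverse-complemented query (the PSL convention), while ``query_start`` /
``query_end`` always refer to the plus strand of the query sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AlignmentEvent:
    """A single discrepancy column group within an alignment.

    kind is ``"sub"`` (one mismatched column), ``"ins"`` (query bases absent
    from the target, anchored at target position ``tpos``), or ``"del"``
    (target bases absent from the query, spanning ``[tpos, tpos + length)``).
    ``qpos`` is in oriented (strand-adjusted) query coordinates.
    """

    kind: str
    tpos: int
    qpos: int
    length: int = 1


@dataclass
class PairwiseAlignment:
    query_id: str
    target_id: str
    strand: str
    query_size: int
    target_size: int
    query_start: int  # plus-strand query coords, 0-based half-open
    query_end: int
    target_start: int
    target_end: int
    blocks: list[tuple[int, int, int]]  # (q_start oriented, t_start, length)
    matches: int
    mismatches: int
    query_gap_bases: int  # target bases absent from query (deletions)
    target_gap_bases: int  # query bases absent from target (insertions)
    score: float
    events: list[AlignmentEvent] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def aligned_columns(self) -> int:
        """Ungapped alignment columns (matches + mismatches)."""
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        denom = (
            self.matches
            + self.mismatches
            + self.query_gap_bases
            + self.target_gap_bases
        )
        return self.matches / denom if denom else 0.0

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)

    def query_block_intervals_plus(self) -> list[tuple[int, int]]:
        """Aligned query intervals on the plus strand of the query."""
        out = []
        for qs, _ts, ln in self.blocks:
            if self.strand == "+":
                out.append((qs, qs + ln))
            else:
                out.append((self.query_size - qs - ln, self.query_size - qs))
        out.sort()
        return out

    def target_block_intervals(self) -> list[tuple[int, int]]:
        return [(ts, ts + ln) for _qs, ts, ln in self.blocks]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_total(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def subtract_intervals(
    span: tuple[int, int], covered: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sub-intervals of ``span`` not covered by the (arbitrary) interval list."""
    s0, e0 = span
    out = []
    cursor = s0
    for s, e in merge_intervals(covered):
        if e <= cursor:
            continue
        if s >= e0:
            break
        if s > cursor:
            out.append((cursor, min(s, e0)))
        cursor = max(cursor, e)
        if cursor >= e0:
            break
    if cursor < e0:
        out.append((cursor, e0))
    return out
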