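"""Readers and writers for FASTA / PSL / BED / GFF3, plus scaffold decomposition.

All coordinates in memory are 0-based half-open. PSL and BED already use that
convention; GFF3 (1-based closed) is converted on read. Sequences are
normalised to uppercase over the alphabet {A, C, G, T, N}; IUPAC ambiguity
codes are mapped to N (with a logged count) so real assemblies parse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alignment import PairwiseAlignment

logger = logging.getLogger(__name__)

_AMBIGUITY = "RYSWKMBDHVU"
_NORMALISE = str.maketrans(_AMBIGUITY + _AMBIGUITY.lower() + "acgtn", "N" * 22 + "ACGTN")
_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One FASTA record, normalised to the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase and map ambiguity codes to N; returns (sequence, n_converted)."""
    seq = raw.upper()
    converted = sum(1 for c in seq if c not in _VALID)
    seq = seq.translate(_NORMALISE)
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq, converted


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Duplicate ids are a hard error; an empty file yields an empty list with a
    warning; ambiguity-code conversions are counted and logged.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_converted = 0
    with open(path) as fh:
        for header, raw in SimpleFastaParser(fh):
            parts = header.split(maxsplit=1)
            rid = parts[0] if parts else ""
            if not rid:
                raise ValueError(f"{path}: record with empty id")
            if rid in seen:
                raise ValueError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            seq, conv = normalize_sequence(raw.replace(" ", ""))
            if not seq:
                raise ValueError(f"{path}: empty sequence for id {rid!r}")
            n_converted += conv
            records.append(
                SequenceRecord(rid, seq, parts[1] if len(parts) > 1 else "")
            )
    if n_converted:
        logger.info("%s: converted %d ambiguity bases to N", path, n_converted)
    if not records:
        logger.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass
class Contig:
    """A gap-free stretch of a scaffold, in scaffold coordinates."""

    scaffold_id: str
    start: int
    end: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}"

    @property
    def record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.sequence)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldedAssembly:
    """Scaffolds decomposable into contigs at N-runs of >= gap_threshold bases."""

    scaffolds: list[SequenceRecord]
    gap_threshold: int
    contigs: list[Contig] = field(default_factory=list)

    def scaffold_lengths(self) -> list[int]:
        return [len(s) for s in self.scaffolds]

    def contig_lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    def contigs_of(self, scaffold_id: str) -> list[Contig]:
        return [c for c in self.contigs if c.scaffold_id == scaffold_id]

    def reconstruct(self, scaffold_id: str) -> str:
        """Rebuild a scaffold exactly from its contigs and the gaps between them."""
        scaffold = next(s for s in self.scaffolds if s.id == scaffold_id)
        parts = []
        cursor = 0
        for c in self.contigs_of(scaffold_id):
            parts.append("N" * (c.start - cursor))
            parts.append(c.sequence)
            cursor = c.end
        parts.append("N" * (len(scaffold) - cursor))
        return "".join(parts)


def decompose_scaffolds(
    records: list[SequenceRecord], gap_threshold: int = 10
) -> ScaffoldedAssembly:
    """Split each scaffold into contigs at N-runs of length >= gap_threshold.

    N-runs shorter than the threshold stay inside contigs; contigs are maximal
    and tile each scaffold together with the qualifying gaps.
    """
    if gap_threshold < 1:
        raise ValueError("gap_threshold must be >= 1")
    gap_re = re.compile("N{%d,}" % gap_threshold)
    contigs: list[Contig] = []
    for rec in records:
        cursor = 0
        for m in gap_re.finditer(rec.sequence):
            if m.start() > cursor:
                contigs.append(
                    Contig(rec.id, cursor, m.start(), rec.sequence[cursor : m.start()])
                )
            cursor = m.end()
        if cursor < len(rec.sequence):
            contigs.append(Contig(rec.id, cursor, len(rec.sequence), rec.sequence[cursor:]))
    return ScaffoldedAssembly(records, gap_threshold, contigs)


# ---------------------------------------------------------------------------
# PSL (BLAT 21-column)

_PSL_HEADER_PREFIXES = ("psLayout", "match", "-----", "\t")


def _psl_int_list(tok: str) -> list[int]:
    return [int(x) for x in tok.rstrip(",").split(",")] if tok.rstrip(",") else []


def read_psl(path: str | Path) -> list[PairwiseAlignment]:
    """Read BLAT 21-column PSL, with or without the psLayout header."""
    out: list[PairwiseAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _PSL_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) != 21:
                raise ValueError(f"{path}:{lineno}: expected 21 PSL columns, got {len(fields)}")
            try:
                out.append(_parse_psl_fields(fields))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PSL line: {exc}") from exc
    return out


def _parse_psl_fields(f: list[str]) -> PairwiseAlignment:
    matches, mismatches = int(f[0]), int(f[1])
    q_gap_bases = int(f[7])  # tBaseInsert: target bases absent from the query
    t_gap_bases = int(f[5])  # qBaseInsert: query bases absent from the target
    strand = f[8]
    q_name, q_size, q_start, q_end = f[9], int(f[10]), int(f[11]), int(f[12])
    t_name, t_size, t_start, t_end = f[13], int(f[14]), int(f[15]), int(f[16])
    block_count = int(f[17])
    sizes = _psl_int_list(f[18])
    q_starts = _psl_int_list(f[19])
    t_starts = _psl_int_list(f[20])
    if not (len(sizes) == len(q_starts) == len(t_starts) == block_count):
        raise ValueError("block list lengths disagree with blockCount")
    blocks = list(zip(q_starts, t_starts, sizes))
    return PairwiseAlignment(
        query_id=q_name,
        target_id=t_name,
        strand=strand,
        query_size=q_size,
        target_size=t_size,
        query_start=q_start,
        query_end=q_end,
        target_start=t_start,
        target_end=t_end,
        blocks=blocks,
        matches=matches,
        mismatches=mismatches,
        query_gap_bases=q_gap_bases,
        target_gap_bases=t_gap_bases,
        score=_psl_score(matches, mismatches, blocks),
    )


def _psl_score(matches: int, mismatches: int, blocks: list[tuple[int, int, int]]) -> float:
    # Recompute the internal affine score from the block structure.
    from .aligner import AlignerParams

    p = AlignerParams()
    score = matches * p.match + mismatches * p.mismatch
    for (q0, t0, l0), (q1, t1, _l1) in zip(blocks, blocks[1:]):
        qgap = q1 - (q0 + l0)
        tgap = t1 - (t0 + l0)
        for g in (qgap, tgap):
            if g > 0:
                score += p.gap_open + g * p.gap_extend
    return float(score)


def write_psl(alignments: list[PairwiseAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            q_num = t_num = 0
            for (q0, t0, l0), (q1, t1, _l1) in zip(a.blocks, a.blocks[1:]):
                if q1 > q0 + l0:
                    q_num += 1
                if t1 > t0 + l0:
                    t_num += 1
            fields = [
                a.matches, a.mismatches, 0, 0,
                q_num, a.target_gap_bases, t_num, a.query_gap_bases,
                a.strand, a.query_id, a.query_size, a.query_start, a.query_end,
                a.target_id, a.target_size, a.target_start, a.target_end,
                len(a.blocks),
                ",".join(str(l) for _q, _t, l in a.blocks) + ",",
                ",".join(str(q) for q, _t, _l in a.blocks) + ",",
                ",".join(str(t) for _q, t, _l in a.blocks) + ",",
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3 interval input (gene loci)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """3- or 6-column BED (0-based half-open, as stored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand))
    return out


def read_gff3(path: str | Path, feature_types: set[str] | None = None) -> list[GenomicInterval]:
    """Extract intervals from GFF3, converting 1-based closed to 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            if feature_types and f[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID", attrs.get("Name", ""))
            out.append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), name, f[6]))
    return out


def write_gff3(intervals: list[GenomicInterval], path: str | Path, source: str = "asmappraise",
               feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attrs = f"ID={iv.name}" if iv.name else "."
            fh.write(
                "\t".join(
                    [iv.chrom, source, feature_type, str(iv.start + 1), str(iv.end),
                     ".", iv.strand, ".", attrs]
                )
                + "\n"
            )


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")
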