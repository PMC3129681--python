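"""Synthetic truth genomes and corrupted assemblies with a machine-readable
ledger of every planted defect.

The generator emulates the statistical structure of real draft assemblies
evaluated against a finished reference: per-base substitution and indel
errors at rates of ~1e-4 to 1e-3 (with a deletion bias inside homopolymer
runs, the signature error mode of flowgram sequencing), fragmentation to
target contig/scaffold N50s with inter-contig gaps of missing sequence,
interchromosomal misjoined contigs flanked by long unique arms, contaminant
contigs drawn from a bundled synthetic foreign genome (the E. coli
stand-in), and GC-shifted novel sequence present in the assembly but absent
from the emitted reference. The :class:`TruthLedger` records every planted
event, and is the ground truth that parameter-recovery tests close the loop
against.

All randomness derives from one seeded NumPy generator per operation, so
identical spec + seed reproduce byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    GenomicInterval,
    ScaffoldedAssembly,
    SequenceRecord,
)
from .alignment import merge_intervals, subtract_intervals
from .structure import PairClass

_BASES = np.frombuffer(b"ACGT", np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(enc: np.ndarray) -> str:
    return _BASES[enc].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Truth genome


@dataclass
class GenomeSpec:
    n_chromosomes: int = 4
    lengths: list[int] | None = None  # explicit; else total_length split evenly
    total_length: int = 5_000_000
    gc: float = 0.416
    repeat_fraction: float = 0.10
    repeat_unit_length: int = 500
    gene_spacing: int = 50_000
    gene_length: tuple[int, int] = (1_000, 2_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if not 0.0 <= self.repeat_fraction <= 0.5:
            raise ValueError("repeat_fraction must be in [0, 0.5]")

    def chromosome_lengths(self) -> list[int]:
        if self.lengths is not None:
            return list(self.lengths)
        base = self.total_length // self.n_chromosomes
        return [base] * self.n_chromosomes


@dataclass
class Genome:
    spec: GenomeSpec
    chromosomes: list[SequenceRecord]
    genes: list[GenomicInterval]
    transcripts: list[SequenceRecord]
    repeats: list[GenomicInterval]

    @property
    def total_length(self) -> int:
        return sum(len(c.sequence) for c in self.chromosomes)

    def chromosome(self, chrom: str) -> SequenceRecord:
        return next(c for c in self.chromosomes if c.id == chrom)


def generate_genome(spec: GenomeSpec) -> Genome:
    """Random truth genome with one planted repeat family and regularly
    spaced gene loci whose transcripts are genomic substrings."""
    rng = np.random.default_rng(spec.seed)
    lengths = spec.chromosome_lengths()
    encoded = [_random_bases(rng, L, spec.gc) for L in lengths]
    names = [f"chr{i + 1}" for i in range(len(lengths))]

    repeats: list[GenomicInterval] = []
    total = sum(lengths)
    if spec.repeat_fraction > 0:
        unit = _random_bases(rng, spec.repeat_unit_length, spec.gc)
        n_copies = int(round(spec.repeat_fraction * total / spec.repeat_unit_length))
        weights = np.array(lengths) / total
        for _ in range(n_copies):
            ci = int(rng.choice(len(lengths), p=weights))
            pos = int(rng.integers(0, lengths[ci] - spec.repeat_unit_length))
            encoded[ci][pos : pos + spec.repeat_unit_length] = unit
            repeats.append(
                GenomicInterval(names[ci], pos, pos + spec.repeat_unit_length, "repeat")
            )
    repeats.sort(key=lambda r: (r.chrom, r.start))

    repeat_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        repeat_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in repeat_by_chrom:
        repeat_by_chrom[chrom] = merge_intervals(repeat_by_chrom[chrom])

    genes: list[GenomicInterval] = []
    transcripts: list[SequenceRecord] = []
    gi = 0
    for ci, (name, L) in enumerate(zip(names, lengths)):
        pos = int(rng.integers(0, spec.gene_spacing // 2))
        while pos + spec.gene_length[1] < L:
            glen = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            interval = (pos, pos + glen)
            overlap = any(
                s < interval[1] and e > interval[0]
                for s, e in repeat_by_chrom.get(name, [])
            )
            if not overlap:
                gi += 1
                gid = f"gene_{gi}"
                genes.append(GenomicInterval(name, interval[0], interval[1], gid, "+"))
                transcripts.append(
                    SequenceRecord(
                        f"transcript_{gi}",
                        _to_str(encoded[ci][interval[0] : interval[1]]),
                        f"unspliced transcript of {gid}",
                    )
                )
            pos += spec.gene_spacing
    chromosomes = [SequenceRecord(n, _to_str(e)) for n, e in zip(names, encoded)]
    return Genome(spec, chromosomes, genes, transcripts, repeats)


# ---------------------------------------------------------------------------
# Corruption


@dataclass
class CorruptionSpec:
    sub_rate: float = 2e-4
    ins_rate: float = 5e-5
    del_rate: float = 1e-4
    homopolymer_del_bias: float = 3.0  # multiplier inside homopolymers >= 4 bp
    target_contig_n50: int | None = 20_000
    target_scaffold_n50: int | None = 100_000
    n_misjoins: int = 5
    misjoin_arm_range: tuple[int, int] = (25_000, 40_000)
    contaminant_fraction: float = 0.02  # of genome-derived contigs
    contaminant_length_range: tuple[int, int] = (1_000, 5_000)
    n_novel_inserts: int = 50
    novel_insert_length: int = 1_000
    novel_gc: float = 0.542
    gap_length_range: tuple[int, int] = (200, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.01:
                raise ValueError("error rates must be in [0, 0.01]")
        if self.n_misjoins < 0:
            raise ValueError("n_misjoins must be >= 0")


@dataclass
class PlantedEvent:
    kind: str  # sub | ins | del
    chrom: str
    truth_pos: int
    contig_index: int
    contig_id: str = ""


@dataclass
class Part:
    """One truth-genome (or contaminant) interval realised inside a contig."""

    chrom: str
    truth_start: int
    truth_end: int
    contig_offset: int  # offset of this part's first base within the contig
    assembly_length: int  # part length after corruption


@dataclass
class ContigRecord:
    index: int
    kind: str  # normal | misjoin | contaminant
    parts: list[Part]
    contig_id: str = ""
    scaffold_id: str = ""
    scaffold_start: int = 0
    scaffold_end: int = 0


@dataclass
class NovelInsertRecord:
    insert_id: str
    contig_index: int
    offset: int  # position within the corrupted contig sequence
    length: int
    sequence: str
    contig_id: str = ""


@dataclass
class MisjoinRecord:
    contig_index: int
    parts: list[Part]
    contig_id: str = ""


@dataclass
class TruthLedger:
    genome_spec: GenomeSpec
    corruption_spec: CorruptionSpec
    contigs: list[ContigRecord] = field(default_factory=list)
    events: list[PlantedEvent] = field(default_factory=list)
    misjoins: list[MisjoinRecord] = field(default_factory=list)
    novel_inserts: list[NovelInsertRecord] = field(default_factory=list)
    contaminant_scaffolds: list[str] = field(default_factory=list)
    contaminant_source: SequenceRecord | None = None
    genome_derived_bases: int = 0

    def event_counts(self) -> dict[str, int]:
        out = {"sub": 0, "ins": 0, "del": 0}
        for e in self.events:
            out[e.kind] += 1
        return out

    def realized_rates(self) -> dict[str, float]:
        n = self.genome_derived_bases
        return {k: v / n for k, v in self.event_counts().items()} if n else {}

    def covered_truth_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Truth intervals represented by at least one assembly contig."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in self.contigs:
            if c.kind == "contaminant":
                continue
            for p in c.parts:
                by_chrom.setdefault(p.chrom, []).append((p.truth_start, p.truth_end))
        return {k: merge_intervals(v) for k, v in by_chrom.items()}

    def planted_counts_in(
        self, regions: dict[str, list[tuple[int, int]]]
    ) -> dict[str, int]:
        """Planted event counts whose truth position falls in the regions."""
        merged = {k: merge_intervals(v) for k, v in regions.items()}
        out = {"sub": 0, "ins": 0, "del": 0}
        for e in self.events:
            for s, t in merged.get(e.chrom, []):
                if s <= e.truth_pos < t:
                    out[e.kind] += 1
                    break
        return out

    def planted_novel_bases(self) -> int:
        return sum(n.length for n in self.novel_inserts)

    def to_json(self, path) -> None:
        import dataclasses as _dc
        import json as _json

        doc = {
            "genome_spec": _dc.asdict(self.genome_spec),
            "corruption_spec": _dc.asdict(self.corruption_spec),
            "genome_derived_bases": self.genome_derived_bases,
            "event_counts": self.event_counts(),
            "realized_rates": self.realized_rates(),
            "contigs": [_dc.asdict(c) for c in self.contigs],
            "events": [_dc.asdict(e) for e in self.events],
            "misjoins": [_dc.asdict(m) for m in self.misjoins],
            "novel_inserts": [_dc.asdict(n) for n in self.novel_inserts],
            "contaminant_scaffolds": self.contaminant_scaffolds,
        }
        with open(path, "w") as fh:
            _json.dump(doc, fh, indent=1)
            fh.write("\n")


def _homopolymer_mask(enc: np.ndarray, min_run: int = 4) -> np.ndarray:
    n = enc.shape[0]
    if n == 0:
        return np.zeros(0, bool)
    change = np.nonzero(enc[1:] != enc[:-1])[0] + 1
    bounds = np.concatenate([[0], change, [n]])
    lens = np.diff(bounds)
    return np.repeat(lens >= min_run, lens)


def _corrupt_segment(
    enc: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply per-base errors; returns (new_enc, sub_pos, ins_pos, del_pos)
    with positions in the input's coordinates (insertions anchored at the
    base they precede)."""
    n = enc.shape[0]
    p_del = np.full(n, spec.del_rate)
    if spec.homopolymer_del_bias != 1.0 and spec.del_rate > 0:
        p_del[_homopolymer_mask(enc)] *= spec.homopolymer_del_bias
    del_mask = rng.random(n) < p_del
    sub_mask = (rng.random(n) < spec.sub_rate) & ~del_mask
    ins_mask = rng.random(n) < spec.ins_rate

    mutated = enc.copy()
    sub_pos = np.nonzero(sub_mask)[0]
    mutated[sub_pos] = (mutated[sub_pos] + rng.integers(1, 4, sub_pos.size)) % 4
    counts = (~del_mask).astype(np.int64) + ins_mask.astype(np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    out = np.empty(int(ends[-1]) if n else 0, np.uint8)
    keep = ~del_mask
    out[starts[keep]] = mutated[keep]
    ins_pos = np.nonzero(ins_mask)[0]
    out[ends[ins_pos] - 1] = rng.integers(0, 4, ins_pos.size).astype(np.uint8)
    return out, sub_pos, ins_pos, np.nonzero(del_mask)[0]


def _reserve_windows(
    rng: np.random.Generator,
    genome: Genome,
    spec: CorruptionSpec,
) -> list[list[tuple[str, int, int]]]:
    """Non-overlapping truth windows for misjoin arms: one
    [(chromA, s, e), (chromB, s, e)] pair per misjoin. Short repeat copies
    inside an arm are allowed: they cannot defeat the uniqueness of a
    multi-kbp segment."""
    if spec.n_misjoins == 0:
        return []
    if len(genome.chromosomes) < 2:
        raise ValueError("misjoins require at least two chromosomes")
    taken: dict[str, list[tuple[int, int]]] = {}

    def blocked(chrom: str, s: int, e: int) -> bool:
        for lo, hi in taken.get(chrom, []):
            if lo < e and hi > s:
                return True
        return False

    names = [c.id for c in genome.chromosomes]
    lengths = {c.id: len(c.sequence) for c in genome.chromosomes}
    pairs = []
    for _ in range(spec.n_misjoins):
        arms = []
        guard = 0
        while len(arms) < 2:
            guard += 1
            if guard > 1000:
                raise ValueError("could not place misjoin arms; genome too small")
            chrom = names[int(rng.integers(0, len(names)))]
            if arms and chrom == arms[0][0]:
                continue
            arm = int(rng.integers(*spec.misjoin_arm_range))
            L = lengths[chrom]
            if L < arm + 2000:
                continue
            s = int(rng.integers(1000, L - arm - 1000))
            if blocked(chrom, s, s + arm):
                continue
            taken.setdefault(chrom, []).append((s, s + arm))
            arms.append((chrom, s, s + arm))
        pairs.append(arms)
    return pairs


def corrupt_assembly(
    genome: Genome, spec: CorruptionSpec, gap_threshold: int = 10
) -> tuple[ScaffoldedAssembly, TruthLedger]:
    """Derive a defect-bearing assembly from a truth genome.

    Fragmentation removes the truth bases between consecutive contigs and
    represents them as N-runs of the true gap length inside scaffolds, so
    scaffold-relative distances are preserved. Errors, misjoins, contaminant
    contigs and novel inserts are recorded in the returned TruthLedger.
    """
    rng = np.random.default_rng(spec.seed)
    from .aligner import encode

    ledger = TruthLedger(genome.spec, spec)
    enc_by_chrom = {c.id: encode(c.sequence) for c in genome.chromosomes}

    contig_mean = (
        spec.target_contig_n50 / 1.118 if spec.target_contig_n50 else None
    )
    scaffold_mean = (
        spec.target_scaffold_n50 / 1.118 if spec.target_scaffold_n50 else None
    )
    if contig_mean is not None:
        shortest = min(len(c.sequence) for c in genome.chromosomes)
        if contig_mean > shortest / 2:
            raise ValueError("target_contig_n50 unreachable for this genome size")

    misjoin_pairs = _reserve_windows(rng, genome, spec)
    reserved: dict[str, list[tuple[int, int]]] = {}
    for pair in misjoin_pairs:
        for chrom, s, e in pair:
            reserved.setdefault(chrom, []).append((s, e))

    # --- plan normal contigs chromosome by chromosome ------------------
    # scaffolds accumulate (list of corrupted contig ContigRecord, gap bp)
    scaffolds: list[list[tuple[ContigRecord, np.ndarray, int]]] = []

    def corrupt_part(chrom: str, s: int, e: int, index: int) -> tuple[np.ndarray, Part, list[PlantedEvent]]:
        seg = enc_by_chrom[chrom][s:e]
        out, subs, ins, dels = _corrupt_segment(seg, spec, rng)
        events = (
            [PlantedEvent("sub", chrom, s + int(p), index) for p in subs]
            + [PlantedEvent("ins", chrom, s + int(p), index) for p in ins]
            + [PlantedEvent("del", chrom, s + int(p), index) for p in dels]
        )
        ledger.genome_derived_bases += e - s
        return out, Part(chrom, s, e, 0, len(out)), events

    contig_counter = 0
    for chrom_rec in genome.chromosomes:
        chrom = chrom_rec.id
        L = len(chrom_rec.sequence)
        free = subtract_intervals((0, L), reserved.get(chrom, []))
        for fs, fe in free:
            if fe - fs < 200:
                continue
            # tile the free interval into contigs and inter-contig gaps
            pieces: list[tuple[int, int, int]] = []  # (s, e, following-gap bp)
            cursor = fs
            while cursor < fe:
                if contig_mean is None:
                    ce = fe
                else:
                    clen = int(rng.uniform(0.5, 1.5) * contig_mean)
                    ce = min(cursor + clen, fe)
                    if fe - ce < 600:
                        ce = fe
                gap = 0
                if ce < fe:
                    gap = int(rng.integers(*spec.gap_length_range))
                    gap = min(gap, fe - ce)
                pieces.append((cursor, ce, gap))
                cursor = ce + gap
            # group pieces into scaffolds
            current: list[tuple[ContigRecord, np.ndarray, int]] = []
            target = (
                rng.uniform(0.5, 1.5) * scaffold_mean if scaffold_mean else None
            )
            span = 0
            for s, e, gap in pieces:
                out, part, events = corrupt_part(chrom, s, e, contig_counter)
                rec = ContigRecord(contig_counter, "normal", [part])
                ledger.contigs.append(rec)
                ledger.events.extend(events)
                contig_counter += 1
                current.append((rec, out, gap))
                span += (e - s) + gap
                if target is not None and span >= target:
                    scaffolds.append(current)
                    current = []
                    span = 0
                    target = rng.uniform(0.5, 1.5) * scaffold_mean
            if current:
                scaffolds.append(current)

    # --- misjoin contigs ------------------------------------------------
    for pair in misjoin_pairs:
        parts = []
        arrs = []
        offset = 0
        rec = ContigRecord(contig_counter, "misjoin", [])
        for chrom, s, e in pair:
            out, part, events = corrupt_part(chrom, s, e, contig_counter)
            part.contig_offset = offset
            offset += len(out)
            parts.append(part)
            arrs.append(out)
            ledger.events.extend(events)
        rec.parts = parts
        ledger.contigs.append(rec)
        ledger.misjoins.append(MisjoinRecord(contig_counter, parts))
        contig_counter += 1
        scaffolds.append([(rec, np.concatenate(arrs), 0)])

    # --- novel inserts ----------------------------------------------------
    flat: list[tuple[ContigRecord, np.ndarray]] = [
        (rec, arr) for scaf in scaffolds for rec, arr, _g in scaf
    ]
    eligible = [
        i
        for i, (rec, arr) in enumerate(flat)
        if rec.kind == "normal" and arr.size > spec.novel_insert_length + 400
    ]
    if spec.n_novel_inserts > 0 and not eligible:
        raise ValueError("no contigs large enough to host novel inserts")
    replacements: dict[int, np.ndarray] = {}
    for ni in range(spec.n_novel_inserts):
        i = eligible[int(rng.integers(0, len(eligible)))]
        rec, arr = flat[i]
        arr = replacements.get(i, arr)
        novel = _random_bases(rng, spec.novel_insert_length, spec.novel_gc)
        pos = int(rng.integers(200, arr.size - 200))
        replacements[i] = np.concatenate([arr[:pos], novel, arr[pos:]])
        ledger.novel_inserts.append(
            NovelInsertRecord(
                f"novel_{ni + 1}", rec.index, pos, spec.novel_insert_length,
                _to_str(novel),
            )
        )
    if replacements:
        flat_i = 0
        for scaf in scaffolds:
            for k, (rec, arr, gap) in enumerate(scaf):
                if flat_i in replacements:
                    scaf[k] = (rec, replacements[flat_i], gap)
                flat_i += 1

    # --- contaminant contigs ---------------------------------------------
    n_genome_contigs = sum(1 for c in ledger.contigs if c.kind != "contaminant")
    n_contam = int(round(spec.contaminant_fraction * n_genome_contigs))
    if n_contam > 0:
        source = foreign_genome(spec.seed)
        ledger.contaminant_source = source
        src_enc = encode(source.sequence)
        for _ in range(n_contam):
            clen = int(rng.integers(*spec.contaminant_length_range))
            s = int(rng.integers(0, len(source.sequence) - clen))
            rec = ContigRecord(contig_counter, "contaminant",
                               [Part("contaminant", s, s + clen, 0, clen)])
            ledger.contigs.append(rec)
            contig_counter += 1
            scaffolds.append([(rec, src_enc[s : s + clen].copy(), 0)])

    # --- assemble scaffold records and final ids ---------------------------
    records: list[SequenceRecord] = []
    for si, scaf in enumerate(scaffolds):
        sid = f"scaffold_{si + 1:05d}"
        parts_str: list[str] = []
        pos = 0
        contaminant = all(rec.kind == "contaminant" for rec, _a, _g in scaf)
        for rec, arr, gap in scaf:
            rec.scaffold_id = sid
            rec.scaffold_start = pos
            rec.scaffold_end = pos + arr.size
            rec.contig_id = f"{sid}:{rec.scaffold_start}-{rec.scaffold_end}"
            parts_str.append(_to_str(arr))
            pos += arr.size
            if gap > 0:
                parts_str.append("N" * gap)
                pos += gap
        if contaminant:
            ledger.contaminant_scaffolds.append(sid)
        records.append(SequenceRecord(sid, "".join(parts_str)))

    for mj in ledger.misjoins:
        mj.contig_id = ledger.contigs[mj.contig_index].contig_id
    by_index = {c.index: c for c in ledger.contigs}
    for ev in ledger.events:
        ev.contig_id = by_index[ev.contig_index].contig_id
    for nv in ledger.novel_inserts:
        nv.contig_id = by_index[nv.contig_index].contig_id

    from .io_formats import decompose_scaffolds

    assembly = decompose_scaffolds(records, gap_threshold)
    return assembly, ledger


def foreign_genome(seed: int, length: int = 200_000, gc: float = 0.50) -> SequenceRecord:
    """Bundled synthetic foreign genome (contamination source stand-in)."""
    rng = np.random.default_rng((seed * 2_654_435_761 + 97) % 2**31)
    return SequenceRecord(
        "foreign_1", _to_str(_random_bases(rng, length, gc)),
        "synthetic contaminant source",
    )


# ---------------------------------------------------------------------------
# Read-pair simulation


@dataclass
class SimulatedPair:
    pair_id: str
    chrom: str
    start: int
    insert_size: int
    read1: SequenceRecord
    read2: SequenceRecord
    truth_class: PairClass | None = None


def simulate_pairs(
    genome: Genome,
    n_pairs: int,
    insert_mean: int = 2_000,
    insert_sd: int = 100,
    read_length: int = 100,
    seed: int = 0,
    ledger: TruthLedger | None = None,
    insert_tolerance: float = 0.3,
) -> list[SimulatedPair]:
    """Uniformly sampled error-free read pairs from the truth genome.

    When a ledger is given, each pair carries the class it should receive
    against that ledger's assembly: a read is considered mappable iff it lies
    entirely within one contig part and retains at least min_unique non-repeat
    bases (reads buried in a repeat family have no unambiguous placement and
    are conservatively counted unmappable, so the expected proper fraction is
    a lower bound), and two mapped ends are proper iff they share a scaffold
    (N-gaps preserve distances) at a concordant insert.
    """
    if insert_mean <= 2 * read_length:
        raise ValueError("insert_mean must exceed twice the read length")
    from .io_formats import revcomp

    rng = np.random.default_rng(seed)
    lengths = np.array([len(c.sequence) for c in genome.chromosomes], float)
    weights = lengths / lengths.sum()

    parts_by_chrom: dict[str, list[tuple[int, int, str, int]]] = {}
    repeats_by_chrom: dict[str, list[tuple[int, int]]] = {}
    min_unique = 24  # non-repeat bases needed to seed an unambiguous placement
    if ledger is not None:
        for c in ledger.contigs:
            if c.kind == "contaminant":
                continue
            for p in c.parts:
                parts_by_chrom.setdefault(p.chrom, []).append(
                    (p.truth_start, p.truth_end, c.scaffold_id,
                     c.scaffold_start + p.contig_offset)
                )
        for chrom in parts_by_chrom:
            parts_by_chrom[chrom].sort()
        for r in genome.repeats:
            repeats_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        repeats_by_chrom = {
            k: merge_intervals(v) for k, v in repeats_by_chrom.items()
        }

    def locate(chrom: str, s: int, e: int):
        repeat_overlap = sum(
            max(0, min(e, re_) - max(s, rs)) for rs, re_ in repeats_by_chrom.get(chrom, [])
            if rs < e and re_ > s
        )
        if (e - s) - repeat_overlap < min_unique:
            return None
        for ts, te, sid, spos in parts_by_chrom.get(chrom, []):
            if ts <= s and e <= te:
                return sid, spos + (s - ts)
        return None

    out: list[SimulatedPair] = []
    for i in range(n_pairs):
        ci = int(rng.choice(len(lengths), p=weights))
        chrom = genome.chromosomes[ci]
        insert = max(2 * read_length, int(round(rng.normal(insert_mean, insert_sd))))
        if insert >= len(chrom.sequence):
            insert = 2 * read_length
        start = int(rng.integers(0, len(chrom.sequence) - insert + 1))
        r1 = chrom.sequence[start : start + read_length]
        r2 = revcomp(chrom.sequence[start + insert - read_length : start + insert])
        truth: PairClass | None = None
        if ledger is not None:
            m1 = locate(chrom.id, start, start + read_length)
            m2 = locate(chrom.id, start + insert - read_length, start + insert)
            if m1 is None and m2 is None:
                truth = PairClass.BOTH_UNMAPPED
            elif m1 is None or m2 is None:
                truth = PairClass.ONE_END_UNMAPPED
            elif m1[0] != m2[0]:
                truth = PairClass.CROSS_SCAFFOLD
            else:
                outer = (m2[1] + read_length) - m1[1]
                lo = insert_mean * (1 - insert_tolerance)
                hi = insert_mean * (1 + insert_tolerance)
                truth = (
                    PairClass.PROPER if lo <= outer <= hi else PairClass.DISCORDANT_DISTANCE
                )
        out.append(
            SimulatedPair(
                f"pair_{i + 1}", chrom.id, start, insert,
                SequenceRecord(f"pair_{i + 1}/1", r1),
                SequenceRecord(f"pair_{i + 1}/2", r2),
                truth,
            )
        )
    return out


def sample_trusted_clones(
    genome: Genome,
    n_clones: int = 12,
    clone_length: int = 40_000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, list[tuple[int, int]]]]:
    """Exact truth-genome substrings standing in for finished clones.

    Returns the clone records and their truth intervals per chromosome
    (non-overlapping within a chromosome).
    """
    rng = np.random.default_rng(seed)
    clones: list[SequenceRecord] = []
    regions: dict[str, list[tuple[int, int]]] = {}
    lengths = np.array([len(c.sequence) for c in genome.chromosomes], float)
    weights = lengths / lengths.sum()
    guard = 0
    while len(clones) < n_clones:
        guard += 1
        if guard > 1000:
            raise ValueError("could not place trusted clones without overlap")
        ci = int(rng.choice(len(lengths), p=weights))
        chrom = genome.chromosomes[ci]
        if len(chrom.sequence) <= clone_length:
            continue
        s = int(rng.integers(0, len(chrom.sequence) - clone_length))
        if any(s < e0 and s + clone_length > s0 for s0, e0 in regions.get(chrom.id, [])):
            continue
        regions.setdefault(chrom.id, []).append((s, s + clone_length))
        clones.append(
            SequenceRecord(
                f"clone_{len(clones) + 1}",
                chrom.sequence[s : s + clone_length],
                f"{chrom.id}:{s}-{s + clone_length}",
            )
        )
    for chrom in regions:
        regions[chrom].sort()
    return clones, regions
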