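"""End-to-end appraisal of one or more assemblies against a reference,
trusted set, and gene sets, with a combined machine-readable report.

Stages run in a fixed order per assembly — contiguity, accuracy, structure,
novelty, gene representation — each stage persisting its alignments as PSL
next to the report, so any stage can be audited or re-run with external
alignments substituted. A rerun with identical config and inputs is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .accuracy import discrepancy_rates, reference_coverage, tally_discrepancies
from .aligner import AlignerParams, align_all, align_pairwise, best_alignment, build_index
from .contiguity import assembly_stats
from .gene_coverage import cdna_completeness, transcript_base_coverage
from .io_formats import (
    GenomicInterval,
    decompose_scaffolds,
    read_fasta,
    write_bed,
    write_psl,
)
from .novelty import chunk_contigs, find_unmapped_segments, gc_content, screen_contamination
from .structure import NormalizationParams, detect_split_contigs, normalize_event_count

logger = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    assemblies: list[str]
    reference: str | None = None
    trusted: str | None = None
    transcripts: str | None = None
    cdnas: str | None = None
    contaminants: str | None = None
    output_dir: str = "appraisal_out"
    seed: int = 0
    gap_threshold: int = 10
    min_contig_length: int = 100
    accuracy_min_identity: float = 0.90
    misassembly_cutoffs: tuple[int, ...] = (10_000, 25_000, 50_000)
    novelty_min_identity: float = 0.90
    min_novel_length: int = 50
    chunk_size: int = 1_000
    contamination_min_identity: float = 0.98
    contamination_min_length: int = 200
    transcript_min_identity: float = 0.95
    transcript_min_length: int = 100
    cdna_min_identity: float = 0.90
    cdna_length_cutoffs: tuple[float, ...] = (0.9, 0.5, 0.2)
    band_width: int = 64

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("misassembly_cutoffs", "cdna_length_cutoffs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if not self.assemblies:
            raise ValueError("at least one assembly path is required")
        for path in self.assemblies + [
            p
            for p in (self.reference, self.trusted, self.transcripts,
                      self.cdnas, self.contaminants)
            if p
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(path)


@dataclass
class AppraisalReport:
    config: dict
    version: str
    config_hash: str
    assemblies: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        rows: list[tuple[str, str, str]] = []
        for name, sections in self.assemblies.items():
            for section, values in sections.items():
                for key, val in _flatten(values, section):
                    rows.append((name, key, val))
        with open(path, "w") as fh:
            fh.write("assembly\tmetric\tvalue\n")
            for r in sorted(rows):
                fh.write("\t".join(r) + "\n")


def _flatten(values, prefix):
    if isinstance(values, dict):
        for k, v in values.items():
            yield from _flatten(v, f"{prefix}.{k}")
    else:
        yield prefix, f"{values:.6g}" if isinstance(values, float) else str(values)


def run_evaluation(config: EvaluationConfig) -> AppraisalReport:
    """Execute every configured stage for every assembly.

    Stage failures are recorded in the report's error block and re-raised as
    RuntimeError after the partial report is written.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = AppraisalReport(cfg_dict, __version__, cfg_hash)

    reference = read_fasta(config.reference) if config.reference else None
    trusted = read_fasta(config.trusted) if config.trusted else None
    transcripts = read_fasta(config.transcripts) if config.transcripts else None
    cdnas = read_fasta(config.cdnas) if config.cdnas else None
    contaminants = read_fasta(config.contaminants) if config.contaminants else None
    ref_index = build_index(reference, 12) if reference else None

    mean_scaffold_lengths: dict[str, float] = {}
    for path in config.assemblies:
        name = Path(path).stem
        report.assemblies[name] = {}
        try:
            _appraise_one(
                name, path, config, outdir, report,
                reference, ref_index, trusted, transcripts, cdnas, contaminants,
                mean_scaffold_lengths,
            )
        except Exception as exc:  # stage failure -> partial report
            report.errors[name] = {
                "error": str(exc),
                "traceback": traceback.format_exc(),
            }
            logger.error("appraisal of %s failed: %s", name, exc)

    # cross-assembly normalization: C = smallest mean scaffold length
    if mean_scaffold_lengths:
        c = min(mean_scaffold_lengths.values())
        for name, sections in report.assemblies.items():
            counts = sections.get("misassembly", {}).get("counts")
            if counts is None:
                continue
            sections["misassembly"]["normalized"] = {
                cutoff: normalize_event_count(
                    NormalizationParams(n, mean_scaffold_lengths[name], c)
                )
                for cutoff, n in counts.items()
            }
            sections["misassembly"]["scale_constant"] = c

    report.to_json(outdir / "report.json")
    report.to_tsv(outdir / "report.tsv")
    if report.errors:
        raise RuntimeError(f"stage failures: {sorted(report.errors)}")
    return report


def _appraise_one(
    name, path, config, outdir, report,
    reference, ref_index, trusted, transcripts, cdnas, contaminants,
    mean_scaffold_lengths,
):
    sections = report.assemblies[name]
    scaffolds = read_fasta(path)
    assembly = decompose_scaffolds(scaffolds, config.gap_threshold)

    stats = assembly_stats(assembly, config.min_contig_length)
    sections["contiguity"] = stats.as_dict()
    mean_scaffold_lengths[name] = stats.mean_scaffold_length
    band = config.band_width

    if trusted:
        params = AlignerParams(
            min_identity=config.accuracy_min_identity, min_align_length=100,
            seed_step=8, band_width=band,
        )
        index = build_index(trusted, params.k)
        alignments = align_all([c.record for c in assembly.contigs], index, params)
        write_psl(alignments, outdir / f"{name}.trusted.psl")
        tally = tally_discrepancies(alignments, trusted)
        sub, dele, ins = discrepancy_rates(tally)
        sections["accuracy"] = {
            "substitution_rate_pct": sub,
            "deletion_rate_pct": dele,
            "insertion_rate_pct": ins,
            "trusted_coverage_pct": reference_coverage(tally),
            "aligned_reference_bases": tally.aligned_reference_bases,
        }

    chunks = None
    if ref_index is not None:
        params = AlignerParams(
            min_identity=0.90, min_align_length=100, seed_step=8, band_width=band
        )
        ref_alignments = align_all(
            [c.record for c in assembly.contigs], ref_index, params
        )
        write_psl(ref_alignments, outdir / f"{name}.reference.psl")
        sections["misassembly"] = {
            "counts": {
                cutoff: len(detect_split_contigs(ref_alignments, cutoff))
                for cutoff in config.misassembly_cutoffs
            }
        }

        chunks = chunk_contigs(assembly, config.chunk_size)
        params = AlignerParams(
            min_identity=config.novelty_min_identity,
            min_align_length=config.min_novel_length, seed_step=8, band_width=band,
        )
        chunk_alignments = align_all([c.record for c in chunks], ref_index, params)
        novel = find_unmapped_segments(
            chunks, chunk_alignments,
            config.novelty_min_identity, config.min_novel_length,
        )
        contaminant_fraction = 0.0
        if contaminants and novel:
            screen = screen_contamination(
                novel, contaminants,
                config.contamination_min_identity, config.contamination_min_length,
            )
            novel = screen.segments
            contaminant_fraction = screen.matched_fraction
        putative = [s for s in novel if s.status == "putative_novel"]
        write_bed(
            [GenomicInterval(s.origin.contig_id, s.start, s.end, s.status) for s in novel],
            outdir / f"{name}.novel.bed",
        )
        sections["novelty"] = {
            "putative_novel_bases": sum(s.length for s in putative),
            "contaminant_fraction": contaminant_fraction,
            "novel_gc_pct": gc_content([s.sequence for s in putative])
            if putative
            else float("nan"),
            "segment_count": len(putative),
        }

    if transcripts:
        if chunks is None:
            chunks = chunk_contigs(assembly, config.chunk_size)
        tx_index = build_index(transcripts, 12)
        params = AlignerParams(
            min_identity=0.90, min_align_length=config.transcript_min_length,
            seed_step=8, band_width=band,
        )
        tx_alignments = align_all([c.record for c in chunks], tx_index, params)
        write_psl(tx_alignments, outdir / f"{name}.transcripts.psl")
        pooled, _per = transcript_base_coverage(
            tx_alignments, transcripts,
            config.transcript_min_identity, config.transcript_min_length,
        )
        sections["genes"] = {"transcript_coverage_pct": pooled}

    if cdnas:
        scaffold_index = build_index(scaffolds, 12)
        params = AlignerParams(
            min_identity=config.cdna_min_identity, min_align_length=100,
            seed_step=4, band_width=band,
        )
        cdna_alignments = align_all(cdnas, scaffold_index, params)
        curve = cdna_completeness(
            cdna_alignments, cdnas, config.cdna_min_identity,
            config.cdna_length_cutoffs,
        )
        sections.setdefault("genes", {})["cdna_completeness"] = {
            str(c): n for c, n in zip(curve.cutoffs, curve.counts)
        }
        sections["genes"]["cdna_total"] = curve.total
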