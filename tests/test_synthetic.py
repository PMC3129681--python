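import numpy as np
import pytest

from asmappraise.aligner import AlignerParams, align_pairwise, build_index
from asmappraise.contiguity import assembly_stats
from asmappraise.novelty import gc_content
from asmappraise.structure import PairClass
from asmappraise.synthetic import (
    CorruptionSpec,
    GenomeSpec,
    corrupt_assembly,
    generate_genome,
    simulate_pairs,
)


class TestGenerateGenome:
    def test_gc_within_half_point(self):
        g = generate_genome(GenomeSpec(n_chromosomes=1, total_length=1_000_000, seed=3))
        assert gc_content([c.sequence for c in g.chromosomes]) == pytest.approx(41.6, abs=0.5)

    def test_same_seed_identical(self):
        spec = GenomeSpec(n_chromosomes=2, total_length=200_000, seed=9)
        a, b = generate_genome(spec), generate_genome(spec)
        assert [c.sequence for c in a.chromosomes] == [c.sequence for c in b.chromosomes]
        assert a.genes == b.genes

    def test_zero_repeat_fraction_has_no_repeated_unit(self):
        spec = GenomeSpec(
            n_chromosomes=1, total_length=300_000, repeat_fraction=0.0,
            repeat_unit_length=100, seed=4,
        )
        g = generate_genome(spec)
        seq = g.chromosomes[0].sequence
        # k-mer census: no 100-mer occurs more than 3 times
        counts = {}
        step = 1
        for i in range(0, len(seq) - 100 + 1, step):
            counts[seq[i : i + 100]] = counts.get(seq[i : i + 100], 0) + 1
        assert max(counts.values()) <= 3

    def test_repeat_family_planted_at_fraction(self):
        spec = GenomeSpec(n_chromosomes=1, total_length=500_000,
                          repeat_fraction=0.1, seed=5)
        g = generate_genome(spec)
        covered = sum(r.end - r.start for r in g.repeats)
        assert covered == pytest.approx(50_000, rel=0.05)

    def test_transcripts_are_genomic_substrings(self):
        g = generate_genome(GenomeSpec(n_chromosomes=1, total_length=300_000, seed=6))
        assert g.genes and len(g.transcripts) == len(g.genes)
        for gene, tx in zip(g.genes, g.transcripts):
            chrom = g.chromosome(gene.chrom)
            assert tx.sequence == chrom.sequence[gene.start : gene.end]


class TestCorruptAssembly:
    def test_null_corruption_is_exact_copy(self):
        g = generate_genome(GenomeSpec(n_chromosomes=2, total_length=200_000, seed=8))
        spec = CorruptionSpec(
            sub_rate=0, ins_rate=0, del_rate=0, n_misjoins=0,
            contaminant_fraction=0, n_novel_inserts=0,
            target_contig_n50=None, target_scaffold_n50=None, seed=8,
        )
        assembly, ledger = corrupt_assembly(g, spec)
        assert len(assembly.scaffolds) == 2
        assert sorted(s.sequence for s in assembly.scaffolds) == sorted(
            c.sequence for c in g.chromosomes
        )
        assert ledger.events == []

    def test_realized_rates_within_three_se(self):
        g = generate_genome(GenomeSpec(n_chromosomes=2, total_length=2_000_000, seed=10))
        spec = CorruptionSpec(seed=10, n_misjoins=0, contaminant_fraction=0,
                              n_novel_inserts=0)
        _asm, ledger = corrupt_assembly(g, spec)
        n = ledger.genome_derived_bases
        counts = ledger.event_counts()
        for kind, rate in (("sub", spec.sub_rate), ("ins", spec.ins_rate)):
            se = np.sqrt(rate * (1 - rate) * n)
            assert abs(counts[kind] - rate * n) <= 3 * se
        # deletions exceed the nominal rate because of the homopolymer bias,
        # but never by more than the bias multiplier
        assert counts["del"] >= spec.del_rate * n - 3 * np.sqrt(spec.del_rate * n)
        assert counts["del"] <= spec.homopolymer_del_bias * spec.del_rate * n

    def test_fragmentation_hits_target_n50(self):
        g = generate_genome(GenomeSpec(n_chromosomes=2, total_length=2_000_000, seed=12))
        spec = CorruptionSpec(seed=12, target_contig_n50=20_000,
                              target_scaffold_n50=100_000, n_misjoins=0,
                              contaminant_fraction=0, n_novel_inserts=0)
        assembly, _ledger = corrupt_assembly(g, spec)
        stats = assembly_stats(assembly, 100)
        assert stats.n50_contig == pytest.approx(20_000, rel=0.2)
        assert stats.n50_scaffold == pytest.approx(100_000, rel=0.2)

    def test_unreachable_target_errors(self):
        g = generate_genome(GenomeSpec(n_chromosomes=2, total_length=100_000, seed=13))
        with pytest.raises(ValueError):
            corrupt_assembly(g, CorruptionSpec(target_contig_n50=1_000_000, seed=13))

    def test_determinism_byte_identical(self):
        g = generate_genome(GenomeSpec(n_chromosomes=2, total_length=300_000, seed=14))
        spec = CorruptionSpec(seed=14, n_misjoins=1, n_novel_inserts=3)
        a1, _ = corrupt_assembly(g, spec)
        a2, _ = corrupt_assembly(g, spec)
        assert [s.sequence for s in a1.scaffolds] == [s.sequence for s in a2.scaffolds]

    def test_null_corruption_alignable_at_full_identity(self):
        g = generate_genome(
            GenomeSpec(n_chromosomes=2, total_length=100_000, repeat_fraction=0, seed=15)
        )
        spec = CorruptionSpec(
            sub_rate=0, ins_rate=0, del_rate=0, n_misjoins=0,
            contaminant_fraction=0, n_novel_inserts=0,
            target_contig_n50=None, target_scaffold_n50=None, seed=15,
        )
        assembly, _ = corrupt_assembly(g, spec)
        index = build_index(g.chromosomes, 12)
        for contig in assembly.contigs:
            (a,) = align_pairwise(contig.record, index, AlignerParams(seed_step=8))
            assert a.identity == 1.0

    def test_ledger_misjoins_recorded_with_two_chromosomes(self):
        g = generate_genome(GenomeSpec(n_chromosomes=3, total_length=900_000, seed=16))
        spec = CorruptionSpec(seed=16, n_misjoins=3, contaminant_fraction=0,
                              n_novel_inserts=0)
        _asm, ledger = corrupt_assembly(g, spec)
        assert len(ledger.misjoins) == 3
        for m in ledger.misjoins:
            assert len({p.chrom for p in m.parts}) == 2
            assert all(p.truth_end - p.truth_start >= 20_000 for p in m.parts)


class TestSimulatePairs:
    def test_zero_pairs(self, small_genome):
        assert simulate_pairs(small_genome, 0, seed=1) == []

    def test_zero_sd_exact_insert(self, small_genome):
        pairs = simulate_pairs(small_genome, 50, insert_mean=2000, insert_sd=0, seed=2)
        assert all(p.insert_size == 2000 for p in pairs)

    def test_reads_match_truth_genome(self, small_genome):
        from asmappraise.io_formats import revcomp

        pairs = simulate_pairs(small_genome, 20, seed=3)
        for p in pairs:
            chrom = small_genome.chromosome(p.chrom)
            assert chrom.sequence[p.start : p.start + 100] == p.read1.sequence
            assert (
                revcomp(chrom.sequence[p.start + p.insert_size - 100 : p.start + p.insert_size])
                == p.read2.sequence
            )

    def test_truth_classes_against_ledger(self, small_genome, small_corrupted):
        _assembly, ledger = small_corrupted
        pairs = simulate_pairs(small_genome, 300, seed=4, ledger=ledger)
        classes = {p.truth_class for p in pairs}
        assert PairClass.PROPER in classes
        assert all(p.truth_class is not None for p in pairs)
        proper = sum(p.truth_class is PairClass.PROPER for p in pairs) / 300
        assert 0.5 < proper <= 1.0

    def test_insert_must_exceed_reads(self, small_genome):
        with pytest.raises(ValueError):
            simulate_pairs(small_genome, 1, insert_mean=150, read_length=100, seed=5)
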