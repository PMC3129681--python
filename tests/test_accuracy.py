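import pytest

from asmappraise.accuracy import (
    DiscrepancyTally,
    discrepancy_rates,
    reference_coverage,
    tally_discrepancies,
)
from asmappraise.aligner import AlignerParams, align_pairwise, build_index
from asmappraise.alignment import AlignmentEvent, PairwiseAlignment
from asmappraise.io_formats import SequenceRecord

from conftest import random_seq


def _aln(target, tstart, tend, blocks, events, score, matches, mismatches=0,
         qgap=0, tgap=0, query="q"):
    return PairwiseAlignment(
        query, target, "+", 1000, 1000, 0, tend - tstart, tstart, tend,
        blocks, matches, mismatches, qgap, tgap, float(score), events,
    )


class TestTally:
    def test_single_substitution_hand_alignment(self):
        trusted = [SequenceRecord("t", "ACGTACGT")]
        a = _aln("t", 0, 8, [(0, 0, 8)], [AlignmentEvent("sub", 3, 3, 1)],
                 score=7 - 3, matches=7, mismatches=1)
        tally = tally_discrepancies([a], trusted)
        assert (tally.substitutions, tally.deletion_bases, tally.insertion_bases) == (1, 0, 0)
        assert tally.aligned_reference_bases == 8

    def test_single_deletion_hand_alignment(self):
        # assembly "ACGACGT" vs trusted "ACGTACGT": T at position 3 deleted
        trusted = [SequenceRecord("t", "ACGTACGT")]
        a = _aln("t", 0, 8, [(0, 0, 3), (3, 4, 4)],
                 [AlignmentEvent("del", 3, 3, 1)],
                 score=7 - 7, matches=7, qgap=1)
        tally = tally_discrepancies([a], trusted)
        assert tally.deletion_bases == 1
        assert tally.covered_reference_bases == 8

    def test_identical_assembly_all_zero(self, rng):
        trusted = [SequenceRecord(f"c{i}", random_seq(rng, 2000)) for i in range(3)]
        index = build_index(trusted, 12)
        alignments = []
        for t in trusted:
            alignments.extend(
                align_pairwise(SequenceRecord("asm_" + t.id, t.sequence), index,
                               AlignerParams())
            )
        tally = tally_discrepancies(alignments, trusted)
        assert tally.substitutions == tally.deletion_bases == tally.insertion_bases == 0
        assert tally.covered_reference_bases == tally.total_reference_bases

    def test_unknown_target_errors(self):
        a = _aln("nope", 0, 8, [(0, 0, 8)], [], 8, 8)
        with pytest.raises(ValueError, match="nope"):
            tally_discrepancies([a], [SequenceRecord("t", "ACGT")])

    def test_overlap_resolved_by_best_score(self):
        # two alignments covering the same trusted span; only the better one
        # may contribute its substitution
        trusted = [SequenceRecord("t", "A" * 100)]
        best = _aln("t", 0, 100, [(0, 0, 100)], [], 100, 100, query="q1")
        worse = _aln("t", 0, 100, [(0, 0, 100)],
                     [AlignmentEvent("sub", 50, 50, 1)], 96, 99, 1, query="q2")
        tally = tally_discrepancies([best, worse], trusted)
        assert tally.substitutions == 0
        assert tally.aligned_reference_bases == 100

    def test_pooling_invariance_across_trusted_split(self, rng):
        trusted = [SequenceRecord(f"c{i}", random_seq(rng, 1500)) for i in range(4)]
        index = build_index(trusted, 12)
        alignments = []
        for t in trusted:
            mutated = list(t.sequence)
            mutated[700] = "A" if mutated[700] != "A" else "C"
            alignments.extend(
                align_pairwise(SequenceRecord("asm_" + t.id, "".join(mutated)),
                               index, AlignerParams())
            )
        pooled = tally_discrepancies(alignments, trusted)
        summed = DiscrepancyTally()
        for t in trusted:
            sub = [a for a in alignments if a.target_id == t.id]
            summed = summed + tally_discrepancies(sub, [t])
        assert pooled == summed


class TestRates:
    def test_direct_division(self):
        t = DiscrepancyTally(1, 0, 0, 8, 8, 8)
        assert discrepancy_rates(t) == (12.5, 0.0, 0.0)

    def test_zero_events(self):
        t = DiscrepancyTally(0, 0, 0, 100, 100, 100)
        assert discrepancy_rates(t) == (0.0, 0.0, 0.0)

    def test_zero_aligned_errors(self):
        with pytest.raises(ValueError):
            discrepancy_rates(DiscrepancyTally())

    def test_indel_unit_events_counts_openings(self):
        trusted = [SequenceRecord("t", "A" * 100)]
        a = _aln("t", 0, 100, [(0, 0, 50), (50, 53, 47)],
                 [AlignmentEvent("del", 50, 50, 3)], 90, 97, qgap=3)
        by_bases = tally_discrepancies([a], trusted)
        by_events = tally_discrepancies([a], trusted, indel_unit="events")
        assert by_bases.deletion_bases == 3
        assert by_events.deletion_bases == 1


class TestCoverage:
    def test_full_copy_is_100(self):
        t = DiscrepancyTally(0, 0, 0, 500, 500, 500)
        assert reference_coverage(t) == 100.0

    def test_half_unalignable_pools_proportionally(self):
        # one clone fully covered, an equal-length clone not at all
        t = DiscrepancyTally(0, 0, 0, 500, 500, 1000)
        assert reference_coverage(t) == 50.0

    def test_planted_missing_fraction_recovered(self, rng):
        # repeat-free genome: 4% of the trusted bases deleted by construction
        from asmappraise.synthetic import (
            CorruptionSpec, GenomeSpec, corrupt_assembly, generate_genome,
            sample_trusted_clones,
        )

        genome = generate_genome(
            GenomeSpec(n_chromosomes=2, total_length=400_000,
                       repeat_fraction=0.0, seed=11)
        )
        spec = CorruptionSpec(
            sub_rate=0, ins_rate=0, del_rate=0, n_misjoins=0,
            contaminant_fraction=0, n_novel_inserts=0,
            target_contig_n50=12_000, target_scaffold_n50=60_000,
            gap_length_range=(450, 550), seed=11,
        )
        assembly, ledger = corrupt_assembly(genome, spec)
        clones, regions = sample_trusted_clones(genome, 6, 30_000, seed=11)
        index = build_index(clones, 12)
        params = AlignerParams(min_align_length=100, seed_step=8)
        alignments = []
        for c in assembly.contigs:
            alignments.extend(align_pairwise(c.record, index, params))
        tally = tally_discrepancies(alignments, clones)
        covered = ledger.covered_truth_intervals()
        expected = 0
        for chrom, ivs in regions.items():
            for s, e in ivs:
                for cs, ce in covered.get(chrom, []):
                    expected += max(0, min(e, ce) - max(s, cs))
        expected_pct = 100.0 * expected / sum(len(c.sequence) for c in clones)
        assert reference_coverage(tally) == pytest.approx(expected_pct, abs=0.5)
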