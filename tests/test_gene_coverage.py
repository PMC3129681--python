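import pytest

from asmappraise.alignment import PairwiseAlignment, interval_total, merge_intervals
from asmappraise.gene_coverage import (
    cdna_completeness,
    gene_fragmentation,
    transcript_base_coverage,
)
from asmappraise.io_formats import GenomicInterval, SequenceRecord

from oracles import union_by_base_set


def _aln(query, target, tstart, tend, identity=0.99, qsize=1000, tsize=2000):
    length = tend - tstart
    matches = int(round(identity * length))
    return PairwiseAlignment(
        query, target, "+", qsize, tsize, 0, length, tstart, tend,
        [(0, tstart, length)], matches, length - matches, 0, 0, float(matches),
    )


class TestTranscriptCoverage:
    def test_qualifying_chunk_covers_its_interval(self):
        tx = [SequenceRecord("t1", "A" * 2000)]
        pooled, per = transcript_base_coverage(
            [_aln("c1", "t1", 100, 220, identity=0.96)], tx, 0.95, 100
        )
        assert per[0].covered_bases == 120
        assert pooled == pytest.approx(100 * 120 / 2000)

    def test_identity_cutoff_is_strict(self):
        tx = [SequenceRecord("t1", "A" * 2000)]
        pooled, per = transcript_base_coverage(
            [_aln("c1", "t1", 100, 220, identity=0.94)], tx, 0.95, 100
        )
        assert per[0].covered_bases == 0 and pooled == 0.0

    def test_overlapping_chunks_union(self):
        tx = [SequenceRecord("t1", "A" * 2000)]
        alns = [
            _aln("c1", "t1", 0, 120, identity=1.0),
            _aln("c2", "t1", 60, 200, identity=1.0),
        ]
        _pooled, per = transcript_base_coverage(alns, tx, 0.95, 100)
        assert per[0].covered_bases == 200

    def test_only_best_alignment_per_chunk_counts(self):
        tx = [SequenceRecord("t1", "A" * 2000), SequenceRecord("t2", "A" * 2000)]
        alns = [
            _aln("c1", "t1", 0, 150, identity=1.0),
            _aln("c1", "t2", 0, 150, identity=0.97),  # lower score, dropped
        ]
        _pooled, per = transcript_base_coverage(alns, tx, 0.95, 100)
        by_id = {p.transcript_id: p.covered_bases for p in per}
        assert by_id == {"t1": 150, "t2": 0}

    def test_pooled_invariant_to_batch_split(self):
        tx = [SequenceRecord(f"t{i}", "A" * 1000) for i in range(4)]
        alns = [
            _aln(f"c{i}", f"t{i % 4}", 0, 400 + 50 * i, identity=1.0) for i in range(8)
        ]
        pooled_all, _ = transcript_base_coverage(alns, tx, 0.95, 100)
        # per-transcript union then pooled must match (transcript split)
        total_cov = 0
        for t in tx:
            _p, per = transcript_base_coverage(
                [a for a in alns if a.target_id == t.id], [t], 0.95, 100
            )
            total_cov += per[0].covered_bases
        assert pooled_all == pytest.approx(100.0 * total_cov / 4000)


class TestIntervalUnion:
    def test_matches_base_set_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 15))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                intervals.append((s, s + int(rng.integers(1, 80))))
            assert interval_total(intervals) == union_by_base_set(intervals)
            merged = merge_intervals(intervals)
            assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))


class TestCdnaCompleteness:
    def _cdna_aln(self, query, aligned, identity=0.96, qsize=1000):
        matches = int(round(identity * aligned))
        return PairwiseAlignment(
            query, "scaf1", "+", qsize, 100_000, 0, aligned, 0, aligned,
            [(0, 0, aligned)], matches, aligned - matches, 0, 0, float(matches),
        )

    def test_cutoff_membership(self):
        cdnas = [SequenceRecord("c1", "A" * 1000)]
        curve = cdna_completeness([self._cdna_aln("c1", 950)], cdnas, 0.9, (0.9, 0.5, 0.2))
        assert curve.counts == [1, 1, 1]
        curve = cdna_completeness([self._cdna_aln("c1", 300)], cdnas, 0.9, (0.9, 0.5, 0.2))
        assert curve.counts == [0, 0, 1]

    def test_identity_floor(self):
        cdnas = [SequenceRecord("c1", "A" * 1000)]
        curve = cdna_completeness(
            [self._cdna_aln("c1", 950, identity=0.85)], cdnas, 0.9, (0.9, 0.2)
        )
        assert curve.counts == [0, 0]

    def test_counts_monotone_in_cutoff(self):
        cdnas = [SequenceRecord(f"c{i}", "A" * 1000) for i in range(5)]
        alns = [self._cdna_aln(f"c{i}", 150 + 200 * i) for i in range(5)]
        curve = cdna_completeness(alns, cdnas, 0.9, (0.9, 0.5, 0.2))
        assert curve.counts == sorted(curve.counts)
        assert curve.fractions[-1] <= 1.0


class TestGeneFragmentation:
    def _scaffold_aln(self, scaffold, chrom, tstart, tend):
        return _aln(scaffold, chrom, tstart, tend, qsize=200_000, tsize=1_000_000)

    def test_locus_in_one_scaffold(self):
        locus = GenomicInterval("chr1", 5000, 8000, "g1")
        alns = [self._scaffold_aln("s1", "chr1", 0, 50_000)]
        assert gene_fragmentation(locus, alns) == 1

    def test_no_overlap_is_zero(self):
        locus = GenomicInterval("chr1", 500_000, 503_000, "g1")
        alns = [self._scaffold_aln("s1", "chr1", 0, 50_000)]
        assert gene_fragmentation(locus, alns) == 0

    def test_breaks_plus_one(self):
        # a gene split across 3 deliberate breaks spans 4 scaffolds
        locus = GenomicInterval("chr1", 0, 40_000, "g1")
        alns = [
            self._scaffold_aln(f"s{i}", "chr1", i * 10_000, (i + 1) * 10_000 - 100)
            for i in range(4)
        ]
        assert gene_fragmentation(locus, alns) == 4

    def test_locus_beyond_chromosome_errors(self):
        locus = GenomicInterval("chr1", 0, 2_000_000, "g1")
        alns = [self._scaffold_aln("s1", "chr1", 0, 50_000)]
        with pytest.raises(ValueError):
            gene_fragmentation(locus, alns)
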