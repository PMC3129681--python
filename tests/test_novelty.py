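import math

import pytest
from hypothesis import given, settings, strategies as st

from asmappraise.alignment import PairwiseAlignment
from asmappraise.io_formats import SequenceRecord, decompose_scaffolds, revcomp
from asmappraise.novelty import (
    ChunkSegment,
    chunk_contigs,
    find_unmapped_segments,
    gc_content,
    screen_contamination,
    shared_novel,
)

from conftest import random_seq


def _assembly(*seqs):
    return decompose_scaffolds(
        [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)], 10
    )


class TestChunkContigs:
    def test_tail_merges_into_final_segment(self):
        asm = _assembly("A" * 2500)
        segs = chunk_contigs(asm, 1000)
        assert [(s.start, s.end) for s in segs] == [(0, 1000), (1000, 2500)]

    def test_exact_multiple(self):
        segs = chunk_contigs(_assembly("A" * 1000), 1000)
        assert [(s.start, s.end) for s in segs] == [(0, 1000)]

    def test_short_contig_single_segment(self):
        segs = chunk_contigs(_assembly("A" * 999), 1000)
        assert [(s.start, s.end) for s in segs] == [(0, 999)]

    @given(st.integers(1, 5000))
    @settings(max_examples=60, deadline=None)
    def test_segments_tile_contig_exactly(self, m):
        segs = chunk_contigs(_assembly("A" * m), 1000)
        assert segs[0].start == 0 and segs[-1].end == m
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert all(len(s) < 2000 for s in segs)
        assert all(len(s) >= 1000 or m < 1000 for s in segs)


def _chunk(seq, contig="s0:0-1000", start=0):
    return ChunkSegment(contig, start, start + len(seq), seq)


def _ref_aln(chunk, qstart, qend, identity=0.99):
    length = qend - qstart
    matches = int(round(identity * length))
    return PairwiseAlignment(
        chunk.id, "chr1", "+", len(chunk), 1_000_000, qstart, qend, 0, length,
        [(qstart, 0, length)], matches, length - matches, 0, 0, float(matches),
    )


class TestFindUnmapped:
    def test_unaligned_chunk_is_fully_novel(self, rng):
        chunk = _chunk(random_seq(rng, 1000))
        (seg,) = find_unmapped_segments([chunk], [], 0.9, 50)
        assert seg.length == 1000 and seg.status == "putative_novel"

    def test_fully_aligned_chunk_yields_nothing(self, rng):
        chunk = _chunk(random_seq(rng, 1000))
        assert find_unmapped_segments([chunk], [_ref_aln(chunk, 0, 1000)], 0.9, 50) == []

    def test_strictly_over_50_rule(self, rng):
        chunk60 = _chunk(random_seq(rng, 1000))
        (seg,) = find_unmapped_segments([chunk60], [_ref_aln(chunk60, 0, 940)], 0.9, 50)
        assert seg.length == 60
        chunk50 = _chunk(random_seq(rng, 1000))
        assert (
            find_unmapped_segments([chunk50], [_ref_aln(chunk50, 0, 950)], 0.9, 50) == []
        )

    def test_low_identity_alignment_does_not_mask(self, rng):
        chunk = _chunk(random_seq(rng, 1000))
        (seg,) = find_unmapped_segments(
            [chunk], [_ref_aln(chunk, 0, 1000, identity=0.8)], 0.9, 50
        )
        assert seg.length == 1000

    def test_novel_bases_monotone_in_identity_threshold(self, rng):
        chunks = [_chunk(random_seq(rng, 1000), f"c{i}:0-1000") for i in range(6)]
        alignments = [
            _ref_aln(c, 0, 900, identity=idy)
            for c, idy in zip(chunks, (1.0, 0.97, 0.93, 0.91, 0.86, 0.8))
        ]
        totals = [
            sum(
                s.length
                for s in find_unmapped_segments(chunks, alignments, mi, 50)
            )
            for mi in (0.98, 0.95, 0.90, 0.85)
        ]
        assert totals == sorted(totals, reverse=True)


class TestScreenContamination:
    def test_verbatim_contaminant_substring(self, rng):
        db = [SequenceRecord("ecoli", random_seq(rng, 5000))]
        seg = find_unmapped_segments([_chunk(db[0].sequence[1000:1500])], [], 0.9, 50)[0]
        result = screen_contamination([seg], db)
        assert result.segments[0].status == "contaminant"
        assert result.matched_fraction == 1.0
        assert result.by_source == {"ecoli": 500}

    def test_no_hits_partition_unchanged(self, rng):
        db = [SequenceRecord("ecoli", random_seq(rng, 5000))]
        seg = find_unmapped_segments([_chunk(random_seq(rng, 500))], [], 0.9, 50)[0]
        result = screen_contamination([seg], db)
        assert result.segments[0].status == "putative_novel"
        assert result.matched_bases == 0

    def test_empty_db_errors(self, rng):
        seg = find_unmapped_segments([_chunk(random_seq(rng, 500))], [], 0.9, 50)[0]
        with pytest.raises(ValueError):
            screen_contamination([seg], [])


class TestSharedNovel:
    def test_identical_sets_fully_shared(self, rng):
        segs = find_unmapped_segments(
            [_chunk(random_seq(rng, 1000), f"c{i}:0-1000") for i in range(3)], [], 0.9, 50
        )
        summary = shared_novel(segs, segs)
        assert summary.a_shared == summary.a_total
        assert summary.shared == summary.a_total

    def test_disjoint_sets_share_nothing(self, rng):
        a = find_unmapped_segments([_chunk(random_seq(rng, 800), "a:0-800")], [], 0.9, 50)
        b = find_unmapped_segments([_chunk(random_seq(rng, 800), "b:0-800")], [], 0.9, 50)
        summary = shared_novel(a, b)
        assert summary.shared == 0
        assert summary.a_exclusive == summary.a_total


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGCC", 100.0)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_excluded_from_denominator(self):
        assert gc_content("GGNNNN") == 100.0

    def test_all_n_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    @given(st.text(alphabet="ACGTN", min_size=1).filter(lambda s: set(s) != {"N"}))
    @settings(max_examples=80, deadline=None)
    def test_revcomp_invariant(self, seq):
        assert math.isclose(gc_content(seq), gc_content(revcomp(seq)))
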