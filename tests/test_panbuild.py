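"""Map-to-pan construction: aligner, classification, redundancy, assembly."""

import numpy as np
import pytest

from pavpan import (
    AlignmentBlock, PanBuildParams, align_contigs, classify_contigs,
    filter_short_contigs, remove_redundancy, filter_contamination,
    build_pangenome,
)
from pavpan.panbuild import NonRefSegment, is_reliable


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(42)
    return {"chr1": _random_seq(rng, 10_000)}


def _unrelated(rng, n, ref):
    """Random sequence sharing no 21-mer with the reference."""
    kmers = {ref[i:i + 21] for i in range(len(ref) - 20)}
    while True:
        s = _random_seq(rng, n)
        if not any(s[i:i + 21] in kmers for i in range(n - 20)):
            return s


class TestAligner:
    def test_exact_substring_one_full_identity_block(self, reference):
        contig = reference["chr1"][3000:5000]
        blocks = align_contigs({"c": contig}, reference)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.query_start, b.query_end) == (0, 2000)
        assert (b.ref_start, b.ref_end) == (3000, 5000)
        assert b.identity == 1.0

    def test_no_shared_kmer_no_blocks(self, reference):
        rng = np.random.default_rng(1)
        contig = _unrelated(rng, 800, reference["chr1"])
        assert align_contigs({"c": contig}, reference) == []

    def test_half_matching_contig_block_covers_only_the_match(self, reference):
        rng = np.random.default_rng(2)
        match = reference["chr1"][1000:2000]
        tail = _unrelated(rng, 1000, reference["chr1"])
        blocks = align_contigs({"c": match + tail}, reference)
        spans = [(b.query_start, b.query_end) for b in blocks]
        # the matching kilobase is covered; nothing reaches deep into the tail
        assert any(s <= 0 + 2 and abs(e - 1000) <= 25 for s, e in spans)
        assert all(e <= 1025 for _, e in spans)

    def test_reverse_complement_contig_is_found(self, reference):
        comp = str.maketrans("ACGT", "TGCA")
        contig = reference["chr1"][3000:5000].translate(comp)[::-1]
        blocks = align_contigs({"c": contig}, reference)
        assert len(blocks) == 1
        assert blocks[0].strand == "-"
        assert blocks[0].identity == 1.0
        assert (blocks[0].ref_start, blocks[0].ref_end) == (3000, 5000)

    def test_identity_equals_matches_over_columns(self, reference):
        contig = list(reference["chr1"][4000:5000])
        # plant 10 mismatches away from the ends
        for i in range(100, 600, 50):
            contig[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[contig[i]]
        blocks = align_contigs({"c": "".join(contig)}, reference)
        assert len(blocks) == 1
        b = blocks[0]
        cols = b.query_end - b.query_start
        assert b.identity == pytest.approx((cols - 10) / cols)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            align_contigs({"c": "ACGT" * 100}, {})


class TestClassification:
    params = PanBuildParams()

    def test_contig_without_blocks_is_fully_unaligned_whole(self):
        contigs = {"c": "ACGT" * 200}
        res = classify_contigs([], contigs, self.params)
        assert res["fully_unaligned"] == ["c"]
        assert res["aligned"] == []
        [seg] = res["segments"]
        assert (seg.start, seg.end) == (0, 800)
        assert seg.sequence == contigs["c"]

    def test_gap_beyond_reliable_block_becomes_segment(self):
        contigs = {"c": "A" * 2000}
        block = AlignmentBlock("c", 0, 1200, "chr1", 0, 1200, 0.99)
        res = classify_contigs([block], contigs, self.params)
        assert res["aligned"] == ["c"]
        [seg] = res["segments"]
        assert (seg.start, seg.end) == (1200, 2000)
        assert len(seg.sequence) == 800

    def test_fully_covered_contig_yields_no_segments(self):
        contigs = {"c": "A" * 1500}
        block = AlignmentBlock("c", 0, 1500, "chr1", 0, 1500, 1.0)
        res = classify_contigs([block], contigs, self.params)
        assert res["segments"] == []

    def test_low_identity_block_is_not_reliable(self):
        # identity exactly at the threshold reads as not exceeding it
        contigs = {"c": "A" * 1500}
        block = AlignmentBlock("c", 0, 1500, "chr1", 0, 1500, 0.90)
        assert not is_reliable(block, self.params)
        res = classify_contigs([block], contigs, self.params)
        assert res["fully_unaligned"] == ["c"]

    def test_short_block_is_not_reliable(self):
        block = AlignmentBlock("c", 0, 300, "chr1", 0, 300, 1.0)
        assert not is_reliable(block, self.params)
        assert is_reliable(AlignmentBlock("c", 0, 301, "chr1", 0, 301, 1.0), self.params)

    def test_unknown_contig_in_block_rejected(self):
        block = AlignmentBlock("ghost", 0, 400, "chr1", 0, 400, 1.0)
        with pytest.raises(ValueError, match="unknown contig"):
            classify_contigs([block], {"c": "A" * 600}, self.params)

    def test_classification_is_a_partition(self, reference):
        rng = np.random.default_rng(3)
        contigs = {
            "match": reference["chr1"][0:1500],
            "novel": _unrelated(rng, 900, reference["chr1"]),
            "mixed": reference["chr1"][2000:3000] + _unrelated(rng, 700, reference["chr1"]),
        }
        blocks = align_contigs(contigs, reference)
        res = classify_contigs(blocks, contigs, self.params)
        assert sorted(res["aligned"] + res["fully_unaligned"]) == sorted(contigs)
        assert set(res["aligned"]) & set(res["fully_unaligned"]) == set()

    def test_segments_never_overlap_reliable_blocks(self, reference):
        rng = np.random.default_rng(4)
        contigs = {
            "mixed": reference["chr1"][2000:3200] + _unrelated(rng, 900, reference["chr1"]),
        }
        blocks = align_contigs(contigs, reference)
        res = classify_contigs(blocks, contigs, self.params)
        reliable = [
            (b.query_start, b.query_end) for b in blocks if is_reliable(b, self.params)
        ]
        for seg in res["segments"]:
            for s, e in reliable:
                assert seg.end <= s or seg.start >= e


def _seg(sid, seq):
    return NonRefSegment(id=sid, source_accession="a", source_contig=sid,
                         start=0, end=len(seq), sequence=seq)


class TestRedundancy:
    def test_identical_segments_keep_exactly_one(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 700)
        out = remove_redundancy([_seg("s1", seq), _seg("s2", seq)])
        assert [s.id for s in out] == ["s1"]

    def test_high_coverage_high_identity_discarded(self):
        rng = np.random.default_rng(6)
        a = _random_seq(rng, 1000)
        # b: 95% of its length matches a at ~99.5% identity
        b = list(a[:950])
        for i in range(200, 800, 200):
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        out = remove_redundancy([_seg("a", a), _seg("b", "".join(b))])
        assert [s.id for s in out] == ["a"]

    def test_low_coverage_retained_despite_high_identity(self):
        rng = np.random.default_rng(7)
        a = _random_seq(rng, 1000)
        # b: only 60% of its length aligns to a (at 100% identity)
        b = a[:600] + _unrelated(rng, 400, a)
        out = remove_redundancy([_seg("a", a), _seg("b", b)])
        assert [s.id for s in out] == ["a", "b"]

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        segs = [
            _seg(f"s{i}", _random_seq(rng, 600 + 50 * i)) for i in range(4)
        ]
        segs.append(_seg("dup", segs[-1].sequence))
        once = remove_redundancy(segs)
        twice = remove_redundancy(once)
        assert [s.id for s in once] == [s.id for s in twice]

    def test_order_is_length_desc_then_id(self):
        rng = np.random.default_rng(9)
        seqs = {sid: _unrelated(rng, n, "") for sid, n in
                [("z", 800), ("a", 800), ("m", 900)]}
        out = remove_redundancy([_seg(sid, seqs[sid]) for sid in ["z", "a", "m"]])
        assert [s.id for s in out] == ["m", "a", "z"]


class TestContaminationAndAssembly:
    def test_contamination_filter(self):
        segs = [_seg("s1", "A" * 600), _seg("s2", "C" * 600), _seg("s3", "G" * 600)]
        assert filter_contamination(segs, {"s1": "keep", "s2": "keep", "s3": "keep"}) == segs
        dropped = filter_contamination(segs, {"s2": "drop"})
        assert [s.id for s in dropped] == ["s1", "s3"]
        assert filter_contamination(segs, {}) == segs

    def test_pangenome_length_is_additive(self, reference):
        segs = [_seg("s1", "A" * 600), _seg("s2", "C" * 700), _seg("s3", "G" * 800)]
        pan = build_pangenome(reference, segs)
        assert sum(map(len, pan.values())) == sum(map(len, reference.values())) + 2100
        assert build_pangenome(reference, []) == reference

    def test_duplicate_id_rejected(self, reference):
        ref = dict(reference)
        ref["panseg00001"] = "A" * 100
        with pytest.raises(ValueError, match="duplicate"):
            build_pangenome(ref, [_seg("x", "C" * 600)])


class TestPipelineOnTruth:
    def test_planted_novel_sequences_recovered(self, small_bundle):
        b = small_bundle
        params = PanBuildParams()
        segments = []
        for acc in b.accessions:
            ctgs = filter_short_contigs(b.contigs[acc], params)
            blocks = align_contigs(ctgs, b.reference)
            segments += classify_contigs(blocks, ctgs, params, accession=acc)["segments"]
        nonred = remove_redundancy(segments, params)
        recovered = {
            nid for nid, seq in b.novel_sequences.items()
            if any(s.sequence == seq for s in nonred)
        }
        planted = {
            nid for nid in b.novel_sequences
            if b.truth.presence.loc[nid].sum() > 0
        }
        assert recovered == planted
        # no pure reference substring survives
        ref = b.reference["chr1"]
        assert not any(s.sequence in ref for s in nonred)
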