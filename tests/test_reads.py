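import numpy as np
import pytest

from mcctools.core import GenomicInterval, TargetRegion
from mcctools.io import FastqRecord
from mcctools.reads import (ChimericSplitter, MergedRead, merge_pairs,
                            place_segments, split_chimeric, trim_adapters)
from mcctools.simulate import ADAPTER_R1, ADAPTER_R2, revcomp

from conftest import random_region


def fq(id_, seq, qual=None):
    return FastqRecord(id_, seq, qual or "F" * len(seq))


def _random_seq(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


class TestTrimAdapters:
    def test_full_adapter_suffix_removed(self):
        insert = _random_seq(0, 100)
        r1 = fq("a", insert + ADAPTER_R1 + "G" * 17)
        r2 = fq("a", _random_seq(1, 100) + ADAPTER_R2 + "G" * 17)
        out, stats = trim_adapters([(r1, r2)])
        assert out[0][0].sequence == insert
        assert len(out[0][1]) == 100
        assert stats["pairs_trimmed"] == 1

    def test_adapter_free_read_unchanged(self):
        r1, r2 = fq("a", _random_seq(2, 150)), fq("a", _random_seq(3, 150))
        out, stats = trim_adapters([(r1, r2)])
        assert out[0][0].sequence == r1.sequence
        assert stats["pairs_trimmed"] == 0

    def test_pair_dropped_when_too_short(self):
        r1 = fq("a", _random_seq(4, 5) + ADAPTER_R1 + ADAPTER_R1[:20])
        r2 = fq("a", _random_seq(5, 58))
        out, stats = trim_adapters([(r1, r2)])
        assert out == []
        assert stats["pairs_dropped_short"] == 1

    def test_partial_terminal_adapter_removed(self):
        insert = _random_seq(6, 130)
        r1 = fq("a", insert + ADAPTER_R1[:20])
        out, _ = trim_adapters([(r1, fq("a", _random_seq(7, 150)))])
        assert out[0][0].sequence == insert


class TestMergePairs:
    def test_exact_overlap_produces_spliced_consensus(self):
        mol = _random_seq(8, 270)
        r1 = fq("m", mol[:150])
        r2 = fq("m", revcomp(mol[-150:]))
        merged, stats = merge_pairs([(r1, r2)])
        assert stats["pairs_merged"] == 1
        assert len(merged) == 1
        assert merged[0].sequence == mol
        assert merged[0].mate_overlap == 30

    def test_disjoint_mates_stay_unmerged(self):
        r1 = fq("m", _random_seq(9, 150))
        r2 = fq("m", _random_seq(10, 150))
        merged, stats = merge_pairs([(r1, r2)])
        assert stats["pairs_unmerged"] == 1
        assert [m.id for m in merged] == ["m/1", "m/2"]
        assert not any(m.merged for m in merged)

    def test_mismatch_in_overlap_takes_higher_quality_base(self):
        mol = _random_seq(11, 60)
        r1_seq = mol[:35]
        r2_region = list(mol[25:])
        # corrupt one base of the 10 bp overlap on the R2 side
        r2_region[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2_region[5]]
        r1 = fq("m", r1_seq, "I" * 35)           # Q40
        r2 = fq("m", revcomp("".join(r2_region)), "#" * 35)  # Q2
        merged, _ = merge_pairs([(r1, r2)])
        assert len(merged) == 1 and merged[0].merged
        assert merged[0].sequence == mol  # R1's base wins at the mismatch


@pytest.fixture(scope="module")
def two_regions():
    return [random_region(20, 2500, start=0, name="A"),
            random_region(21, 2500, start=5000, name="B")]


class TestChimericSplit:

    def _chimeric_read(self, regions, cut_a, cut_b, len_a=75, len_b=75):
        """75 bp from A + 75 bp from B, spliced with zero micro-homology."""
        a = regions[0].sequence[cut_a - len_a : cut_a]
        b = regions[1].sequence[cut_b : cut_b + len_b]
        return a + b

    def test_two_locus_read_split_at_exact_boundary(self, two_regions):
        # choose a splice with no chance micro-homology on either side
        for cut_a in range(100, 400):
            a_cont = two_regions[0].sequence[cut_a]
            b_first = two_regions[1].sequence[200]
            a_last = two_regions[0].sequence[cut_a - 1]
            b_pre = two_regions[1].sequence[199]
            if a_cont != b_first and a_last != b_pre:
                break
        seq = self._chimeric_read(two_regions, cut_a, 200)
        splitter = ChimericSplitter(two_regions)
        segs = splitter.split(MergedRead("r", seq, "F" * len(seq), True))
        assert [(s.q_start, s.q_end) for s in segs] == [(0, 75), (75, 150)]
        assert segs[0].chrom == "chrT" and segs[0].g_end == cut_a
        assert segs[1].g_start == 5000 + 200

    def test_single_locus_read_gives_one_segment(self, two_regions):
        seq = two_regions[0].sequence[300:450]
        segments, stats = split_chimeric(
            [MergedRead("r", seq, "F" * 150, True)], two_regions)
        assert len(segments["r"]) == 1
        seg = segments["r"][0]
        assert (seg.q_start, seg.q_end) == (0, 150)
        assert (seg.g_start, seg.g_end, seg.strand) == (300, 450, "+")

    def test_reverse_strand_read_recognized(self, two_regions):
        seq = revcomp(two_regions[0].sequence[300:450])
        segs = ChimericSplitter(two_regions).split(
            MergedRead("r", seq, "F" * 150, True))
        assert len(segs) == 1
        assert segs[0].strand == "-"
        assert (segs[0].g_start, segs[0].g_end) == (300, 450)

    def test_off_target_read_discarded(self, two_regions):
        seq = _random_seq(99, 150)
        segments, stats = split_chimeric(
            [MergedRead("r", seq, "F" * 150, True)], two_regions)
        assert segments == {}
        assert stats["reads_off_target"] == 1

    def test_query_overlap_bounded(self, small_processed):
        for segs in small_processed["placed"].values():
            segs = sorted(segs, key=lambda s: s.q_start)
            for a, b in zip(segs, segs[1:]):
                assert a.q_end - b.q_start <= 35

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            ChimericSplitter([])


class TestPlacement:
    def test_concordant_segment_kept_with_coordinates(self):
        region = random_region(30, 2000, start=1000, name="A")
        genome = {"chrT": _random_seq(31, 1000) + region.sequence
                  + _random_seq(32, 1000)}
        read = MergedRead("r", region.sequence[100:250], "F" * 150, True)
        segments, _ = split_chimeric([read], [region])
        placed, stats = place_segments(segments, {"r": read.sequence}, genome)
        assert stats["segments_ambiguous"] == 0
        seg = placed["r"][0]
        assert (seg.g_start, seg.g_end) == (1100, 1250)

    def test_substituted_segment_placed_with_reduced_identity(self):
        region = random_region(33, 2000, start=0, name="A")
        genome = {"chrT": region.sequence}
        sub = list(region.sequence[100:175])
        sub[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[30]]
        read = MergedRead("r", "".join(sub), "F" * 75, True)
        segments, _ = split_chimeric([read], [region])
        placed, _ = place_segments(segments, {"r": read.sequence}, genome)
        seg = placed["r"][0]
        assert (seg.g_start, seg.g_end) == (100, 175)
        assert seg.identity == pytest.approx(74 / 75)

    def test_duplicated_locus_flagged_ambiguous(self):
        unit = _random_seq(34, 400)
        genome = {"chrT": unit + _random_seq(35, 2000) + unit}
        region = TargetRegion("A", GenomicInterval("chrT", 0, 400), unit)
        read = MergedRead("r", unit[50:200], "F" * 150, True)
        segments, _ = split_chimeric([read], [region])
        placed, stats = place_segments(segments, {"r": read.sequence}, genome)
        assert stats["segments_ambiguous"] == 1
        assert placed == {}
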