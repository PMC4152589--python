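"""MAPQ / proper-pair / multi-mapper filters, duplicate marking and
library complexity, including the brute-force duplicate oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from peakforge import read_filtering as rf
from peakforge.genomic_io import ReadPair

from conftest import pe_pair, se_read


class TestClassifyPair:
    @pytest.mark.parametrize(
        "mapqs,expected",
        [
            ((60, 37), rf.PairClass.both_unique),
            ((30, 0), rf.PairClass.one_unique),
            ((0, 0), rf.PairClass.both_multi),
        ],
    )
    def test_mapping_states(self, mapqs, expected):
        assert rf.classify_pair(pe_pair("p", mapq1=mapqs[0], mapq2=mapqs[1])) == expected

    def test_unmapped_mate_rejected(self):
        pair = pe_pair("p")
        broken = ReadPair(pair.first, pair.second.with_flag(0x4))
        with pytest.raises(ValueError, match="proper-pair"):
            rf.classify_pair(broken)


class TestMapqSingle:
    def test_boundary_is_inclusive(self):
        reads = [se_read("a", mapq=19), se_read("b", mapq=20)]
        kept = rf.filter_mapq_single(reads, 20)
        assert [r.query_name for r in kept] == ["b"]

    def test_cutoff_zero_keeps_all_mapped(self):
        reads = [se_read(f"r{q}", mapq=q) for q in (0, 1, 60)]
        assert len(rf.filter_mapq_single(reads, 0)) == 3

    def test_random_match_exemption_keeps_mapq_zero(self):
        reads = [se_read("multi", mapq=0), se_read("low", mapq=5)]
        kept = rf.filter_mapq_single(reads, 20, keep_zero_mapq=True)
        assert [r.query_name for r in kept] == ["multi"]


class TestMapqPairs:
    def test_one_low_end_removes_whole_pair(self):
        pairs = [pe_pair("p", mapq1=5, mapq2=60)]
        assert rf.filter_mapq_pairs(pairs, 20) == []

    def test_both_zero_exemption(self):
        pairs = [pe_pair("p", mapq1=0, mapq2=0)]
        assert rf.filter_mapq_pairs(pairs, 20, keep_multi_both_zero=True) == pairs
        assert rf.filter_mapq_pairs(pairs, 20, keep_multi_both_zero=False) == []

    @given(
        mapqs=hst.lists(
            hst.tuples(hst.integers(0, 60), hst.integers(0, 60)), max_size=30
        ),
        low=hst.integers(0, 60),
        high=hst.integers(0, 60),
    )
    @settings(deadline=None, max_examples=50)
    def test_raising_cutoff_never_adds_survivors(self, mapqs, low, high):
        low, high = min(low, high), max(low, high)
        pairs = [
            pe_pair(f"p{i}", mapq1=a, mapq2=b) for i, (a, b) in enumerate(mapqs)
        ]
        survivors_low = {p.query_name for p in rf.filter_mapq_pairs(pairs, low)}
        survivors_high = {p.query_name for p in rf.filter_mapq_pairs(pairs, high)}
        assert survivors_high <= survivors_low


class TestProperPairs:
    def test_fr_within_bounds_kept(self):
        assert rf.filter_proper_pairs([pe_pair("p", insert=200)]) != []

    @pytest.mark.parametrize("orientation", ["RR", "FF", "RF"])
    def test_wrong_orientation_removed(self, orientation):
        assert rf.filter_proper_pairs([pe_pair("p", orientation=orientation)]) == []

    def test_cross_chromosome_removed(self):
        pair = pe_pair("p")
        moved = ReadPair(
            pair.first,
            pair.second.__class__(
                "p", "chr2", 300, 336, "-", 60, pair.second.flags, tlen=0
            ),
        )
        assert rf.filter_proper_pairs([moved]) == []

    def test_insert_bounds(self):
        config = rf.FilterConfig(min_insert=100, max_insert=300)
        assert rf.filter_proper_pairs([pe_pair("p", insert=350)], config) == []
        assert rf.filter_proper_pairs([pe_pair("p", insert=300)], config) != []

    def test_pairing_integrity_survivors_have_both_mates(self):
        pairs = [pe_pair(f"p{i}", insert=150 + i) for i in range(5)]
        survivors = rf.filter_proper_pairs(pairs)
        names = [m.query_name for p in survivors for m in p.mates]
        assert all(names.count(n) == 2 for n in set(names))


class TestMultimapPolicy:
    @pytest.fixture
    def mixed_pairs(self):
        a = [pe_pair(f"a{i}", mapq1=60, mapq2=60) for i in range(10)]
        b = [pe_pair(f"b{i}", mapq1=30, mapq2=0) for i in range(5)]
        c = [pe_pair(f"c{i}", mapq1=0, mapq2=0) for i in range(3)]
        return a + b + c

    @pytest.mark.parametrize(
        "policy,expected",
        [
            ("unique_only", 10),
            ("one_end_unique", 15),
            ("one_end_unique_plus_random", 18),
        ],
    )
    def test_policy_counts(self, mixed_pairs, policy, expected):
        assert len(rf.apply_multimap_policy(mixed_pairs, policy)) == expected

    def test_unknown_policy_raises(self, mixed_pairs):
        with pytest.raises(ValueError, match="policy"):
            rf.apply_multimap_policy(mixed_pairs, "keep_everything")


class TestMarkDuplicates:
    def test_three_reads_same_position_one_survives(self):
        reads = [se_read(f"r{i}", start=100) for i in range(3)]
        flagged, dedup = rf.mark_duplicates(reads)
        assert sum(r.is_duplicate for r in flagged) == 2
        assert len(dedup) == 1

    def test_opposite_strands_both_kept(self):
        reads = [
            se_read("f", start=100, strand="+"),
            se_read("r", start=100 - 35, strand="-"),  # same span, - strand
        ]
        flagged, dedup = rf.mark_duplicates(reads)
        assert len(dedup) == 2

    def test_pe_identical_outer_coordinates_collapse(self):
        pairs = [pe_pair("p1", left=100, insert=200), pe_pair("p2", left=100, insert=200)]
        _, dedup = rf.mark_duplicates(pairs)
        assert len(dedup) == 1

    def test_representative_has_highest_mapq(self):
        reads = [se_read("low", start=100, mapq=10), se_read("high", start=100, mapq=60)]
        _, dedup = rf.mark_duplicates(reads)
        assert dedup[0].query_name == "high"

    def test_idempotent(self):
        reads = [se_read(f"r{i}", start=100 * (i % 3)) for i in range(9)]
        flagged1, dedup1 = rf.mark_duplicates(reads)
        flagged2, dedup2 = rf.mark_duplicates(flagged1)
        assert [(r.query_name, r.is_duplicate) for r in flagged1] == [
            (r.query_name, r.is_duplicate) for r in flagged2
        ]
        assert [r.query_name for r in dedup1] == [r.query_name for r in dedup2]

    @given(
        positions=hst.lists(
            hst.tuples(
                hst.integers(0, 50),  # start (small range forces collisions)
                hst.sampled_from("+-"),
                hst.integers(0, 60),
            ),
            max_size=200,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_key_comparison(self, positions):
        """Duplicate sets agree with an all-pairs key comparison oracle."""
        reads = [
            se_read(f"r{i}", start=pos, strand=strand, mapq=mapq)
            for i, (pos, strand, mapq) in enumerate(positions)
        ]
        flagged, dedup = rf.mark_duplicates(reads)
        # oracle: two reads are duplicates iff (chrom, 5', strand) matches
        def key(r):
            return (r.chrom, r.start if r.strand == "+" else r.end, r.strand)

        groups = {}
        for r in reads:
            groups.setdefault(key(r), []).append(r)
        expected_dups = sum(len(g) - 1 for g in groups.values())
        assert sum(r.is_duplicate for r in flagged) == expected_dups
        assert len(dedup) == len(groups)
        # every flagged duplicate shares its key with its group's survivor
        for a, b in itertools.combinations(flagged, 2):
            if key(a) == key(b):
                assert a.is_duplicate or b.is_duplicate


class TestLibraryComplexity:
    def test_table_counts_give_24_pct_duplicates(self):
        report = rf.library_complexity(22_270_000, 16_900_000)
        assert report.complexity == pytest.approx(0.759, abs=0.001)
        assert report.duplicate_pct == pytest.approx(24.1, abs=0.1)
        assert not report.guideline_flag

    def test_no_duplicates_is_full_complexity(self):
        report = rf.library_complexity(1000, 1000)
        assert report.complexity == 1.0
        assert report.guideline_flag

    def test_all_identical_reads(self):
        report = rf.library_complexity(50, 1)
        assert report.complexity == pytest.approx(1 / 50)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rf.library_complexity(0, 0)
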