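"""Fold-change filtering, top-peak selection, set overlap (with the
brute-force oracle), peak-to-gene assignment and centered windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from peakforge import peak_tools as pt
from peakforge.genomic_io import GenomeTable, Peak

from conftest import peak


class TestFoldChangeFilter:
    def test_threshold_is_inclusive(self):
        peaks = [
            peak(start=0, end=10, fold_change=3.0),
            peak(start=20, end=30, fold_change=1.9),
            peak(start=40, end=50, fold_change=2.0),
        ]
        kept = pt.fold_change_filter(peaks)
        assert [p.fold_change for p in kept] == [3.0, 2.0]

    def test_pseudocount_fallback_for_zero_control(self):
        p = peak(start=0, end=10, ip_count=30.0, ctrl_count=0.0)
        assert pt.fold_change_filter([p], ip_total=1000, ctrl_total=1000) == [p]

    def test_missing_everything_raises(self):
        with pytest.raises(ValueError, match="neither"):
            pt.fold_change_filter([peak(start=0, end=10)])

    def test_idempotent_subset(self):
        peaks = [peak(start=10 * i, end=10 * i + 5, fold_change=float(i)) for i in range(1, 9)]
        once = pt.fold_change_filter(peaks)
        twice = pt.fold_change_filter(once)
        assert twice == once
        assert set(p.interval() for p in once) <= set(p.interval() for p in peaks)


class TestSelectTopPeaks:
    def make(self, scores):
        return [
            peak(start=100 * i, end=100 * i + 50, neg_log10_p=s)
            for i, s in enumerate(scores)
        ]

    def test_top_fraction_takes_largest_scores(self):
        peaks = self.make(range(20))
        top = pt.select_top_peaks(peaks, "fraction", 0.1)
        assert sorted(p.neg_log10_p for p in top) == [18, 19]

    def test_score_cutoff(self):
        peaks = self.make([2.0, 5.0, 7.5])
        selected = pt.select_top_peaks(peaks, "score_cutoff", 5.0)
        assert sorted(p.neg_log10_p for p in selected) == [5.0, 7.5]

    def test_ties_broken_by_coordinate(self):
        peaks = self.make([1.0, 1.0, 1.0, 1.0])
        top = pt.select_top_peaks(peaks, "fraction", 0.5)
        assert [p.start for p in top] == [0, 100]

    def test_no_score_field_raises(self):
        with pytest.raises(ValueError, match="score"):
            pt.select_top_peaks([peak(start=0, end=10)], "fraction", 0.5)


class TestComparePeakSets:
    def test_one_of_two_overlapped(self):
        a = [peak(start=0, end=100), peak(start=200, end=300)]
        b = [peak(start=50, end=80)]
        report = pt.compare_peak_sets(a, b)
        assert (report.overlapped_a, report.unique_a) == (1, 1)
        assert report.pct_overlap_a == pytest.approx(50.0)
        assert report.pct_overlap_b == pytest.approx(100.0)

    def test_identical_sets_fully_overlap(self):
        a = [peak(start=10 * i, end=10 * i + 5) for i in range(10)]
        report = pt.compare_peak_sets(a, list(a))
        assert report.pct_overlap_a == report.pct_overlap_b == 100.0

    def test_adjacent_intervals_do_not_overlap(self):
        a = [peak(start=0, end=100)]
        b = [peak(start=100, end=200)]
        assert pt.compare_peak_sets(a, b).overlapped_a == 0

    @given(seed=hst.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def random_set(n):
            out = []
            for _ in range(n):
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                start = int(rng.integers(0, 5000))
                out.append(peak(chrom=chrom, start=start, end=start + int(rng.integers(1, 300))))
            return out

        a, b = random_set(int(rng.integers(1, 120))), random_set(int(rng.integers(1, 120)))
        report = pt.compare_peak_sets(a, b)
        brute_a = sum(
            1
            for p in a
            if any(p.chrom == q.chrom and p.start < q.end and q.start < p.end for q in b)
        )
        brute_b = sum(
            1
            for q in b
            if any(p.chrom == q.chrom and p.start < q.end and q.start < p.end for p in a)
        )
        assert (report.overlapped_a, report.overlapped_b) == (brute_a, brute_b)


class TestAssignPeaksToGenes:
    @pytest.fixture
    def genes(self):
        return [
            pt.GeneModel("gA", "chr1", 20_000, 25_000, "+"),
            pt.GeneModel("gB", "chr1", 40_000, 35_000, "-"),
        ]

    def test_within_10kb_assigned(self, genes):
        p = peak(start=10_950, end=11_050)  # center 11 000, 9 kb from gA TSS
        records = pt.assign_peaks_to_genes([p], genes)
        assert [r.gene_id for r in records] == ["gA"]
        assert records[0].anchor == "TSS"
        assert records[0].distance == 9_000

    def test_beyond_cutoff_not_assigned(self, genes):
        p = peak(chrom="chr1", start=90_000, end=90_100)
        assert pt.assign_peaks_to_genes([p], genes) == []

    def test_two_genes_nearest_flagged(self):
        genes = [
            pt.GeneModel("near", "chr1", 12_000, 20_000, "+"),
            pt.GeneModel("far", "chr1", 15_000, 21_000, "+"),
        ]
        p = peak(start=9_950, end=10_050)  # center 10 000: 2 kb and 5 kb
        records = pt.assign_peaks_to_genes([p], genes)
        assert {r.gene_id: r.is_closest for r in records} == {"near": True, "far": False}

    def test_equidistant_tie_flags_both(self):
        genes = [
            pt.GeneModel("left", "chr1", 8_000, 2_000, "-"),
            pt.GeneModel("right", "chr1", 12_000, 18_000, "+"),
        ]
        p = peak(start=9_950, end=10_050)
        records = pt.assign_peaks_to_genes([p], genes)
        assert all(r.is_closest for r in records)
        assert [r.gene_id for r in records] == ["left", "right"]

    def test_stored_distance_recomputable(self, genes):
        p = peak(start=30_500, end=30_700)
        for r in pt.assign_peaks_to_genes([p], genes):
            center = (r.peak_start + r.peak_end) // 2
            gene = {g.id: g for g in genes}[r.gene_id]
            anchor_coord = gene.tss if r.anchor == "TSS" else gene.tes
            assert r.distance == anchor_coord - center

    def test_empty_gene_list_warns(self):
        with pytest.warns(UserWarning, match="empty gene list"):
            assert pt.assign_peaks_to_genes([peak(start=0, end=10)], []) == []


class TestCenterWindows:
    def test_centered_window(self):
        assert pt.center_windows([peak(start=100, end=300)], 100) == [("chr1", 150, 250)]

    def test_clipped_at_chromosome_start(self):
        assert pt.center_windows([peak(start=0, end=10)], 100) == [("chr1", 0, 55)]

    def test_unclipped_windows_have_exact_width(self):
        windows = pt.center_windows(
            [peak(start=s, end=s + 33) for s in (100, 1234, 9_000)], 100
        )
        assert all(e - s == 100 for _, s, e in windows)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            pt.center_windows([peak(start=0, end=10)], 99)


class TestGeneIO:
    def test_bed_round_trip_preserves_anchors(self, tmp_path):
        genes = [
            pt.GeneModel("gA", "chr1", 100, 500, "+"),
            pt.GeneModel("gB", "chr1", 900, 600, "-"),
        ]
        path = tmp_path / "genes.bed"
        pt.write_genes(genes, path)
        assert pt.read_genes(path) == genes
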