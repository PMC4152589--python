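"""Format round-trips and coordinate conventions at the I/O boundary."""

import pytest

from peakforge import genomic_io as gio
from peakforge import signal_tracks as st

from conftest import pe_pair, se_read


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:5000\n"


def write_sam_text(tmp_path, body, name="in.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + body)
    return path


class TestReadSam:
    def test_pos_converted_to_zero_based(self, tmp_path):
        path = write_sam_text(
            tmp_path, "r1\t0\tchr1\t1\t60\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\n"
        )
        (read,) = list(gio.read_sam(path))
        assert (read.start, read.end) == (0, 36)
        assert read.strand == "+"

    def test_flag_99_decodes_proper_first_forward(self, tmp_path):
        path = write_sam_text(
            tmp_path, "r1\t99\tchr1\t101\t60\t36M\t=\t265\t200\t*\t*\n"
        )
        (read,) = list(gio.read_sam(path))
        assert read.is_paired and read.is_proper and read.is_first
        assert read.strand == "+"
        assert read.start == 100

    def test_unmapped_kept_and_flagged(self, tmp_path):
        path = write_sam_text(tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        (read,) = list(gio.read_sam(path))
        assert read.is_unmapped
        assert read.chrom is None

    def test_write_read_round_trip_preserves_coordinates(self, tmp_path, genome):
        reads = [
            se_read("a", start=0, strand="+"),
            se_read("b", start=500, strand="-", mapq=0),
            se_read("c", chrom="chr2", start=4000, strand="+", mapq=13),
        ]
        path = tmp_path / "rt.sam"
        gio.write_sam(reads, path, genome)
        back = list(gio.read_sam(path))
        assert [(r.query_name, r.chrom, r.start, r.end, r.strand, r.mapq) for r in back] == [
            (r.query_name, r.chrom, r.start, r.end, r.strand, r.mapq) for r in reads
        ]

    def test_genome_table_from_header(self, tmp_path):
        path = write_sam_text(tmp_path, "")
        table = gio.sam_genome_table(path)
        assert table == {"chr1": 10_000, "chr2": 5_000}

    def test_missing_sq_header_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@HD\tVN:1.6\n")
        with pytest.raises(gio.SamFormatError):
            gio.sam_genome_table(path)


class TestPairReads:
    def test_pairs_by_query_name(self):
        pair = pe_pair("p1")
        (rebuilt,) = gio.pair_reads([pair.second, pair.first])
        assert rebuilt.first.is_first
        assert rebuilt.query_name == "p1"

    def test_orphan_read_raises(self):
        pair = pe_pair("p1")
        with pytest.raises(ValueError, match="without mates"):
            gio.pair_reads([pair.first])

    @pytest.mark.parametrize("orientation", ["FR", "RF", "FF", "RR"])
    def test_orientation_derived_from_strands(self, orientation):
        assert pe_pair("p", orientation=orientation).orientation == orientation

    def test_cross_chromosome_orientation(self):
        pair = pe_pair("p")
        moved = gio.AlignedRead(
            "p", "chr2", 100, 136, "-", 60, pair.second.flags, tlen=0
        )
        assert gio.ReadPair(pair.first, moved).orientation == "cross-chrom"


class TestPeakDialects:
    def test_encodepeak_fields(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t300\tpeak_1\t53\t.\t4.2\t5.30103\t3.1\t100\n")
        (p,) = gio.read_peaks(path, "encodePeak")
        assert p.neg_log10_p == pytest.approx(5.30103)
        assert p.fold_change == pytest.approx(4.2)
        assert p.idr is None  # non-numeric name

    def test_encodepeak_numeric_name_is_idr(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t300\t0.005\t53\t.\t4.2\t5.3\t3.1\t100\n")
        (p,) = gio.read_peaks(path, "encodePeak")
        assert p.idr == pytest.approx(0.005)

    def test_sicer_summary_fields(self, tmp_path):
        path = tmp_path / "islands.tsv"
        path.write_text("chr1\t1000\t4000\t150\t40\t1e-10\t1.5\t0.001\n")
        (p,) = gio.read_peaks(path, "sicer_summary")
        assert p.fold_change == pytest.approx(1.5)
        assert p.ip_count == 150
        assert p.neg_log10_fdr == pytest.approx(3.0)

    def test_bed3_minimal(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t10\t20\n")
        (p,) = gio.read_peaks(path, "bed")
        assert p.strand == "."
        assert p.neg_log10_p is None

    def test_column_count_mismatch_raises(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t10\t20\tx\t0\t.\n")
        with pytest.raises(gio.PeakFormatError, match="10 columns"):
            gio.read_peaks(path, "encodePeak")

    def test_non_numeric_score_raises(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t300\tx\tNA\t.\t4.2\t5.3\t3.1\t100\n")
        with pytest.raises(gio.PeakFormatError, match="score"):
            gio.read_peaks(path, "encodePeak")

    def test_encodepeak_round_trip(self, tmp_path):
        peaks = [
            gio.Peak(
                chrom="chr1",
                start=10,
                end=400,
                name="a",
                score=10,
                strand=".",
                fold_change=3.0,
                neg_log10_p=8.5,
                neg_log10_fdr=6.5,
                idr=0.02,
                summit=195,
            )
        ]
        path = tmp_path / "out.narrowPeak"
        gio.write_peaks(peaks, path)
        (back,) = gio.read_peaks(path, "encodePeak")
        assert back.idr == pytest.approx(0.02)
        assert back.interval() == peaks[0].interval()


class TestTrackWriting:
    def test_single_interval_bedgraph_line(self, tmp_path, genome):
        track = st.CoverageTrack(genome=genome, runs={"chr1": [(0, 100, 4.0)]})
        path = tmp_path / "t.bedgraph"
        gio.write_track(track, path, "bedgraph")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["chr1\t0\t100\t4"]

    def test_wig_fixed_step_five_values(self, tmp_path, genome):
        track = st.CoverageTrack(genome=genome, runs={"chr1": [(0, 100, 4.0)]}, step=20)
        path = tmp_path / "t.wig"
        gio.write_track(track, path, "wig")
        lines = path.read_text().splitlines()
        assert "fixedStep chrom=chr1 start=1 step=20 span=20" in lines
        values = [l for l in lines if not l.startswith(("track", "fixedStep"))]
        assert values == ["4", "4", "4", "4", "4"]

    def test_empty_track_writes_header_only(self, tmp_path, genome):
        track = st.CoverageTrack(genome=genome)
        path = tmp_path / "t.bedgraph"
        gio.write_track(track, path, "bedgraph")
        assert path.read_text().startswith("track")
        assert len(path.read_text().splitlines()) == 1

    def test_bedgraph_round_trip(self, tmp_path, genome):
        runs = {"chr1": [(0, 50, 1.0), (50, 75, 3.0)], "chr2": [(10, 20, 2.5)]}
        track = st.CoverageTrack(genome=genome, runs=runs)
        path = tmp_path / "t.bedgraph"
        gio.write_track(track, path, "bedgraph")
        back = st.read_bedgraph(path, genome)
        assert back.runs == runs

    def test_interval_beyond_chromosome_raises(self, tmp_path, genome):
        bad = tmp_path / "bad.bedgraph"
        bad.write_text("chr2\t4000\t6000\t1\n")
        with pytest.raises(ValueError, match="chr2"):
            st.read_bedgraph(bad, genome)


class TestFetchSequence:
    @pytest.fixture
    def fasta(self, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(">chrA\nacgtacgt\n")
        return path

    def test_subsequence_uppercased(self, fasta):
        assert gio.fetch_sequence(fasta, "chrA", 2, 6) == "GTAC"

    def test_empty_interval(self, fasta):
        assert gio.fetch_sequence(fasta, "chrA", 0, 0) == ""

    def test_beyond_contig_end_raises(self, fasta):
        with pytest.raises(ValueError, match="outside contig"):
            gio.fetch_sequence(fasta, "chrA", 4, 12)

    def test_unknown_chrom_raises(self, fasta):
        with pytest.raises(KeyError):
            gio.fetch_sequence(fasta, "chrB", 0, 4)
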