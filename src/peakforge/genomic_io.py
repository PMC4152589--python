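"""Readers and writers for the genomic file formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (BED convention);
the only conversion happens at the SAM boundary, where pysam already maps
the 1-based POS field onto ``reference_start``.  Peak files come in three
dialects: MACS ``encodePeak`` (narrowPeak, BED6+4), the SICER island
summary table, and plain BED3/6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from pyfaidx import Fasta

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_DUP = 0x400


class SamFormatError(ValueError):
    """Raised when a SAM file cannot be parsed or lacks required header."""


class PeakFormatError(ValueError):
    """Raised when a peak file does not match its declared dialect."""


@dataclass(frozen=True)
class AlignedRead:
    """One mapped (or unmapped) read with 0-based half-open coordinates.

    ``mapq == 0`` conventionally marks a multi-mapping placement: BWA and
    Novoalign both assign zero mapping quality when a read has several
    equally good locations, so downstream filters treat MAPQ 0 as
    "multi-mapped" throughout.
    """

    query_name: str
    chrom: str | None
    start: int
    end: int
    strand: str
    mapq: int
    flags: int
    tlen: int = 0
    seq: str | None = None

    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_first(self) -> bool:
        return bool(self.flags & FLAG_FIRST)

    @property
    def is_proper(self) -> bool:
        return bool(self.flags & FLAG_PROPER)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUP)

    @property
    def five_prime(self) -> int:
        """5' coordinate: alignment start on +, alignment end on −.

        On the minus strand the 5' base is the last covered position
        ``end - 1``; we keep the exclusive ``end`` here because duplicate
        keys only need a consistent per-strand anchor, and the exclusive
        bound survives coordinate arithmetic without off-by-one fixups.
        """
        return self.start if self.strand == "+" else self.end

    def with_flag(self, bit: int, on: bool = True) -> "AlignedRead":
        flags = self.flags | bit if on else self.flags & ~bit
        return replace(self, flags=flags)


@dataclass(frozen=True)
class ReadPair:
    """Two mates of a properly parsed read pair (not necessarily proper-pair).

    ``insert`` is |TLEN|; ``orientation`` is derived from the mates'
    strands in genomic order: FR is the expected innie configuration.
    """

    first: AlignedRead
    second: AlignedRead

    def __post_init__(self) -> None:
        if self.first.query_name != self.second.query_name:
            raise ValueError(
                f"mates with different names: {self.first.query_name!r} "
                f"vs {self.second.query_name!r}"
            )

    @property
    def query_name(self) -> str:
        return self.first.query_name

    @property
    def insert(self) -> int:
        return abs(self.first.tlen)

    @property
    def orientation(self) -> str:
        if self.first.chrom != self.second.chrom:
            return "cross-chrom"
        left, right = sorted((self.first, self.second), key=lambda r: (r.start, r.end))
        combo = left.strand + right.strand
        return {"+-": "FR", "-+": "RF", "++": "FF", "--": "RR"}[combo]

    @property
    def chrom(self) -> str | None:
        return self.first.chrom

    @property
    def mates(self) -> tuple[AlignedRead, AlignedRead]:
        return (self.first, self.second)


@dataclass
class Peak:
    """A scored genomic interval from a peak caller.

    MACS peaks carry ``neg_log10_p`` (narrowPeak column 8); SICER islands
    carry ``neg_log10_fdr`` plus the raw IP/control window counts.  The
    encodePeak name column is dual-use: after IDR annotation it holds the
    numeric IDR value, which is mirrored into ``idr`` when parseable.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    fold_change: float | None = None
    neg_log10_p: float | None = None
    neg_log10_fdr: float | None = None
    idr: float | None = None
    ip_count: float | None = None
    ctrl_count: float | None = None
    summit: int = -1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peak interval {self.chrom}:{self.start}-{self.end}")
        if self.idr is not None and not (0.0 <= self.idr <= 1.0):
            raise ValueError(f"IDR {self.idr} outside [0, 1]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class GenomeTable(dict):
    """Ordered chromosome -> length (bp) mapping."""

    def __init__(self, items: dict[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(items)
        for chrom, length in self.items():
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {chrom}")

    @property
    def total_length(self) -> int:
        return sum(self.values())

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {self[chrom]})"
            )


def read_chrom_sizes(path: str | Path) -> GenomeTable:
    """Read a UCSC chrom.sizes table (chrom<TAB>length)."""
    table = GenomeTable()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            table[chrom] = int(length)
    return table


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _read_from_segment(seg: pysam.AlignedSegment) -> AlignedRead:
    if seg.is_unmapped:
        return AlignedRead(
            query_name=seg.query_name or "",
            chrom=None,
            start=-1,
            end=-1,
            strand=".",
            mapq=seg.mapping_quality,
            flags=seg.flag,
            tlen=seg.template_length,
        )
    return AlignedRead(
        query_name=seg.query_name or "",
        chrom=seg.reference_name,
        start=seg.reference_start,
        end=seg.reference_end,
        strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
        flags=seg.flag,
        tlen=seg.template_length,
    )


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM (or BAM) file.

    Unmapped records are yielded with ``is_unmapped`` set rather than
    dropped, so callers can account for them in mapping summaries.
    """
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for i, seg in enumerate(fh, start=1):
                try:
                    yield _read_from_segment(seg)
                except ValueError as exc:  # pragma: no cover - defensive
                    raise SamFormatError(f"{path}: record {i}: {exc}") from exc
    except ValueError as exc:
        raise SamFormatError(f"{path}: {exc}") from exc


def sam_genome_table(path: str | Path) -> GenomeTable:
    """Extract the chromosome table from the @SQ header lines."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if not fh.references:
            raise SamFormatError(f"{path}: no @SQ header lines")
        return GenomeTable(zip(fh.references, fh.lengths))


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    genome: GenomeTable,
    read_length: int | None = None,
) -> int:
    """Write AlignedRead records as a minimal SAM file; returns record count.

    The CIGAR is reconstructed as a single match run covering
    ``end - start``; sequences are emitted when present, otherwise '*'.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in genome.items()],
        }
    )
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.query_name
            seg.flag = read.flags
            seg.mapping_quality = read.mapq
            seg.template_length = read.tlen
            if read.chrom is not None and not read.is_unmapped:
                genome.check_interval(read.chrom, read.start, read.end)
                seg.reference_name = read.chrom
                seg.reference_start = read.start
                span = read.end - read.start
                seg.cigarstring = f"{span}M"
                seg.query_sequence = read.seq if read.seq else "N" * span
                seg.query_qualities = pysam.qualitystring_to_array("I" * span)
                if read.is_paired:
                    seg.next_reference_name = read.chrom
            n += 1
            out.write(seg)
    return n


def pair_reads(reads: Iterable[AlignedRead]) -> list[ReadPair]:
    """Group mapped paired-end reads into ReadPair objects by query name.

    Reads whose mate never appears (or appears more than twice) raise,
    since every pair filter downstream assumes pairing integrity.
    """
    pending: dict[str, AlignedRead] = {}
    pairs: list[ReadPair] = []
    for read in reads:
        if not read.is_paired:
            raise ValueError(f"unpaired read {read.query_name!r} in pair stream")
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
        else:
            first, second = (mate, read) if mate.is_first else (read, mate)
            pairs.append(ReadPair(first, second))
    if pending:
        name = next(iter(pending))
        raise ValueError(f"{len(pending)} reads without mates (e.g. {name!r})")
    return pairs


# ---------------------------------------------------------------------------
# Peak files
# ---------------------------------------------------------------------------

DIALECTS = ("encodePeak", "sicer_summary", "bed")


def _parse_float(token: str, path, lineno, what) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise PeakFormatError(f"{path}:{lineno}: non-numeric {what}: {token!r}") from exc


def read_peaks(path: str | Path, dialect: str = "encodePeak") -> list[Peak]:
    """Read a peak file in one of the supported dialects.

    encodePeak (narrowPeak, 10 cols): chrom start end name score strand
    signalValue(fold) -log10(p) -log10(q) summit.  Column 4 may carry an
    IDR value after annotation; numeric names are mirrored into ``idr``.

    sicer_summary (8 cols): chrom start end ip_count control_count p
    fold_change FDR.

    bed: first 3-6 columns.
    """
    if dialect not in DIALECTS:
        raise PeakFormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            peaks.append(_parse_peak_row(cols, dialect, path, lineno))
    return peaks


def _parse_peak_row(cols: Sequence[str], dialect: str, path, lineno) -> Peak:
    if dialect == "encodePeak":
        if len(cols) != 10:
            raise PeakFormatError(
                f"{path}:{lineno}: encodePeak needs 10 columns, got {len(cols)}"
            )
        name = cols[3]
        idr = None
        try:
            value = float(name)
            if 0.0 <= value <= 1.0:
                idr = value
        except ValueError:
            pass
        return Peak(
            chrom=cols[0],
            start=int(cols[1]),
            end=int(cols[2]),
            name=name,
            score=_parse_float(cols[4], path, lineno, "score"),
            strand=cols[5],
            fold_change=_parse_float(cols[6], path, lineno, "fold change"),
            neg_log10_p=_parse_float(cols[7], path, lineno, "-log10 p"),
            neg_log10_fdr=_parse_float(cols[8], path, lineno, "-log10 q"),
            idr=idr,
            summit=int(cols[9]),
        )
    if dialect == "sicer_summary":
        if len(cols) != 8:
            raise PeakFormatError(
                f"{path}:{lineno}: SICER summary needs 8 columns, got {len(cols)}"
            )
        fdr = _parse_float(cols[7], path, lineno, "FDR")
        return Peak(
            chrom=cols[0],
            start=int(cols[1]),
            end=int(cols[2]),
            ip_count=_parse_float(cols[3], path, lineno, "IP count"),
            ctrl_count=_parse_float(cols[4], path, lineno, "control count"),
            fold_change=_parse_float(cols[6], path, lineno, "fold change"),
            neg_log10_fdr=-math.log10(fdr) if fdr > 0 else 323.0,
        )
    # bed
    if not 3 <= len(cols) <= 6:
        raise PeakFormatError(f"{path}:{lineno}: BED needs 3-6 columns, got {len(cols)}")
    return Peak(
        chrom=cols[0],
        start=int(cols[1]),
        end=int(cols[2]),
        name=cols[3] if len(cols) > 3 else ".",
        score=_parse_float(cols[4], path, lineno, "score") if len(cols) > 4 else 0.0,
        strand=cols[5] if len(cols) > 5 else ".",
    )


def _fmt(value: float | None, default: str = "-1") -> str:
    if value is None:
        return default
    return f"{value:g}"


def write_peaks(
    peaks: Iterable[Peak], path: str | Path, dialect: str = "encodePeak"
) -> None:
    """Write peaks back out; encodePeak puts the IDR value in column 4
    when present (the annotated-file convention), the name otherwise."""
    if dialect not in ("encodePeak", "bed"):
        raise PeakFormatError(f"cannot write dialect {dialect!r}")
    with open(path, "w") as out:
        for p in peaks:
            if dialect == "encodePeak":
                col4 = f"{p.idr:g}" if p.idr is not None else p.name
                out.write(
                    "\t".join(
                        [
                            p.chrom,
                            str(p.start),
                            str(p.end),
                            col4,
                            f"{p.score:g}",
                            p.strand,
                            _fmt(p.fold_change, "0"),
                            _fmt(p.neg_log10_p),
                            _fmt(p.neg_log10_fdr),
                            str(p.summit),
                        ]
                    )
                    + "\n"
                )
            else:
                out.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n"
                )


def write_track(track, path: str | Path, format: str = "bedgraph") -> None:
    """Write a CoverageTrack as bedGraph or fixedStep Wig.

    Thin delegation kept here so every on-disk format has a single home;
    the run-length encoding itself lives in :mod:`peakforge.signal_tracks`.
    """
    from peakforge import signal_tracks

    signal_tracks.write_track(track, path, format=format)


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------

def fetch_sequence(fasta_path: str | Path, chrom: str, start: int, end: int) -> str:
    """Fetch the uppercased sequence of [start, end) from a FASTA file.

    No reverse-complementing: strand handling belongs to the caller.
    """
    if end < start:
        raise ValueError(f"inverted interval [{start}, {end})")
    fasta = Fasta(str(fasta_path), rebuild=False)
    try:
        record = fasta[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in {fasta_path}") from exc
    if start < 0 or end > len(record):
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside contig (length {len(record)})"
        )
    if start == end:
        return ""
    return record[start:end].seq.upper()
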