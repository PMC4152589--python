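"""Extended-fragment coverage tracks: bedGraph, fixedStep Wig, per-million.

Single-end reads are extended to the average fragment length of the
library (default 200 bp) from their 5' end; paired-end reads contribute
one fragment per pair spanning the observed insert, so fragment length
varies per pair instead of using a library average.  Coverage is stored
run-length encoded; normalization scales to a library of one million
mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from peakforge.genomic_io import AlignedRead, GenomeTable, ReadPair

DEFAULT_FRAGMENT_LENGTH = 200
DEFAULT_WIG_STEP = 20

Run = tuple[int, int, float]  # start, end, value
Fragment = tuple[str, int, int, str]  # chrom, start, end, strand


@dataclass
class CoverageTrack:
    """Run-length encoded per-base signal over a genome.

    ``runs`` maps chromosome -> sorted non-overlapping (start, end, value)
    triples with value > 0; uncovered stretches are implicit zeros.
    """

    genome: GenomeTable
    runs: dict[str, list[Run]] = field(default_factory=dict)
    step: int = DEFAULT_WIG_STEP
    normalized: bool = False
    library_size: int | None = None

    def total_signal(self) -> float:
        """Sum of value x run-length over the whole track."""
        return sum(
            (e - s) * v for runs in self.runs.values() for s, e, v in runs
        )

    def values_per_base(self, chrom: str) -> np.ndarray:
        """Materialize the per-base value array for one chromosome."""
        arr = np.zeros(self.genome[chrom], dtype=float)
        for s, e, v in self.runs.get(chrom, []):
            arr[s:e] = v
        return arr


def extend_single_end(
    read: AlignedRead, fragment_length: int, genome: GenomeTable
) -> Fragment:
    """Extend a single-end read to the fragment length from its 5' end,
    clipped to the chromosome."""
    if read.is_unmapped or read.chrom is None:
        raise ValueError(f"cannot extend unmapped read {read.query_name!r}")
    chrom_len = genome[read.chrom]
    if read.strand == "+":
        start, end = read.start, read.start + fragment_length
    else:
        start, end = read.end - fragment_length, read.end
    return (read.chrom, max(0, start), min(chrom_len, end), read.strand)


def fragment_from_pair(pair: ReadPair) -> Fragment:
    """One fragment per proper pair: [leftmost 5', leftmost 5' + |TLEN|)."""
    if pair.insert == 0:
        raise ValueError(
            f"pair {pair.query_name!r} has TLEN 0; proper-pair filter was skipped?"
        )
    left = min(pair.first.start, pair.second.start)
    return (pair.first.chrom, left, left + pair.insert, "+")


def fragments_from_reads(
    records: Sequence[AlignedRead] | Sequence[ReadPair],
    genome: GenomeTable,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> list[Fragment]:
    """Extend a filtered read/pair stream into coverage fragments."""
    frags = []
    for rec in records:
        if isinstance(rec, ReadPair):
            chrom, start, end, strand = fragment_from_pair(rec)
            frags.append((chrom, max(0, start), min(genome[chrom], end), strand))
        else:
            frags.append(extend_single_end(rec, fragment_length, genome))
    return frags


def coverage_from_fragments(
    fragments: Iterable[Fragment], genome: GenomeTable
) -> CoverageTrack:
    """Count fragments per base and encode maximal constant runs.

    Uses an event (difference) array per chromosome: +1 at each fragment
    start, -1 at each end, cumulative sum, then boundaries wherever the
    value changes.
    """
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for chrom, start, end, _strand in fragments:
        genome.check_interval(chrom, start, end)
        starts.setdefault(chrom, []).append(start)
        ends.setdefault(chrom, []).append(end)

    track = CoverageTrack(genome=genome)
    for chrom in starts:
        length = genome[chrom]
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, np.asarray(starts[chrom]), 1)
        np.add.at(diff, np.asarray(ends[chrom]), -1)
        depth = np.cumsum(diff)[:length]
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        edges = np.concatenate(([0], boundaries, [length]))
        runs = [
            (int(s), int(e), float(depth[s]))
            for s, e in zip(edges[:-1], edges[1:])
            if depth[s] > 0
        ]
        if runs:
            track.runs[chrom] = runs
    return track


def normalize_per_million(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale every value by 1e6 / library_size (reads-per-million)."""
    if track.normalized:
        raise ValueError("track is already normalized")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    scale = 1e6 / library_size
    runs = {
        chrom: [(s, e, v * scale) for s, e, v in chrom_runs]
        for chrom, chrom_runs in track.runs.items()
    }
    return CoverageTrack(
        genome=track.genome,
        runs=runs,
        step=track.step,
        normalized=True,
        library_size=library_size,
    )


def wig_steps(
    track: CoverageTrack, step: int = DEFAULT_WIG_STEP, sample: str = "mean"
) -> dict[str, np.ndarray]:
    """Aggregate per-base coverage into fixedStep windows per chromosome.

    The window value is the mean per-base coverage over the window
    (``sample="start"`` takes the window's first base instead); a trailing
    partial window is averaged over its true width.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if sample not in ("mean", "start"):
        raise ValueError(f"unknown sampling mode {sample!r}")
    out: dict[str, np.ndarray] = {}
    for chrom in track.runs:
        if not track.runs[chrom]:
            continue
        # report only up to the last covered base: trailing zero windows
        # are omitted (they are implicit in the format)
        covered_end = max(e for _s, e, _v in track.runs[chrom])
        limit = min(track.genome[chrom], -(-covered_end // step) * step)
        arr = track.values_per_base(chrom)[:limit]
        if sample == "start":
            out[chrom] = arr[::step].copy()
            continue
        idx = np.arange(0, limit, step)
        sums = np.add.reduceat(arr, idx)
        widths = np.minimum(idx + step, limit) - idx
        out[chrom] = sums / widths
    return out


def write_track(track: CoverageTrack, path: str | Path, format: str = "bedgraph") -> None:
    """Write bedGraph (zero runs omitted) or fixedStep Wig (span = step)."""
    if format == "bedgraph":
        with open(path, "w") as out:
            out.write('track type=bedGraph name="peakforge coverage"\n')
            for chrom in track.runs:
                for s, e, v in track.runs[chrom]:
                    out.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    elif format == "wig":
        step = track.step
        with open(path, "w") as out:
            out.write('track type=wiggle_0 name="peakforge coverage"\n')
            for chrom, values in wig_steps(track, step).items():
                # fixedStep start is 1-based in the Wig spec
                out.write(f"fixedStep chrom={chrom} start=1 step={step} span={step}\n")
                for v in values:
                    out.write(f"{v:g}\n")
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_bedgraph(path: str | Path, genome: GenomeTable) -> CoverageTrack:
    """Re-read a bedGraph written by write_track (round-trip support)."""
    track = CoverageTrack(genome=genome)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split()
            genome.check_interval(chrom, int(start), int(end))
            track.runs.setdefault(chrom, []).append(
                (int(start), int(end), float(value))
            )
    for runs in track.runs.values():
        runs.sort()
    return track


def track_from_records(
    records,
    genome: GenomeTable,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    step: int = DEFAULT_WIG_STEP,
    normalize: bool = False,
) -> CoverageTrack:
    """Convenience: reads/pairs -> fragments -> coverage (-> per-million).

    The library size used for normalization is the number of records the
    track was built from (post-filter counts).
    """
    records = list(records)
    frags = fragments_from_reads(records, genome, fragment_length)
    track = coverage_from_fragments(frags, genome)
    track.step = step
    track.library_size = len(records)
    if normalize:
        track = normalize_per_million(track, len(records))
        track.step = step
    return track
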