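"""Duplicate-distribution diagnostics.

Two analyses that distinguish punctate transcription-factor libraries
from broad histone-mark libraries: (1) duplicate rates inside peak
regions versus the non-peak background (the complement of peaks padded
by 100 bp on each side), and (2) the duplicate rate stratified by
peak-confidence decile.  In TF data duplicates concentrate in the
strongest peaks; in broad-mark data the rate is flat and close to the
background level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from peakforge.genomic_io import AlignedRead, GenomeTable, Peak, ReadPair
from peakforge.go_enrichment import merge_intervals
from peakforge.peak_tools import rank_peaks

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class RegionDupStats:
    """Duplicate bookkeeping for one region class (Table-style row)."""

    region_class: str
    span: int  # union length in bp
    non_duplicates: int
    duplicates: int
    total_duplicates: int  # library-wide, for the portion column

    @property
    def sum(self) -> int:
        return self.non_duplicates + self.duplicates

    @property
    def dup_pct(self) -> float:
        return duplicate_percentage(self.duplicates, self.sum)

    @property
    def portion_pct(self) -> float:
        if self.total_duplicates == 0:
            return 0.0
        return 100.0 * self.duplicates / self.total_duplicates


def duplicate_percentage(duplicates: float, total: float) -> float:
    """Duplicates as a percentage of all reads in a region (0 if empty)."""
    if total <= 0:
        return 0.0
    return 100.0 * duplicates / total


@dataclass(frozen=True)
class DecileProfile:
    """Per-confidence-group duplicate rates, strongest peaks first."""

    group_peak_counts: tuple[int, ...]
    group_duplicates: tuple[int, ...]
    group_totals: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_peak_counts)

    @property
    def dup_pcts(self) -> tuple[float, ...]:
        return tuple(
            duplicate_percentage(d, t)
            for d, t in zip(self.group_duplicates, self.group_totals)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": range(1, self.n_groups + 1),
                "peaks": self.group_peak_counts,
                "duplicates": self.group_duplicates,
                "total_reads": self.group_totals,
                "dup_pct": self.dup_pcts,
            }
        )


def _five_prime(rec: AlignedRead | ReadPair) -> tuple[str, int]:
    if isinstance(rec, ReadPair):
        left = min(rec.first.start, rec.second.start)
        return (rec.first.chrom, left)
    return (rec.chrom, rec.five_prime if rec.strand == "+" else rec.end - 1)


def _is_dup(rec: AlignedRead | ReadPair) -> bool:
    if isinstance(rec, ReadPair):
        return rec.first.is_duplicate
    return rec.is_duplicate


def merged_by_chrom(regions: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    return {c: merge_intervals(v) for c, v in by_chrom.items()}


def nonpeak_complement(
    peaks: Sequence[Peak], genome: GenomeTable, pad: int = 100
) -> list[Interval]:
    """Complement of the union of peaks padded by ``pad`` bp on each side."""
    padded = merged_by_chrom(
        (p.chrom, max(0, p.start - pad), min(genome[p.chrom], p.end + pad))
        for p in peaks
    )
    complement: list[Interval] = []
    for chrom, length in genome.items():
        cursor = 0
        for start, end in padded.get(chrom, []):
            if start > cursor:
                complement.append((chrom, cursor, start))
            cursor = max(cursor, end)
        if cursor < length:
            complement.append((chrom, cursor, length))
    return complement


def _point_in(merged: dict[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
    for start, end in merged.get(chrom, []):
        if start <= pos < end:
            return True
        if start > pos:
            break
    return False


def region_dup_stats(
    records: Sequence[AlignedRead] | Sequence[ReadPair],
    regions: Sequence[Interval],
    total_duplicates: int | None = None,
    region_class: str = "region",
) -> RegionDupStats:
    """Duplicate statistics for reads whose 5' position lies in ``regions``.

    Records must carry duplicate flags from ``mark_duplicates``.  A read
    belongs to a region iff its 5' base (leftmost position for pairs)
    falls inside, so disjoint region classes partition the reads exactly.
    """
    merged = merged_by_chrom(regions)
    span = sum(e - s for ivs in merged.values() for s, e in ivs)
    dups = non_dups = 0
    total_dup_count = 0
    for rec in records:
        is_dup = _is_dup(rec)
        total_dup_count += is_dup
        chrom, pos = _five_prime(rec)
        if _point_in(merged, chrom, pos):
            if is_dup:
                dups += 1
            else:
                non_dups += 1
    return RegionDupStats(
        region_class=region_class,
        span=span,
        non_duplicates=non_dups,
        duplicates=dups,
        total_duplicates=(
            total_duplicates if total_duplicates is not None else total_dup_count
        ),
    )


def duplication_table(
    records: Sequence[AlignedRead] | Sequence[ReadPair],
    peaks: Sequence[Peak],
    genome: GenomeTable,
    top_fraction: float = 0.1,
    pad: int = 100,
    rank_by: str | None = None,
) -> list[RegionDupStats]:
    """Assemble the all-peaks / top-peaks / non-peak / total summary.

    The non-peak class excludes peaks plus their ±pad bp buffer, so reads
    falling in the buffer belong to neither peak nor non-peak rows; the
    total row covers the whole library.
    """
    from math import ceil

    total_dups = sum(_is_dup(r) for r in records)
    all_iv = [(p.chrom, p.start, p.end) for p in peaks]
    ranked = rank_peaks(peaks, rank_by)
    top = ranked[: ceil(top_fraction * len(ranked))]
    top_iv = [(p.chrom, p.start, p.end) for p in top]
    rows = [
        region_dup_stats(records, all_iv, total_dups, "all_peaks"),
        region_dup_stats(records, top_iv, total_dups, "top_peaks"),
        region_dup_stats(
            records, nonpeak_complement(peaks, genome, pad), total_dups, "non_peak"
        ),
        region_dup_stats(
            records,
            [(c, 0, length) for c, length in genome.items()],
            total_dups,
            "total",
        ),
    ]
    return rows


def group_sizes(n: int, n_groups: int) -> list[int]:
    """Near-equal split; earlier (higher-confidence) groups take the remainder."""
    base, rem = divmod(n, n_groups)
    return [base + (1 if i < rem else 0) for i in range(n_groups)]


def decile_profile(
    peaks: Sequence[Peak],
    records: Sequence[AlignedRead] | Sequence[ReadPair],
    rank_by: str = "neg_log10_p",
    n_groups: int = 10,
) -> DecileProfile:
    """Duplicate rate per peak-confidence group.

    Peaks are ranked by -log10 p (or -log10 FDR) descending, split into
    ``n_groups`` contiguous near-equal groups, and each flagged read is
    assigned to the highest-confidence group whose peaks contain its 5'
    position — so group totals partition the all-peak reads exactly.
    """
    if len(peaks) < n_groups:
        raise ValueError(
            f"{len(peaks)} peaks cannot fill {n_groups} groups; "
            "reduce the group count"
        )
    ranked = rank_peaks(peaks, rank_by)
    sizes = group_sizes(len(ranked), n_groups)
    group_intervals: list[dict[str, list[tuple[int, int]]]] = []
    counts = []
    offset = 0
    for size in sizes:
        chunk = ranked[offset : offset + size]
        offset += size
        counts.append(len(chunk))
        group_intervals.append(
            merged_by_chrom((p.chrom, p.start, p.end) for p in chunk)
        )
    dups = [0] * n_groups
    totals = [0] * n_groups
    for rec in records:
        chrom, pos = _five_prime(rec)
        for gi, merged in enumerate(group_intervals):
            if _point_in(merged, chrom, pos):
                totals[gi] += 1
                dups[gi] += _is_dup(rec)
                break
    return DecileProfile(tuple(counts), tuple(dups), tuple(totals))
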