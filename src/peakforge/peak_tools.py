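"""Peak-call post-processing: fold-change filtering, top-peak selection,
set comparison, peak-to-gene assignment and peak-centered windows.

Overlap throughout means sharing at least one base in half-open
arithmetic (``a.start < b.end and b.start < a.end``).  Peak-to-gene
distance is measured from the peak center to the gene's TSS or TES
anchors, with a default 10 kb cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from peakforge.genomic_io import GenomeTable, Peak


@dataclass(frozen=True)
class GeneModel:
    """Gene anchors: TSS is the 5' end (so tss > tes on the minus strand)."""

    id: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.id}: + strand needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.id}: - strand needs tss > tes")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


def read_genes(path) -> list[GeneModel]:
    """Read a BED6-like gene table: chrom start end id score strand.

    The TSS is taken at the strand-appropriate edge (start for +, end
    for -).
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split()
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            gid = cols[3] if len(cols) > 3 else f"{chrom}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 else "+"
            if strand == "+":
                genes.append(GeneModel(gid, chrom, start, end, "+"))
            else:
                genes.append(GeneModel(gid, chrom, end, start, "-"))
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


@dataclass(frozen=True)
class OverlapReport:
    """Two-way overlap bookkeeping between peak sets A and B."""

    n_a: int
    n_b: int
    overlapped_a: int
    overlapped_b: int

    @property
    def unique_a(self) -> int:
        return self.n_a - self.overlapped_a

    @property
    def unique_b(self) -> int:
        return self.n_b - self.overlapped_b

    @property
    def pct_overlap_a(self) -> float:
        return overlap_percentage(self.overlapped_a, self.n_a)

    @property
    def pct_overlap_b(self) -> float:
        return overlap_percentage(self.overlapped_b, self.n_b)


def overlap_percentage(overlapped: int, total: int) -> float:
    """Share of a peak set touched by another, as a percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * overlapped / total


@dataclass(frozen=True)
class AssignmentRecord:
    """One peak-to-gene association within the distance cutoff."""

    peak_chrom: str
    peak_start: int
    peak_end: int
    peak_name: str
    gene_id: str
    anchor: str  # TSS or TES
    distance: int  # signed: anchor coordinate minus peak center
    is_closest: bool


def fold_change_filter(
    peaks: Iterable[Peak],
    threshold: float = 2.0,
    ip_total: float | None = None,
    ctrl_total: float | None = None,
) -> list[Peak]:
    """Keep broad domains whose IP/control fold change is >= threshold.

    Peaks lacking a fold_change fall back to the normalized count ratio
    (ip/ip_total)/(ctrl/ctrl_total), with a pseudocount of 1 on the
    control count when it is zero.
    """
    kept = []
    for p in peaks:
        fc = p.fold_change
        if fc is None:
            if p.ip_count is None or p.ctrl_count is None:
                raise ValueError(
                    f"peak {p.chrom}:{p.start}-{p.end} has neither fold_change "
                    "nor IP/control counts"
                )
            it = ip_total if ip_total is not None else 1.0
            ct = ctrl_total if ctrl_total is not None else 1.0
            ctrl = p.ctrl_count if p.ctrl_count > 0 else 1.0
            fc = (p.ip_count / it) / (ctrl / ct)
        if fc >= threshold:
            kept.append(p)
    return kept


def _score_of(peak: Peak, rank_by: str | None = None) -> float:
    if rank_by == "neg_log10_p":
        if peak.neg_log10_p is None:
            raise ValueError("peak lacks -log10 p")
        return peak.neg_log10_p
    if rank_by == "neg_log10_fdr":
        if peak.neg_log10_fdr is None:
            raise ValueError("peak lacks -log10 FDR")
        return peak.neg_log10_fdr
    if peak.neg_log10_p is not None:
        return peak.neg_log10_p
    if peak.neg_log10_fdr is not None:
        return peak.neg_log10_fdr
    raise ValueError(
        f"peak {peak.chrom}:{peak.start}-{peak.end} has no usable score field"
    )


def rank_peaks(peaks: Sequence[Peak], rank_by: str | None = None) -> list[Peak]:
    """Sort by confidence score descending; ties by (chrom, start, end)."""
    return sorted(
        peaks,
        key=lambda p: (-_score_of(p, rank_by), p.chrom, p.start, p.end),
    )


def select_top_peaks(
    peaks: Sequence[Peak],
    mode: str = "fraction",
    value: float = 0.1,
    rank_by: str | None = None,
) -> list[Peak]:
    """Select the most confident peaks by fraction, count or score cutoff.

    fraction: top ceil(f*n) by score; count: top k; score_cutoff: all
    peaks with score >= value.
    """
    ranked = rank_peaks(peaks, rank_by)
    if mode == "fraction":
        if not 0 < value <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = math.ceil(value * len(ranked))
        return ranked[:k]
    if mode == "count":
        return ranked[: int(value)]
    if mode == "score_cutoff":
        return [p for p in ranked if _score_of(p, rank_by) >= value]
    raise ValueError(f"unknown selection mode {mode!r}")


def _tree_by_chrom(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def compare_peak_sets(a: Sequence[Peak], b: Sequence[Peak]) -> OverlapReport:
    """Count peaks of each set sharing >= 1 bp with any peak of the other."""
    trees_a = _tree_by_chrom(a)
    trees_b = _tree_by_chrom(b)
    overlapped_a = sum(
        1 for p in a if p.chrom in trees_b and trees_b[p.chrom].overlaps(p.start, p.end)
    )
    overlapped_b = sum(
        1 for p in b if p.chrom in trees_a and trees_a[p.chrom].overlaps(p.start, p.end)
    )
    return OverlapReport(len(a), len(b), overlapped_a, overlapped_b)


def match_peaks(a: Sequence[Peak], b: Sequence[Peak]) -> list[tuple[int, int]]:
    """Greedy best-overlap matching of peaks across two sets.

    Each peak of A is paired with the B peak sharing the most bases;
    every B peak is used at most once.  Pairs are committed in order of
    decreasing shared bases, so a B peak contested by two A peaks goes to
    the one it overlaps more.
    """
    trees_b = _tree_by_chrom(b)
    index_b: dict[tuple[str, int, int], list[int]] = {}
    for j, p in enumerate(b):
        index_b.setdefault(p.interval(), []).append(j)
    candidates = []
    for i, p in enumerate(a):
        if p.chrom not in trees_b:
            continue
        for iv in trees_b[p.chrom].overlap(p.start, p.end):
            shared = min(p.end, iv.end) - max(p.start, iv.begin)
            for j in index_b[(p.chrom, iv.begin, iv.end)]:
                candidates.append((shared, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _shared, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> list[AssignmentRecord]:
    """Report every gene with a TSS or TES within max_distance of each
    peak center; the nearest gene(s) are flagged ``is_closest``.

    Distances are signed (anchor minus center); a gene's distance is the
    anchor with the smaller magnitude, TSS winning exact ties.  Equally
    near genes are all flagged closest, ordered by gene id.
    """
    if not genes:
        warnings.warn("empty gene list; no assignments produced", stacklevel=2)
        return []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    records: list[AssignmentRecord] = []
    for peak in peaks:
        center = peak.center
        hits = []
        for gene in by_chrom.get(peak.chrom, []):
            d_tss = gene.tss - center
            d_tes = gene.tes - center
            anchor, dist = ("TSS", d_tss) if abs(d_tss) <= abs(d_tes) else ("TES", d_tes)
            if abs(dist) <= max_distance:
                hits.append((abs(dist), gene.id, anchor, dist))
        if not hits:
            continue
        hits.sort()
        best = hits[0][0]
        for absd, gid, anchor, dist in hits:
            records.append(
                AssignmentRecord(
                    peak_chrom=peak.chrom,
                    peak_start=peak.start,
                    peak_end=peak.end,
                    peak_name=peak.name,
                    gene_id=gid,
                    anchor=anchor,
                    distance=dist,
                    is_closest=absd == best,
                )
            )
    return records


def center_windows(
    peaks: Sequence[Peak], width: int = 100, genome: GenomeTable | None = None
) -> list[tuple[str, int, int]]:
    """Fixed-width windows centered on each peak (for motif extraction),
    clipped to the chromosome when a genome table is given."""
    if width < 2 or width % 2:
        raise ValueError("width must be an even integer >= 2")
    half = width // 2
    windows = []
    for p in peaks:
        start, end = p.center - half, p.center + half
        if genome is not None:
            start = max(0, start)
            end = min(genome[p.chrom], end)
        windows.append((p.chrom, max(0, start), end))
    return windows
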