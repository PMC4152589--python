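"""Synthetic ChIP-Seq fixtures with controllable statistical structure.

Generates aligned reads (SAM), peak calls, gene models and GO-term
annotations so every stage of the package can be exercised without
external downloads.  Two presets capture the two binding archetypes:

* ``tf_like`` — punctate binding with duplicates concentrated in the
  strongest peaks (duplicate rate decreasing across confidence deciles,
  elevated well above the background rate), as seen for sequence-specific
  transcription factors;
* ``broad_like`` — diffuse domains with a uniform, low duplicate rate
  indistinguishable between peak and non-peak regions, as seen for broad
  histone marks.

Duplicates are created by re-emitting existing reads at the configured
rates, so planted rates are exact by construction; the ground-truth table
records every read's origin (peak id or background) and planted
duplicate status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from peakforge.genomic_io import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    AlignedRead,
    GenomeTable,
    Peak,
    ReadPair,
    write_peaks,
    write_sam,
)

UNIQUE_MAPQ = 60


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    ``background_read_rate`` is unique background reads per bp (0.01
    corresponds to a few million reads on a human-scale genome, scaled to
    the fixture genome).  ``peak_enrichment_factor`` multiplies that rate
    inside planted peaks.  ``dup_rate_peaks`` may be a single rate or one
    rate per confidence decile (strongest first).
    """

    seed: int = 0
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    n_peaks: int = 60
    peak_width_mean: float = 300.0
    peak_width_sd: float = 60.0
    background_read_rate: float = 0.01
    peak_enrichment_factor: float = 20.0
    dup_rate_background: float = 0.05
    dup_rate_peaks: float | Sequence[float] = 0.3
    paired: bool = False
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    read_length: int = 36
    multimap_fraction: float = 0.0
    n_genes: int = 40
    n_terms: int = 8
    term_enrichment_factor: float = 1.0
    # reproducibility fixture sizes
    n_shared_peaks: int = 100
    n_specific_peaks: tuple[int, int] = (20, 20)
    idr_shared_max: float = 0.05

    def __post_init__(self) -> None:
        rates = [self.dup_rate_background, self.multimap_fraction]
        rates += list(np.atleast_1d(self.dup_rate_peaks))
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("rates must lie in [0, 1)")
        if self.paired and self.fragment_length_mean <= self.read_length:
            raise ValueError("fragment length mean must exceed read length")

    @property
    def genome_table(self) -> GenomeTable:
        return GenomeTable(self.genome)


def tf_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Punctate-binding preset: duplicates pile up in the strongest peaks."""
    params = dict(
        seed=seed,
        n_peaks=80,
        peak_width_mean=250.0,
        peak_width_sd=40.0,
        peak_enrichment_factor=25.0,
        dup_rate_background=0.05,
        dup_rate_peaks=tuple(np.linspace(0.55, 0.08, 10)),
    )
    params.update(overrides)
    return SimulationConfig(**params)


def broad_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Broad-mark preset: uniform duplication, wide domains."""
    params = dict(
        seed=seed,
        n_peaks=40,
        peak_width_mean=2500.0,
        peak_width_sd=500.0,
        peak_enrichment_factor=6.0,
        dup_rate_background=0.05,
        dup_rate_peaks=0.05,
    )
    params.update(overrides)
    return SimulationConfig(**params)


PROFILES = {"tf_like": tf_like, "broad_like": broad_like}


@dataclass
class SimulatedLibrary:
    """In-memory result of simulate_reads: records, peaks and ground truth."""

    config: SimulationConfig
    reads: list[AlignedRead] | list[ReadPair]
    peaks: list[Peak]
    truth: pd.DataFrame  # read_id, chrom, pos5, strand, origin, planted_duplicate

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome = self.config.genome_table
        sam = outdir / f"{prefix}.sam"
        flat: list[AlignedRead] = []
        for rec in self.reads:
            if isinstance(rec, ReadPair):
                flat.extend(rec.mates)
            else:
                flat.append(rec)
        write_sam(flat, sam, genome)
        peaks_path = outdir / f"{prefix}_peaks.narrowPeak"
        write_peaks(self.peaks, peaks_path, dialect="encodePeak")
        sizes = outdir / f"{prefix}.chrom.sizes"
        sizes.write_text("".join(f"{c}\t{n}\n" for c, n in genome.items()))
        truth_path = outdir / f"{prefix}_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {
            "sam": sam,
            "peaks": peaks_path,
            "chrom_sizes": sizes,
            "truth": truth_path,
        }


def _plant_peaks(config: SimulationConfig, rng: np.random.Generator) -> list[Peak]:
    """Non-overlapping scored peaks; score decreases with planted rank."""
    genome = config.genome_table
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    peaks: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    gap = 2 * int(config.peak_width_mean)
    while len(peaks) < config.n_peaks:
        attempts += 1
        if attempts > 200 * config.n_peaks:
            raise ValueError(
                "genome too small to place the requested number of peaks"
            )
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        width = max(
            100, int(rng.normal(config.peak_width_mean, config.peak_width_sd))
        )
        if width + 2 * gap >= genome[chrom]:
            continue
        start = int(rng.integers(gap, genome[chrom] - width - gap))
        end = start + width
        if any(s - gap < end and start < e + gap for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        peaks.append((chrom, start, end))
    # rank 0 = strongest; -log10 p decreasing with rank, distinct values
    out = []
    n = config.n_peaks
    for rank, (chrom, start, end) in enumerate(peaks):
        neg_p = 3.0 + 50.0 * (n - rank) / n
        out.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                name=f"peak_{rank:04d}",
                score=round(neg_p * 10),
                strand=".",
                fold_change=5.0,
                neg_log10_p=neg_p,
                neg_log10_fdr=neg_p - 1.0,
                summit=(end - start) // 2,
            )
        )
    return out


def _peak_dup_rate(config: SimulationConfig, rank: int) -> float:
    rates = np.atleast_1d(np.asarray(config.dup_rate_peaks, dtype=float))
    if rates.size == 1:
        return float(rates[0])
    group = min(rates.size - 1, rank * rates.size // config.n_peaks)
    return float(rates[group])


def _make_se_read(
    name: str, chrom: str, pos5: int, strand: str, mapq: int, length: int
) -> AlignedRead:
    if strand == "+":
        start, end = pos5, pos5 + length
        flags = 0
    else:
        start, end = pos5 - length + 1, pos5 + 1
        flags = FLAG_REVERSE
    return AlignedRead(name, chrom, start, end, strand, mapq, flags)


def _make_pair(
    name: str, chrom: str, left: int, insert: int, mapq: int, length: int
) -> ReadPair:
    right_end = left + insert
    f1 = FLAG_PAIRED | FLAG_PROPER | FLAG_FIRST | FLAG_MATE_REVERSE
    f2 = FLAG_PAIRED | FLAG_PROPER | FLAG_SECOND | FLAG_REVERSE
    first = AlignedRead(name, chrom, left, left + length, "+", mapq, f1, tlen=insert)
    second = AlignedRead(
        name, chrom, right_end - length, right_end, "-", mapq, f2, tlen=-insert
    )
    return ReadPair(first, second)


def simulate_reads(config: SimulationConfig) -> SimulatedLibrary:
    """Simulate an aligned ChIP-Seq library with planted structure.

    Unique reads are placed uniformly over the genome at
    ``background_read_rate`` per bp and inside each planted peak at
    ``rate x peak_enrichment_factor``; duplicates then re-emit existing
    reads so that the duplicate fraction of each region class matches its
    configured rate.  A ``multimap_fraction`` of reads is emitted with
    MAPQ 0 (the aligner's single random placement).
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome_table
    peaks = _plant_peaks(config, rng)
    rlen = config.read_length

    # unique reads are drawn WITHOUT replacement from the (position,
    # strand) grid, so planted duplicate rates are exact: every duplicate
    # in the emitted library is a deliberate re-emission, not a chance
    # coordinate collision
    def sample_slots(lo: int, hi: int, n: int) -> list[tuple[int, str]]:
        n_slots = 2 * (hi - lo)
        n = min(n, n_slots)
        picks = rng.choice(n_slots, size=n, replace=False)
        return [(lo + int(s) // 2, "+" if s % 2 == 0 else "-") for s in picks]

    uniques: list[tuple[str, int, str, int, str]] = []  # chrom,pos5,strand,insert,origin
    # background 5' positions live in the complement of peaks plus a
    # 200 bp margin, so the peak and background read classes stay disjoint
    margin = 200
    for chrom, length in genome.items():
        segments: list[tuple[int, int]] = []
        cursor = rlen
        for p in sorted((p for p in peaks if p.chrom == chrom), key=lambda p: p.start):
            if p.start - margin > cursor:
                segments.append((cursor, p.start - margin))
            cursor = max(cursor, p.end + margin)
        if cursor < length - rlen:
            segments.append((cursor, length - rlen))
        seg_len = np.array([e - s for s, e in segments])
        n_bg = int(round(config.background_read_rate * length))
        slots = rng.choice(2 * int(seg_len.sum()), size=n_bg, replace=False)
        bounds = np.concatenate(([0], np.cumsum(seg_len)))
        for slot in np.sort(slots):
            offset, strand = int(slot) // 2, "+" if slot % 2 == 0 else "-"
            seg = int(np.searchsorted(bounds, offset, side="right")) - 1
            pos = segments[seg][0] + (offset - int(bounds[seg]))
            uniques.append((chrom, pos, strand, 0, "background"))
    n_background = len(uniques)
    # peaks
    peak_rank = {p.name: i for i, p in enumerate(peaks)}
    for p in peaks:
        rate = config.background_read_rate * config.peak_enrichment_factor
        n_pk = max(2, int(round(rate * p.length)))
        lo, hi = p.start, max(p.start + 1, p.end - rlen)
        for pos, strand in sample_slots(lo, hi, n_pk):
            pos5 = pos if strand == "+" else min(pos + rlen - 1, p.end - 1)
            uniques.append((p.chrom, pos5, strand, 0, p.name))

    # duplicates: re-emit existing reads at the class rate d -> extra
    # copies n_unique * d / (1 - d), chosen with replacement
    dup_emissions: list[int] = []
    bg_idx = np.arange(n_background)
    d_bg = config.dup_rate_background
    if d_bg > 0 and n_background:
        n_dup = int(round(n_background * d_bg / (1 - d_bg)))
        dup_emissions.extend(rng.choice(bg_idx, size=n_dup).tolist())
    by_peak: dict[str, list[int]] = {}
    for i, rec in enumerate(uniques[n_background:], start=n_background):
        by_peak.setdefault(rec[4], []).append(i)
    for name, idx in by_peak.items():
        d = _peak_dup_rate(config, peak_rank[name])
        if d > 0:
            n_dup = int(round(len(idx) * d / (1 - d)))
            dup_emissions.extend(
                rng.choice(np.asarray(idx), size=n_dup).tolist()
            )

    if config.paired:
        # fix each unique fragment's insert up front so duplicate
        # re-emissions share both mates' coordinates exactly
        inserts = np.maximum(
            rlen + 1,
            rng.normal(
                config.fragment_length_mean,
                config.fragment_length_sd,
                size=len(uniques),
            ).astype(int),
        )
        uniques = [
            (chrom, pos5, strand, int(ins), origin)
            for (chrom, pos5, strand, _z, origin), ins in zip(uniques, inserts)
        ]

    emissions = [(i, False) for i in range(len(uniques))] + [
        (int(i), True) for i in dup_emissions
    ]
    # deterministic shuffle so duplicates are interleaved like real data
    order = rng.permutation(len(emissions))
    emissions = [emissions[i] for i in order]

    mm = rng.random(len(emissions)) < config.multimap_fraction
    reads: list = []
    rows = []
    for serial, ((src, is_dup), is_mm) in enumerate(zip(emissions, mm)):
        chrom, pos5, strand, insert, origin = uniques[src]
        mapq = 0 if is_mm else UNIQUE_MAPQ
        name = f"read_{serial:07d}"
        if config.paired:
            left = min(pos5, genome[chrom] - insert - 1)
            reads.append(_make_pair(name, chrom, left, insert, mapq, rlen))
            pos_record = left
        else:
            reads.append(_make_se_read(name, chrom, pos5, strand, mapq, rlen))
            pos_record = pos5
        rows.append(
            {
                "read_id": name,
                "chrom": chrom,
                "pos5": pos_record,
                "strand": strand,
                "origin": origin,
                "planted_duplicate": bool(is_dup),
                "multimap": bool(is_mm),
            }
        )
    truth = pd.DataFrame(rows)
    return SimulatedLibrary(config=config, reads=reads, peaks=peaks, truth=truth)


@dataclass
class SimulatedReplicatePeaks:
    """Two replicate peak sets with IDR annotations and planted truth."""

    rep1: list[Peak]
    rep2: list[Peak]
    idr_values: dict[tuple[str, int, int], float]  # keyed on rep1 intervals
    n_shared: int


def simulate_peaks_and_scores(config: SimulationConfig) -> SimulatedReplicatePeaks:
    """Two replicate peak sets: shared peaks with jittered boundaries,
    correlated scores and low IDR; replicate-specific peaks with IDR 1."""
    rng = np.random.default_rng(config.seed + 1)
    genome = config.genome_table
    chroms = list(genome)
    width = 300
    spacing = 1200
    slots = []
    for chrom in chroms:
        for start in range(500, genome[chrom] - width - 500, spacing):
            slots.append((chrom, start))
    n1, n2 = config.n_specific_peaks
    needed = config.n_shared_peaks + n1 + n2
    if needed > len(slots):
        raise ValueError("genome too small for the requested peak counts")
    chosen = rng.choice(len(slots), size=needed, replace=False)
    rep1, rep2 = [], []
    idr_values: dict[tuple[str, int, int], float] = {}

    def mk(chrom, start, score, name):
        return Peak(
            chrom=chrom,
            start=start,
            end=start + width,
            name=name,
            score=round(score * 10),
            strand=".",
            fold_change=4.0,
            neg_log10_p=score,
            neg_log10_fdr=score - 1.0,
            summit=width // 2,
        )

    for i in range(config.n_shared_peaks):
        chrom, start = slots[chosen[i]]
        score = float(rng.uniform(5, 40))
        jitter = int(rng.integers(-50, 51))
        p1 = mk(chrom, start, score, f"shared_{i:04d}")
        p2 = mk(chrom, max(0, start + jitter), score + rng.normal(0, 1), f"shared_{i:04d}")
        rep1.append(p1)
        rep2.append(p2)
        idr_values[p1.interval()] = float(rng.uniform(0, config.idr_shared_max))
    for i in range(n1):
        chrom, start = slots[chosen[config.n_shared_peaks + i]]
        rep1.append(mk(chrom, start, float(rng.uniform(3, 10)), f"r1_only_{i:04d}"))
    for i in range(n2):
        chrom, start = slots[chosen[config.n_shared_peaks + n1 + i]]
        rep2.append(mk(chrom, start, float(rng.uniform(3, 10)), f"r2_only_{i:04d}"))
    return SimulatedReplicatePeaks(rep1, rep2, idr_values, config.n_shared_peaks)


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list, pd.DataFrame]:
    """Non-overlapping stranded gene models plus a gene -> GO-term table.

    Term 0 ("TERM_0000") is the designated target for enrichment tests:
    ``simulate_go_peaks`` places peak centers into its regulatory domains
    at ``term_enrichment_factor`` times the base per-bp rate.
    """
    from peakforge.peak_tools import GeneModel

    rng = np.random.default_rng(config.seed + 2)
    genome = config.genome_table
    total = genome.total_length
    # each gene needs ~20 kb of slack: body up to 8 kb plus regulatory
    # margins on both sides
    if config.n_genes * 20_000 > total:
        raise ValueError("genome too small for the requested gene count")
    genes: list[GeneModel] = []
    gi = 0
    for chrom, length in genome.items():
        n_here = max(1, round(config.n_genes * length / total))
        slot = length // n_here
        for j in range(n_here):
            if gi >= config.n_genes:
                break
            body = int(rng.integers(2000, 8000))
            start = j * slot + int(rng.integers(6000, max(6001, slot - body - 6000)))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{gi:04d}"
            if strand == "+":
                genes.append(GeneModel(gid, chrom, start, start + body, "+"))
            else:
                genes.append(GeneModel(gid, chrom, start + body, start, "-"))
            gi += 1
    rows = []
    for g in genes:
        n_terms_here = int(rng.integers(1, min(4, config.n_terms + 1)))
        terms = rng.choice(config.n_terms, size=n_terms_here, replace=False)
        for t in terms:
            rows.append({"gene_id": g.id, "term_id": f"TERM_{t:04d}"})
    annotations = pd.DataFrame(rows).sort_values(["gene_id", "term_id"]).reset_index(
        drop=True
    )
    return genes, annotations


def simulate_go_peaks(
    config: SimulationConfig,
    genes,
    annotations: pd.DataFrame,
    n_peaks: int = 200,
    domain_config=None,
    enriched_term: str = "TERM_0000",
) -> list[Peak]:
    """Peak centers over the annotatable genome, enriched for one term.

    A center lands in the enriched term's domain union with probability
    f*L_e / (f*L_e + L_rest) where f is ``term_enrichment_factor`` and
    L_e / L_rest are the union lengths inside / outside the term; factor
    1 reduces to uniform placement over the annotatable genome.
    """
    from peakforge.go_enrichment import (
        RegulatoryDomainConfig,
        build_domains,
        merge_intervals,
    )

    rng = np.random.default_rng(config.seed + 3)
    genome = config.genome_table
    domain_config = domain_config or RegulatoryDomainConfig()
    domains = build_domains(genes, domain_config, genome)
    enriched_genes = set(
        annotations.loc[annotations["term_id"] == enriched_term, "gene_id"]
    )
    enr: dict[str, list[tuple[int, int]]] = {}
    rest: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        bucket = enr if d.gene_id in enriched_genes else rest
        bucket.setdefault(d.chrom, []).append((d.extended_start, d.extended_end))
    enr = {c: merge_intervals(v) for c, v in enr.items()}
    # subtract the enriched union from the rest so the two partitions are disjoint
    rest_merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in rest.items():
        out = []
        for s, e in merge_intervals(ivs):
            cursor = s
            for es, ee in enr.get(chrom, []):
                if ee <= cursor or es >= e:
                    continue
                if es > cursor:
                    out.append((cursor, min(es, e)))
                cursor = max(cursor, ee)
            if cursor < e:
                out.append((cursor, e))
        rest_merged[chrom] = out

    def flatten(d):
        return [(c, s, e) for c, ivs in d.items() for s, e in ivs]

    enr_flat, rest_flat = flatten(enr), flatten(rest_merged)
    len_e = sum(e - s for _, s, e in enr_flat)
    len_r = sum(e - s for _, s, e in rest_flat)
    f = config.term_enrichment_factor
    p_enr = f * len_e / (f * len_e + len_r) if (len_e and len_r) else float(bool(len_e))

    def draw_from(flat):
        weights = np.array([e - s for _, s, e in flat], dtype=float)
        idx = rng.choice(len(flat), p=weights / weights.sum())
        chrom, s, e = flat[idx]
        return chrom, int(rng.integers(s, e))

    peaks = []
    half = 100
    for i in range(n_peaks):
        source = enr_flat if (rng.random() < p_enr and enr_flat) else rest_flat
        chrom, center = draw_from(source)
        start = max(0, center - half)
        end = min(genome[chrom], center + half)
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                name=f"gopeak_{i:04d}",
                score=100,
                strand=".",
                neg_log10_p=float(rng.uniform(5, 50)),
                summit=half,
            )
        )
    return peaks
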