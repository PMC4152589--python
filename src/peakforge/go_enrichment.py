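"""Binomial GO-term enrichment over gene regulatory domains.

Follows the GREAT-style basal-plus-extension model: every gene annotated
with at least one ontology term gets a proximal (basal) regulatory domain
from U bp upstream (default 5000) to D bp downstream (default 1000) of
its TSS, optionally extended up to UE/DE bp further, but never into a
neighboring gene's proximal domain.  Each GO term is then tested with a
binomial upper tail: given n peak centers falling in the annotatable
genome, how surprising is it that k of them lie inside the union of the
term's domains, whose genomic fraction is p_term?
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from peakforge.genomic_io import GenomeTable, Peak
from peakforge.peak_tools import GeneModel

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class RegulatoryDomainConfig:
    """Basal-plus-extension domain sizes, in bp around the TSS."""

    U: int = 5000  # proximal upstream
    D: int = 1000  # proximal downstream
    UE: int = 0  # maximum upstream extension
    DE: int = 0  # maximum downstream extension

    def __post_init__(self) -> None:
        if min(self.U, self.D, self.UE, self.DE) < 0:
            raise ValueError("domain sizes must be non-negative")


@dataclass(frozen=True)
class RegulatoryDomain:
    """A gene's proximal and extended regulatory intervals (proximal ⊆ extended)."""

    gene_id: str
    chrom: str
    proximal_start: int
    proximal_end: int
    extended_start: int
    extended_end: int

    @property
    def extended(self) -> Interval:
        return (self.chrom, self.extended_start, self.extended_end)


@dataclass(frozen=True)
class TermResult:
    """Binomial test outcome for one GO term."""

    term: str
    n: int  # peaks tested
    k: int  # peaks in the term's domain union
    p_term: float  # genomic fraction covered by the union
    p_value: float
    fdr: float
    genes: tuple[str, ...] = ()


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-D intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def union_length(intervals_by_chrom: Mapping[str, Sequence[tuple[int, int]]]) -> int:
    return sum(
        e - s
        for ivs in intervals_by_chrom.values()
        for s, e in merge_intervals(ivs)
    )


def build_domains(
    genes: Sequence[GeneModel],
    config: RegulatoryDomainConfig | None = None,
    genome: GenomeTable | None = None,
    annotated_ids: set[str] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for (annotated) genes.

    The proximal domain is [tss-U, tss+D) on the + strand and its mirror
    on the - strand.  Extensions reach at most UE/DE bp further but stop
    at the nearest neighboring gene's proximal domain; the proximal
    domain itself is never truncated.  Intervals are clipped to the
    chromosome when a genome table is supplied.
    """
    config = config or RegulatoryDomainConfig()
    if annotated_ids is not None:
        genes = [g for g in genes if g.id in annotated_ids]
    prox: dict[str, tuple[int, int]] = {}
    for g in genes:
        if g.strand == "+":
            prox[g.id] = (g.tss - config.U, g.tss + config.D)
        else:
            prox[g.id] = (g.tss - config.D, g.tss + config.U)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains = []
    for chrom, chrom_genes in by_chrom.items():
        for g in chrom_genes:
            p_start, p_end = prox[g.id]
            if g.strand == "+":
                e_start, e_end = p_start - config.UE, p_end + config.DE
            else:
                e_start, e_end = p_start - config.DE, p_end + config.UE
            # extensions stop at neighboring proximal domains; the basal
            # (proximal) domain itself is never truncated, so caps are
            # applied first and the basal extent restored afterwards
            for other in chrom_genes:
                if other.id == g.id:
                    continue
                o_start, o_end = prox[other.id]
                if o_end <= p_end:
                    e_start = max(e_start, o_end)
                if o_start >= p_start:
                    e_end = min(e_end, o_start)
            e_start = min(e_start, p_start)
            e_end = max(e_end, p_end)
            if genome is not None:
                limit = genome[chrom]
                p_start, p_end = max(0, p_start), min(limit, p_end)
                e_start, e_end = max(0, e_start), min(limit, e_end)
            else:
                p_start, e_start = max(0, p_start), max(0, e_start)
            domains.append(
                RegulatoryDomain(g.id, chrom, p_start, p_end, e_start, e_end)
            )
    return domains


def read_term_annotations(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene_id, term_id) -> DataFrame with those columns."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str
    )
    return df


def binomial_enrichment(
    peaks: Sequence[Peak],
    domains: Sequence[RegulatoryDomain],
    term_annotations: pd.DataFrame | Mapping[str, Iterable[str]],
    genome: GenomeTable | None = None,
    whole_genome_background: bool = False,
    max_genes_reported: int = 10,
) -> list[TermResult]:
    """GREAT-style binomial test per GO term.

    The annotatable background is the union of all genes' extended
    domains (or the whole genome when ``whole_genome_background``); each
    peak is reduced to its center point; ``p_term`` is the fraction of
    the background covered by the term's domain union and ``k`` counts
    peak centers inside it.  Results are sorted by p-value and carry
    Benjamini-Hochberg FDRs.
    """
    if isinstance(term_annotations, pd.DataFrame):
        term_to_genes: dict[str, list[str]] = {
            term: sorted(set(group["gene_id"]))
            for term, group in term_annotations.groupby("term_id")
        }
    else:
        term_to_genes = {t: sorted(set(gs)) for t, gs in term_annotations.items()}

    dom_by_gene: dict[str, list[RegulatoryDomain]] = {}
    all_ivs: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        dom_by_gene.setdefault(d.gene_id, []).append(d)
        all_ivs.setdefault(d.chrom, []).append((d.extended_start, d.extended_end))

    if whole_genome_background:
        if genome is None:
            raise ValueError("whole-genome background requires a genome table")
        background = genome.total_length
    else:
        background = union_length(all_ivs)
    if background <= 0:
        raise ValueError("annotatable genome length is zero")

    centers = [(p.chrom, p.center) for p in peaks]
    n = len(centers)

    results = []
    for term, gene_ids in sorted(term_to_genes.items()):
        ivs: dict[str, list[tuple[int, int]]] = {}
        for gid in gene_ids:
            for d in dom_by_gene.get(gid, []):
                ivs.setdefault(d.chrom, []).append((d.extended_start, d.extended_end))
        if not ivs:
            continue  # term with no domain-bearing genes: nothing to test
        merged = {c: merge_intervals(v) for c, v in ivs.items()}
        term_len = sum(e - s for v in merged.values() for s, e in v)
        p_term = min(1.0, term_len / background)
        k = sum(
            1
            for chrom, center in centers
            if chrom in merged
            and any(s <= center < e for s, e in merged[chrom])
        )
        p_value = float(binom.sf(k - 1, n, p_term)) if n else 1.0
        results.append((term, n, k, p_term, p_value, tuple(gene_ids)))

    if not results:
        return []
    fdrs = bh_fdr([r[4] for r in results])
    out = [
        TermResult(term, n, k, p_term, p_value, fdr, genes[:max_genes_reported])
        for (term, n, k, p_term, p_value, genes), fdr in zip(results, fdrs)
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return list(adjusted)


def results_table(results: Sequence[TermResult]) -> pd.DataFrame:
    """TermResults as the output table: term, n, k, p_term, p_value, fdr, genes."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "p_term": [r.p_term for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "genes": [",".join(r.genes) for r in results],
        }
    )
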