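"""Post-alignment filters and the library-complexity statistic.

The filters mirror what a careful ChIP-Seq analyst does between the
aligner and the peak caller: drop poorly mapped reads (MAPQ cutoff,
applied pair-wise for paired-end data so pairing is never broken), keep
only proper pairs (same chromosome, innie FR orientation, sane insert),
decide what to do with multi-mapping placements, and remove PCR
duplicates.  Library complexity — distinct fragments over total uniquely
mapped — is the standard QC statistic; ~0.8 at 10 M reads is the usual
guideline for a healthy library.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from peakforge.genomic_io import FLAG_DUP, AlignedRead, ReadPair

COMPLEXITY_GUIDELINE = 0.8


class PairClass(enum.Enum):
    """Mapping state of a read pair, judged by MAPQ>0 per end."""

    both_unique = "a"
    one_unique = "b"
    both_multi = "c"


class MultimapPolicy(enum.Enum):
    unique_only = "a"  # keep only both-unique pairs
    one_end_unique = "b"  # plus pairs with exactly one unique end
    one_end_unique_plus_random = "c"  # plus both-multi pairs (their single
    # reported placement is the aligner's random choice among alternatives)


@dataclass
class FilterConfig:
    """Knobs for the post-alignment filtering stage.

    ``mapq_cutoff`` keeps reads with MAPQ >= cutoff (the boundary value
    survives).  ``keep_multi_both_zero`` exempts pairs where both ends
    have MAPQ 0 from the MAPQ filter, so the multimap policy can decide
    their fate instead.  Insert bounds default to [1, 1000] bp.
    """

    mapq_cutoff: int = 20
    keep_multi_both_zero: bool = False
    multimap_policy: MultimapPolicy = MultimapPolicy.unique_only
    se_random_match: bool = False
    min_insert: int = 1
    max_insert: int = 1000
    require_fr: bool = True
    remove_duplicates: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.multimap_policy, str):
            self.multimap_policy = MultimapPolicy[self.multimap_policy]
        if self.mapq_cutoff < 0:
            raise ValueError("mapq_cutoff must be >= 0")
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert > max_insert")


@dataclass(frozen=True)
class ComplexityReport:
    """Library complexity = after_dedup / total_unique_mapped."""

    total_unique_mapped: int
    after_dedup: int

    @property
    def complexity(self) -> float:
        return self.after_dedup / self.total_unique_mapped

    @property
    def duplicate_pct(self) -> float:
        return 100.0 * (1.0 - self.complexity)

    @property
    def guideline_flag(self) -> bool:
        """True when complexity meets the ~0.8 quality guideline."""
        return self.complexity >= COMPLEXITY_GUIDELINE


def classify_pair(pair: ReadPair) -> PairClass:
    """Classify a mapped pair by how many ends mapped uniquely (MAPQ>0)."""
    if pair.first.is_unmapped or pair.second.is_unmapped:
        raise ValueError(
            "unmapped mate in pair; run the proper-pair filter before classifying"
        )
    unique = (pair.first.mapq > 0) + (pair.second.mapq > 0)
    return (PairClass.both_multi, PairClass.one_unique, PairClass.both_unique)[unique]


def filter_mapq_single(
    reads: Iterable[AlignedRead], cutoff: int, keep_zero_mapq: bool = False
) -> list[AlignedRead]:
    """Keep single-end reads with MAPQ >= cutoff.

    ``keep_zero_mapq`` additionally retains MAPQ-0 reads (the aligner's
    single random placement of a multi-mapper), mirroring the paired-end
    exemption for both-multi pairs.
    """
    return [
        r
        for r in reads
        if not r.is_unmapped and (r.mapq >= cutoff or (keep_zero_mapq and r.mapq == 0))
    ]


def filter_mapq_pairs(
    pairs: Iterable[ReadPair], cutoff: int, keep_multi_both_zero: bool = False
) -> list[ReadPair]:
    """Drop pairs with any end below the MAPQ cutoff, keeping pairs intact.

    Both-multi pairs (both ends MAPQ 0) survive when
    ``keep_multi_both_zero`` is set, so the multimap policy can handle
    them downstream.
    """
    kept = []
    for pair in pairs:
        if keep_multi_both_zero and classify_pair(pair) is PairClass.both_multi:
            kept.append(pair)
        elif pair.first.mapq >= cutoff and pair.second.mapq >= cutoff:
            kept.append(pair)
    return kept


def filter_proper_pairs(
    pairs: Iterable[ReadPair], config: FilterConfig | None = None
) -> list[ReadPair]:
    """Keep pairs on one chromosome, FR-oriented, with insert in bounds."""
    config = config or FilterConfig()
    kept = []
    for pair in pairs:
        if pair.first.is_unmapped or pair.second.is_unmapped:
            continue
        if pair.orientation == "cross-chrom":
            continue
        if config.require_fr and pair.orientation != "FR":
            continue
        if not (config.min_insert <= pair.insert <= config.max_insert):
            continue
        kept.append(pair)
    return kept


def apply_multimap_policy(
    pairs: Iterable[ReadPair], policy: MultimapPolicy | str
) -> list[ReadPair]:
    """Apply the three-way multi-mapper policy to proper pairs.

    (a) unique_only: both ends MAPQ>0; (b) one_end_unique: at least one
    end MAPQ>0; (c) one_end_unique_plus_random: additionally keep
    both-multi pairs at their single reported placement.
    """
    if isinstance(policy, str):
        try:
            policy = MultimapPolicy[policy]
        except KeyError as exc:
            raise ValueError(f"unknown multimap policy {policy!r}") from exc
    allowed = {
        MultimapPolicy.unique_only: {PairClass.both_unique},
        MultimapPolicy.one_end_unique: {PairClass.both_unique, PairClass.one_unique},
        MultimapPolicy.one_end_unique_plus_random: set(PairClass),
    }[policy]
    return [p for p in pairs if classify_pair(p) in allowed]


def _se_key(read: AlignedRead) -> tuple:
    return (read.chrom, read.five_prime, read.strand)


def _pe_key(pair: ReadPair) -> tuple:
    ends = tuple(sorted((r.chrom, r.five_prime) for r in pair.mates))
    return ends + (pair.orientation,)


def mark_duplicates(records: Sequence[AlignedRead] | Sequence[ReadPair]):
    """Flag duplicate reads or pairs and return (flagged, dedup) streams.

    Records sharing a duplicate key — (chrom, 5' position, strand) for
    single-end reads; (both mates' chrom + 5' positions, orientation) for
    pairs — are one duplicate group.  The representative is the record
    with the highest MAPQ (summed over mates for pairs), ties broken by
    input order; every other member gets the SAM duplicate flag.  The
    operation is idempotent.

    Returns ``(flagged, dedup)`` where ``flagged`` preserves input order
    with duplicate flags set, and ``dedup`` contains representatives only.
    """
    records = list(records)
    if not records:
        return [], []
    paired = isinstance(records[0], ReadPair)
    keyfn = _pe_key if paired else _se_key
    mapqfn = (
        (lambda p: p.first.mapq + p.second.mapq) if paired else (lambda r: r.mapq)
    )

    best: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        key = keyfn(rec)
        if key not in best or mapqfn(rec) > mapqfn(records[best[key]]):
            best[key] = i
    keep = set(best.values())

    def flag(rec, is_dup):
        if paired:
            return ReadPair(
                rec.first.with_flag(FLAG_DUP, is_dup),
                rec.second.with_flag(FLAG_DUP, is_dup),
            )
        return rec.with_flag(FLAG_DUP, is_dup)

    flagged = [flag(rec, i not in keep) for i, rec in enumerate(records)]
    dedup = [rec for i, rec in enumerate(flagged) if i in keep]
    return flagged, dedup


def library_complexity(total_unique_mapped: int, after_dedup: int) -> ComplexityReport:
    """Build a ComplexityReport from pre- and post-dedup read counts."""
    if total_unique_mapped <= 0:
        raise ValueError("library complexity undefined for empty library")
    if not 0 < after_dedup <= total_unique_mapped:
        raise ValueError(
            f"after_dedup ({after_dedup}) must be in (0, {total_unique_mapped}]"
        )
    return ComplexityReport(total_unique_mapped, after_dedup)


def filter_single_end(
    reads: Iterable[AlignedRead], config: FilterConfig | None = None
) -> tuple[list[AlignedRead], ComplexityReport | None]:
    """Full single-end filter chain: MAPQ -> duplicates.

    Returns the surviving reads and, when duplicates were removed, the
    complexity report computed over the uniquely mapped input.
    """
    config = config or FilterConfig()
    survivors = filter_mapq_single(
        reads, config.mapq_cutoff, keep_zero_mapq=config.se_random_match
    )
    if not config.remove_duplicates:
        return survivors, None
    flagged, dedup = mark_duplicates(survivors)
    report = library_complexity(len(flagged), len(dedup)) if flagged else None
    return dedup, report


def filter_paired_end(
    pairs: Iterable[ReadPair], config: FilterConfig | None = None
) -> tuple[list[ReadPair], ComplexityReport | None]:
    """Full paired-end chain: proper-pair -> MAPQ -> policy -> duplicates."""
    config = config or FilterConfig()
    survivors = filter_proper_pairs(pairs, config)
    survivors = filter_mapq_pairs(
        survivors, config.mapq_cutoff, keep_multi_both_zero=config.keep_multi_both_zero
    )
    survivors = apply_multimap_policy(survivors, config.multimap_policy)
    if not config.remove_duplicates:
        return survivors, None
    flagged, dedup = mark_duplicates(survivors)
    report = library_complexity(len(flagged), len(dedup)) if flagged else None
    return dedup, report
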