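"""Pseudoreplicate and IDR bookkeeping.

The IDR statistic itself comes from an external estimator (or the
synthetic-fixture generator); this module implements the orchestration
around it: merging replicates, randomized equal splits into
pseudoreplicates, writing IDR values into the encodePeak name column,
counting consistent peaks at a cutoff, and the ENCODE factor-of-two
rescue / self-consistency decision rule, together with the conservative
(shared between biological replicates) and optimal (the larger of that
and the merged-pseudoreplicate count) peak lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from peakforge.genomic_io import Peak

DEFAULT_IDR_CUTOFF = 0.01
IDR_CUTOFF_GRID = (0.001, 0.005, 0.01, 0.02, 0.05, 0.1)
MAX_RATIO = 2.0


@dataclass(frozen=True)
class ReproducibilityReport:
    """Factor-of-two assessment of replicate consistency.

    rescue_ratio compares consistent peaks between true replicates with
    those between pseudoreplicates of the merged IP; self_ratio compares
    the two within-replicate pseudoreplicate counts.  Both must stay
    within a factor of two for the experiment to pass.
    """

    n_true: int
    n_merged_pseudo: int
    n_self_1: int
    n_self_2: int

    @property
    def rescue_ratio(self) -> float:
        hi, lo = max(self.n_true, self.n_merged_pseudo), min(
            self.n_true, self.n_merged_pseudo
        )
        return hi / lo

    @property
    def self_ratio(self) -> float:
        hi, lo = max(self.n_self_1, self.n_self_2), min(self.n_self_1, self.n_self_2)
        return hi / lo

    @property
    def rescue_ratio_rounded(self) -> float:
        return round(self.rescue_ratio, 1)

    @property
    def self_ratio_rounded(self) -> float:
        return round(self.self_ratio, 1)

    @property
    def passed(self) -> bool:
        return self.rescue_ratio <= MAX_RATIO and self.self_ratio <= MAX_RATIO

    @property
    def conservative_n(self) -> int:
        """Peaks shared between biological replicates."""
        return self.n_true

    @property
    def optimal_n(self) -> int:
        """The larger of the true-replicate and merged-pseudoreplicate counts."""
        return max(self.n_true, self.n_merged_pseudo)


def merge_replicates(*read_streams: Iterable) -> list:
    """Concatenate replicate read streams into one merged dataset."""
    merged: list = []
    for stream in read_streams:
        merged.extend(stream)
    return merged


def split_pseudoreplicates(reads: Sequence, seed: int) -> tuple[list, list]:
    """Randomly split reads into two equal-sized pseudoreplicates.

    A uniform permutation under the given seed; the first ceil(n/2)
    records form pseudoreplicate 1.  Deterministic given the seed, and
    the two halves always partition the input.
    """
    reads = list(reads)
    n = len(reads)
    if n < 2:
        raise ValueError("need at least 2 reads to split into pseudoreplicates")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    half = math.ceil(n / 2)
    pseudo1 = [reads[i] for i in order[:half]]
    pseudo2 = [reads[i] for i in order[half:]]
    return pseudo1, pseudo2


def annotate_idr(
    peaks: Sequence[Peak], idr_values: dict[tuple[str, int, int], float]
) -> list[Peak]:
    """Write per-peak IDR values into the encodePeak name column.

    ``idr_values`` maps (chrom, start, end) of shared peaks to their
    estimated IDR (< 1); peaks with no counterpart in the other replicate
    get the sentinel value 1, so consistent peaks can later be extracted
    at any cutoff.
    """
    annotated = []
    for p in peaks:
        idr = idr_values.get(p.interval())
        if idr is not None and not 0.0 <= idr < 1.0:
            raise ValueError(
                f"IDR {idr} for shared peak {p.chrom}:{p.start}-{p.end} "
                "must be in [0, 1)"
            )
        annotated.append(
            Peak(
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                name=p.name,
                score=p.score,
                strand=p.strand,
                fold_change=p.fold_change,
                neg_log10_p=p.neg_log10_p,
                neg_log10_fdr=p.neg_log10_fdr,
                idr=idr if idr is not None else 1.0,
                summit=p.summit,
            )
        )
    return annotated


def count_consistent(
    annotated_peaks: Iterable[Peak], cutoff: float = DEFAULT_IDR_CUTOFF
) -> int:
    """Number of peaks with IDR <= cutoff (monotone in the cutoff)."""
    n = 0
    for p in annotated_peaks:
        if p.idr is None:
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} lacks an IDR annotation"
            )
        if p.idr <= cutoff:
            n += 1
    return n


def consistency_curve(
    annotated_peaks: Sequence[Peak], cutoffs: Sequence[float] = IDR_CUTOFF_GRID
) -> dict[float, int]:
    """Consistent-peak counts over a grid of IDR cutoffs."""
    return {c: count_consistent(annotated_peaks, c) for c in cutoffs}


def assess_reproducibility(
    n_true: int, n_merged_pseudo: int, n_self_1: int, n_self_2: int
) -> ReproducibilityReport:
    """Apply the factor-of-two rule to the four consistent-peak counts."""
    counts = (n_true, n_merged_pseudo, n_self_1, n_self_2)
    if any(c <= 0 for c in counts):
        raise ValueError(
            "zero consistent-peak count: reproducibility undefined; "
            "consider generating a third replicate"
        )
    return ReproducibilityReport(n_true, n_merged_pseudo, n_self_1, n_self_2)
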