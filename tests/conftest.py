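"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import pytest

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
)


def se_read(
    name: str,
    chrom: str = "chr1",
    start: int = 100,
    length: int = 36,
    strand: str = "+",
    mapq: int = 60,
    flags: int = 0,
) -> AlignedRead:
    if strand == "-":
        flags |= FLAG_REVERSE
    return AlignedRead(name, chrom, start, start + length, strand, mapq, flags)


def pe_pair(
    name: str,
    chrom: str = "chr1",
    left: int = 100,
    insert: int = 200,
    length: int = 36,
    mapq1: int = 60,
    mapq2: int = 60,
    orientation: str = "FR",
) -> ReadPair:
    """Build a mate pair with the requested orientation."""
    base = FLAG_PAIRED | FLAG_PROPER
    right = left + insert
    strands = {"FR": "+-", "RF": "-+", "FF": "++", "RR": "--"}[orientation]

    def mate(pos_left, strand, mapq, which, tlen):
        flags = base | which
        if strand == "-":
            flags |= FLAG_REVERSE
        else:
            flags |= FLAG_MATE_REVERSE
        return AlignedRead(
            name, chrom, pos_left, pos_left + length, strand, mapq, flags, tlen=tlen
        )

    first = mate(left, strands[0], mapq1, FLAG_FIRST, insert)
    second = mate(right - length, strands[1], mapq2, FLAG_SECOND, -insert)
    return ReadPair(first, second)


def peak(
    chrom="chr1", start=0, end=100, name=".", neg_log10_p=None, neg_log10_fdr=None, **kw
) -> Peak:
    return Peak(
        chrom=chrom,
        start=start,
        end=end,
        name=name,
        neg_log10_p=neg_log10_p,
        neg_log10_fdr=neg_log10_fdr,
        **kw,
    )


@pytest.fixture
def genome() -> GenomeTable:
    return GenomeTable({"chr1": 10_000, "chr2": 5_000})
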