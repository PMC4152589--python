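"""Fold-change filtering, peak-set comparison and peak-to-gene assignment.

Builds a broad-domain call set with mixed fold changes, filters at the
2x threshold, compares two jittered replicate peak sets, and assigns
peaks to the genes whose TSS/TES lie within 10 kb of the peak center.
"""

from peakforge import peak_tools as pt
from peakforge import synthetic_fixtures as sf
from peakforge.genomic_io import Peak

config = sf.SimulationConfig(seed=0)
rep = sf.simulate_peaks_and_scores(config)

# fold-change filter on broad domains
domains = [
    Peak(chrom="chr1", start=10_000 * i, end=10_000 * i + 4_000,
         fold_change=fc, neg_log10_fdr=8.0)
    for i, fc in enumerate([3.2, 1.5, 2.0, 0.9, 6.1], start=1)
]
kept = pt.fold_change_filter(domains, threshold=2.0)
print(f"domains with fold change >= 2: {len(kept)}/{len(domains)}")

# two-way replicate overlap
report = pt.compare_peak_sets(rep.rep1, rep.rep2)
print(
    f"replicate overlap: {report.pct_overlap_a:.1f}% of set A, "
    f"{report.pct_overlap_b:.1f}% of set B"
)

# peak-to-gene assignment
genes, _ = sf.simulate_annotation(config)
records = pt.assign_peaks_to_genes(rep.rep1, genes, max_distance=10_000)
closest = [r for r in records if r.is_closest]
print(f"{len(closest)} peaks assigned to a nearest gene within 10 kb")
example = closest[0]
print(
    f"e.g. peak {example.peak_name} -> {example.gene_id} "
    f"({example.anchor} at {example.distance:+d} bp from peak center)"
)
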