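# Methods

This note records the models, conventions and numerical choices behind
`peakforge`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and formats

Everything inside the package is 0-based half-open (BED convention); the
single conversion happens at the SAM boundary, where pysam maps the 1-based
POS field to `reference_start`. Peak files are read in three dialects:
MACS encodePeak/narrowPeak (10 columns, −log₁₀ p in column 8), the SICER
island summary (8 columns with raw IP/control window counts, fold change
and FDR), and plain BED3–6. The encodePeak name column is dual-use: after
IDR annotation it carries the numeric IDR value, and the reader mirrors a
numeric name in [0, 1] into the `idr` field while preserving the verbatim
string. Filtered SICER islands are re-emitted 0-based half-open. Wig output
is fixedStep only (span = step), since tracks are generated at a uniform
step size; trailing all-zero windows are omitted.

## Read filtering

MAPQ filtering keeps a read (or both ends of a pair) when MAPQ ≥ cutoff —
the boundary value survives. MAPQ 0 is treated throughout as the aligner's
mark for a multi-mapping placement. Pairs are never broken: either both
mates survive a filter or neither does. The both-MAPQ-0 exemption
(`keep_multi_both_zero`) defers those pairs to the multi-mapper policy
rather than discarding them at the MAPQ stage. For single-end data the
analogous exemption (`se_random_match`) is applied only when explicitly
enabled; it retains the aligner's single reported placement of each
multi-mapper rather than re-sampling among alternatives, since the random
choice was already made upstream by the aligner's random mode.

Proper-pair filtering requires one chromosome, FR (innie) orientation when
`require_fr` is set, and an insert within `[min_insert, max_insert]`. The
default bounds are [1, 1000] bp — wide enough not to truncate ordinary
ChIP fragment-size distributions; they are configuration, not biology.

Duplicate keys are (chromosome, 5′ position, strand) for single-end reads
and (both mates' chromosome + 5′ position, orientation) for pairs. The 5′
position is the alignment start on the plus strand and the alignment end on
the minus strand, without soft-clip adjustment — a deliberate simplification
relative to Picard's unclipped-position refinement, adequate because the
package's inputs are post-filter alignments and its fixtures contain no
clipping. The representative of a duplicate group is the record with the
highest MAPQ (summed over mates for pairs), ties resolved by input order;
the per-pair rule generalizes the per-read one, which does not define the
pair case. This determinism is what makes exact dedup tests possible.
Optical-duplicate detection and base-quality tie-breaking are out of scope.

Library complexity is `after_dedup / total_unique_mapped`; the guideline
flag compares against 0.8, the conventional threshold at ~10 M reads.

## Coverage tracks

Single-end reads extend to the average library fragment length (default
200 bp) from the 5′ end; each proper pair contributes exactly one fragment
spanning its observed insert (|TLEN| from the leftmost mate), so paired
coverage uses actual fragment sizes rather than a library average.
Fragments are clipped to chromosome bounds. Coverage is computed with an
event/difference array per chromosome and stored as maximal constant runs;
the invariant Σ(value × run length) = Σ fragment lengths holds exactly when
no fragment was clipped. Per-million normalization multiplies every value
by 10⁶ / library size, where the library size defaults to the number of
records the track was built from (post-filter); the pre-dedup count can be
supplied instead. The Wig step value is the window mean, which preserves
the conservation property under aggregation; start-point sampling is
available as an option. The trailing partial window is averaged over its
true width.

## Reproducibility bookkeeping

Pseudoreplicates are produced by a uniform random permutation under an
explicit seed (default 42); the first ⌈n/2⌉ records form pseudoreplicate 1,
so the two halves always partition the input with sizes differing by at
most one. IDR values come from an external estimator or the fixture
generator — the copula mixture model itself is out of scope, because the
package's contribution is the orchestration around it. Shared peaks get
their IDR (< 1) written into the encodePeak name column; replicate-specific
peaks get the sentinel 1, so consistent peaks are extractable at any cutoff
by a column comparison. Peak correspondence across replicates, where
needed, uses ≥ 1 bp overlap with greedy best-overlap matching. Ratios are
reported both raw and rounded to one decimal (the conventional
presentation); the pass flag uses the raw values, and the self ratio is
max/min, so it is invariant to replicate order. The consistent-peak count
grid {0.001, 0.005, 0.01, 0.02, 0.05, 0.1} mirrors common reporting.

## Peak post-processing

Overlap between peaks means sharing at least one base in half-open
arithmetic (`a.start < b.end and b.start < a.end`); adjacency is not
overlap. Top-peak selection sorts by −log₁₀ p (or −log₁₀ FDR) descending
with (chrom, start, end) tie-breaking and takes ⌈f·n⌉ for a fraction f.
Peak-to-gene distance is measured from the peak center — the midpoint
⌊(start+end)/2⌋ — to the gene's TSS and TES anchors; the anchor with the
smaller magnitude wins, TSS on exact ties; every gene within the 10 kb
default cutoff is reported and the nearest flagged, with equidistant genes
all flagged in id order. The fold-change fallback for islands lacking a
precomputed value is (ip/ip_total)/(ctrl/ctrl_total) with a pseudocount of
1 on a zero control count.

## GO enrichment

Regulatory domains follow the basal-plus-extension model: basal domain
[TSS−U, TSS+D) on the plus strand (defaults U = 5000, D = 1000), mirrored
on the minus strand; extensions reach at most UE/DE bp further but stop at
the nearest neighboring gene's basal domain, and the basal domain itself is
never truncated. The annotatable background is the union of all annotated
genes' extended domains; a whole-genome background is available as an
option. Each peak is reduced to its center point. For a term whose domain
union covers fraction p of the background, with k of n peak centers inside,
the p-value is the exact binomial upper tail `scipy.stats.binom.sf(k−1, n,
p)`; Benjamini–Hochberg FDRs are reported alongside raw p-values. All n
peaks are tested, including those outside every domain (the alternative —
restricting n to in-domain peaks — would change p and k together and is not
what the binomial model assumes). Annotations are taken as given,
pre-propagated; no GO DAG handling.

## Duplicate diagnostics

A read belongs to a region iff its 5′ base lies inside (point rule, not
overlap), so disjoint region classes partition the reads exactly and group
totals are additive. The non-peak background is the complement of peaks
extended by 100 bp on each side; reads falling in that buffer belong to
neither the peak nor the non-peak class. Confidence groups are formed by
sorting peaks by score descending and splitting into ten contiguous groups,
earlier (higher-confidence) groups taking the remainder; a read inside
peaks of two groups is counted in the higher-confidence one.

## Synthetic fixtures

The generator emulates the statistical structure of the two binding
archetypes, not sequencing physics. Unique reads are drawn without
replacement from the (position × strand) grid — background reads in the
complement of peaks ± 200 bp, peak reads inside their peak — so every
duplicate in the emitted library is a deliberate re-emission and planted
rates are exact by construction. For a region-class rate d, the generator
re-emits `n·d/(1−d)` copies sampled with replacement from that class's
unique reads. Defaults: a 1 Mb two-chromosome genome, 60 peaks of mean
width 300 bp, 0.01 unique background reads per bp, 20× enrichment inside
peaks, 36 bp reads; paired mode draws inserts from a truncated Normal(200,
20). The `tf_like` preset plants duplicate rates decreasing linearly from
0.55 to 0.08 across confidence deciles over a 5 % background; `broad_like`
plants a uniform 5 % everywhere with 2.5 kb domains. Peak confidence scores
decrease deterministically with planted rank, so decile recovery is exact.
SAM output carries minimal mandatory fields with correct flags and TLEN;
sequences are placeholder bases and qualities constant, since no downstream
module inspects them.

What passing tests show: the filters, statistics and bookkeeping compute
what they claim on data whose ground truth is known exactly. What they do
not show: robustness to mappability structure, soft-clipping, chimeric
pairs, optical duplicates, or non-uniform background — real-library
phenomena the generator deliberately omits.

## Problem sizes and determinism

Test and acceptance runs use fixture genomes of ~1 Mb with 10⁴–2×10⁴ reads
per library, brute-force oracles on instances up to 500×500 peaks, 100 kb
per-base arrays and n ≤ 12 binomial enumeration — sizes chosen so every
oracle comparison is exhaustive yet the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeded explicitly;
identical configuration and seed give byte-identical outputs.

## Pipeline

`run_pipeline` executes stages serially from a YAML config and writes a
manifest; every number in the summary TSVs is produced by the corresponding
library function on the stage outputs, never recomputed independently. The
punctate profile consumes four pre-annotated encodePeak files (true
replicates, merged-IP pseudoreplicates, within-replicate pseudoreplicates)
for the factor-of-two assessment; the broad profile runs the fold-change
filter and skips IDR, which is meaningless for diffuse domains. Cluster
parallelization, HTML reports and genome-browser session files are out of
scope.
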