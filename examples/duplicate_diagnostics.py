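"""Where do the duplicates live: peaks or background?

Simulates the two binding archetypes and contrasts their duplicate
distributions.  Punctate (TF-like) libraries concentrate duplicates in
the strongest peaks — the confidence-decile profile falls steeply — while
broad-mark libraries show a flat profile at the background level.
"""

from peakforge import dup_diagnostics as dd
from peakforge import read_filtering as rf
from peakforge import synthetic_fixtures as sf

for name, config in (("tf_like", sf.tf_like(seed=0)), ("broad_like", sf.broad_like(seed=0))):
    library = sf.simulate_reads(config)
    flagged, _ = rf.mark_duplicates(library.reads)
    print(f"\n== {name} ==")
    for row in dd.duplication_table(flagged, library.peaks, config.genome_table):
        print(
            f"{row.region_class:>10}: {row.dup_pct:5.1f}% duplicates, "
            f"{row.portion_pct:5.1f}% of all duplicates, span {row.span:,} bp"
        )
    profile = dd.decile_profile(library.peaks, flagged)
    pcts = ", ".join(f"{p:.1f}" for p in profile.dup_pcts)
    print(f"decile duplicate % (strongest peaks first): {pcts}")
# In the TF-like library the top decile is dominated by duplicates even
# though peaks cover a sliver of the genome; in the broad-like library
# removing duplicates barely changes peak-region signal.
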