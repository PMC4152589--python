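"""Build normalized bedGraph and Wig coverage tracks from reads.

Single-end reads are extended to the library's average fragment length
(200 bp) from their 5' ends; coverage is run-length encoded and scaled
to a library of one million mapped reads.
"""

import tempfile
from pathlib import Path

from peakforge import read_filtering as rf
from peakforge import signal_tracks as st
from peakforge import synthetic_fixtures as sf

config = sf.tf_like(seed=0)
library = sf.simulate_reads(config)
_, dedup = rf.mark_duplicates(library.reads)
genome = config.genome_table

track = st.track_from_records(dedup, genome, fragment_length=200, step=20,
                              normalize=True)
total = track.total_signal()
print(f"reads used: {len(dedup)}; normalized track signal sum: {total:.0f}")
# signal sum = fragment bp x 1e6 / library size; with 200 bp fragments
# this is ~200e6 regardless of sequencing depth, which is the point of
# per-million normalization.

outdir = Path(tempfile.mkdtemp())
st.write_track(track, outdir / "ip.bedgraph", "bedgraph")
st.write_track(track, outdir / "ip.wig", "wig")
print(f"wrote {outdir}/ip.bedgraph and {outdir}/ip.wig")
peak = library.peaks[0]
window = st.wig_steps(track, 20)[peak.chrom]
inside = float(window[peak.start // 20])
print(f"coverage in the strongest peak's first window: {inside:.2f} reads-per-million")
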