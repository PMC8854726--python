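"""Peak-vs-input subtraction and genome-size BH q-values.

ATAC peaks sharing more than half their length with the nucleosome-free
input sample are treated as false positives and removed whole; surviving
peaks receive Benjamini-Hochberg q-scores computed against a fixed
number of tests equal to the 2.7 Gb cattle genome.
"""

from pangnovel import bh_qvalues, inframe_fraction, subtract_input_peaks, titv

peaks = [
    ("chr1", 1_000, 1_400, "peak1", 1e-12),
    ("chr1", 5_000, 5_300, "peak2", 1e-8),
    ("chr1", 9_000, 9_200, "peak3", 1e-5),
]
input_peaks = [("chr1", 5_100, 5_600)]  # covers 200/300 bp of peak2

kept = subtract_input_peaks(peaks, input_peaks, min_frac=0.5)
print(f"peaks kept after input subtraction: {[p[3] for p in kept]}")

qs = bh_qvalues([p[4] for p in kept], m_override=2_700_000_000)
for peak, q in zip(kept, qs):
    print(f"  {peak[3]}: p={peak[4]:.1e} -> q={q:.3g}")

# small variant summaries used in the same benchmarking reports
print(f"Ti/Tv of {{A>G, C>T, A>T, G>C}}: {titv([('A','G'),('C','T'),('A','T'),('G','C')])[0]}")
print(f"in-frame fraction of indel sizes [3,6,9,4]: {inframe_fraction([3,6,9,4])}")
# With m fixed at the genome size, even a 1e-12 peak p-value maps to a
# q-score near 2.7e-3: the correction is deliberately conservative.
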