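"""Read-level QC toolbox: Tn5 correction, consensus peaks, FRiP, correlation.

Small constructed inputs show each quality-control convention: the +4/-5
Tn5 insertion-site shift, the 50%-overlap replicate-consensus rule for
pooled peaks, signal quantification by 5'-end counting, FRiP, and replicate
Pearson correlation of log10-RPM signal.
"""

import numpy as np
import pandas as pd

from acrage import consensus_acrs, frip, quantify_signal, replicate_correlation, tn5_correct

# Tn5 correction: the transposase duplicates 9 bp; plus-strand 5' ends shift
# +4 and minus-strand ends -5 so both report the insertion centre
reads = pd.DataFrame(
    {"chrom": ["chr1", "chr1"], "pos": [100, 200], "strand": ["+", "-"]}
)
print("raw 5' ends :", reads["pos"].tolist())
print("corrected   :", tn5_correct(reads)["pos"].tolist(), "(+4 / -5)")

# replicate consensus: pooled peak kept iff every replicate overlaps >= 50%
pooled = pd.DataFrame([("chr1", 100, 200), ("chr1", 500, 600)],
                      columns=["chrom", "start", "end"])
rep1 = pd.DataFrame([("chr1", 100, 180), ("chr1", 500, 540)],
                    columns=["chrom", "start", "end"])  # 80% and 40%
rep2 = pd.DataFrame([("chr1", 120, 200), ("chr1", 500, 600)],
                    columns=["chrom", "start", "end"])  # 80% and 100%
kept = consensus_acrs(pooled, [rep1, rep2], min_frac=0.5)
print(f"\nconsensus: {len(kept)} of {len(pooled)} pooled peaks retained "
      "(the second fails the 50% rule in replicate 1)")

# signal and FRiP on toy reads: 30 of 100 5' ends inside the one ACR
rng = np.random.default_rng(0)
inside = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(100, 200, 30), "strand": "+"})
outside = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1000, 9000, 70), "strand": "+"})
all_reads = pd.concat([inside, outside], ignore_index=True)
acrs = kept
table = quantify_signal(all_reads, acrs)
print(f"\nACR counts: {table['count'].tolist()}, RPM: {table['rpm'].round(0).tolist()}")
print(f"FRiP = {frip(all_reads, acrs):.2f}  (> 0.2 passes the quality bound)")

# replicate correlation: r = 1 for a duplicated replicate
rows = []
for rep in ("rep1", "rep2"):
    for i, v in enumerate([2.0, 8.0, 32.0, 128.0]):
        rows.append((f"acr{i}", "st1", rep, v, v, np.log10(v)))
tab = pd.DataFrame(rows, columns=["acr_id", "stage", "replicate", "count", "rpm", "log10_rpm"])
corr = replicate_correlation(tab)
print(f"\nPearson r (duplicated replicate): {corr.loc['rep1', 'rep2']:.3f}")
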