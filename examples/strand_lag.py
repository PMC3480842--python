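"""Estimating the inter-strand lag of a peak by cross-correlation.

Sequencing reads come from fragment ends, so forward-strand coverage peaks
upstream of a binding site and reverse-strand coverage downstream.  The lag
that maximizes the sliding dot product of the two profiles estimates that
offset; true binding sites show a clear positive lag, coincident profiles
do not.
"""

import numpy as np

from triform import ReadAlignment, best_lag, build_track

rng = np.random.default_rng(7)
site = 5_000
fragment, read_len = 200, 36

fwd_reads, rev_reads = [], []
for _ in range(60):
    start = int(rng.normal(site - fragment / 2, 20))
    fwd_reads.append(ReadAlignment("chr1", start, start + read_len, "+"))
    end = int(rng.normal(site + fragment / 2, 20))
    rev_reads.append(ReadAlignment("chr1", end - read_len, end, "-"))

fwd = build_track(sorted(fwd_reads, key=lambda r: r.start), "+", 100)
rev = build_track(sorted(rev_reads, key=lambda r: r.start), "-", 100)

lag = best_lag(fwd, rev, site - 400, site + 400, max_lag=300)
print(f"binding site at {site}, fragment {fragment} bp, reads {read_len} bp")
print(f"estimated inter-strand lag: {lag} bp")
print(f"expected for 5'-anchored extension to w=100: {fragment - 100} bp")
print("(a lag near the expectation and above min.lag marks a real peak;")
print(" artifacts without strand structure fail this test)")
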