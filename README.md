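# triform

Model-free peak finding for transcription-factor ChIP-Seq.

Chromatin immunoprecipitation followed by sequencing maps where a
transcription factor binds DNA: mapped reads pile up around each binding
site. Many callers define a peak merely as "significantly elevated
coverage" and consequently accept *noisy plateaus* — wide blocks of
elevated coverage with no peak-shaped core and no strand structure. This
package implements the Triform approach instead: a peak is a region whose
coverage profile has a significantly peak-like *shape*, tested with fully
nonparametric Poisson contrasts (Hoel tests), confirmed by enrichment over
a matched control and by the characteristic offset between forward- and
reverse-strand coverage. It is aimed at anyone calling TF binding sites
from stranded aligned reads (BED input) and at method developers who want
a small, fully testable reference implementation with a built-in
ground-truth simulator.

## The statistics

Coverage `C_x` at position `x` (reads extended to a fixed width
`w = 100 bp`) is treated as a Poisson count with unknown rate
`λ_x = E[C_x]`. With flank spacing `δ = 150 bp`, three peak-like shapes
are tested through normalized contrasts that are approximately standard
normal under rate equality:

```
z1 = (2·C_x − C_{x−δ} − C_{x+δ}) / sqrt(2·(C_{x−δ} + C_x + C_{x+δ}))   Form 1: peak with two shoulders
z2 = (C_x − C_{x−δ}) / sqrt(C_{x−δ} + C_x)                             Form 2: rising edge
z3 = (C_x − C_{x+δ}) / sqrt(C_x + C_{x+δ})                             Form 3: falling edge
```

Local enrichment over the control coverage `B_x`, with `r` the
control/ChIP library-size ratio:

```
z4 = (r·C_x − B_x) / sqrt(r·(C_x + B_x))        ER_x = (1 + r·C_x) / (1 + B_x)
```

A region is called on one strand when every position has form-z and z4
above `min.z` (default: the normal 0.9 quantile, p = 0.1), its width
exceeds `min.n = 10 bp`, its center enrichment ratio exceeds `min.er`
(the 3/8 quantile of Form-1 enrichment ratios on that strand) and, with
replicates, every replicate agrees in sign. Forward and reverse regions
of the same form are paired when they overlap uniquely, must show an
inter-strand cross-correlation lag above `min.lag = 10 bp`, and are
scored with `PEAK.NLP` — the sum of the two strands' `−log10 p` — at the
reported location `PEAK.LOC`, the span midpoint. Partial forms merge into
Form-1 peaks; redundant ones are dropped.

## Worked example

`python examples/simulate_and_call.py` plants 12 binding sites on a
400 kb genome (200 bp fragments sequenced for 36 bp, Poisson background
in ChIP and control), calls peaks with default parameters and prints:

```
simulated 4930 ChIP and 3902 control reads, 12 planted sites

library ratio r = 0.791, min.er = {'+': 3.37, '-': 3.37}
stage counts: {'detected_form1_+': 68, ..., 'pairs': 36, 'after_lag': 36, 'final': 12}

top peaks (of 12):
  CHR    START     END      LOC     NLP    FORM  LAG
  chr1   290367   290611   290489   43.62   1    96
  chr1   113219   113467   113343   42.37   1    105
  ...

recall 1.000, false-discovery proportion 0.000, median positional error 2.5 bp
```

All 12 planted sites are recovered with a median location error of
2.5 bp; the lag column sits near 100 bp, the expected strand offset for
200 bp fragments after extension to `w = 100`. The other examples show
the Hoel statistics on small counts (`examples/hoel_statistics.py`) and
lag estimation in isolation (`examples/strand_lag.py`).

The same workflow from the shell:

```sh
triform simulate --out-dir sim --n-sites 50 --seed 1
triform call --chip sim/chip.bed --control sim/control.bed --out peaks.txt
triform evaluate --peaks peaks.txt --truth sim/truth.tsv --tol 100
```

`call` writes a tab-delimited peak table (1-based inclusive coordinates,
sorted by descending `PEAK.NLP`), optional BED, and a metadata JSON with
the parameter set, library sizes, `r`, per-strand `min.er` and the number
of candidates surviving each stage.

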