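# Methods

## Model and procedure

Coverage at each strand position, after read extension, is modelled as a
Poisson variate with an unspecified, position-dependent rate. Nothing is
assumed about the background: every test is a normalized linear contrast
of independently measured Poisson counts (a Hoel test), divided by the
square root of an unbiased estimate of the contrast's null variance. Such
statistics are close to standard normal even at low counts, so fixed
normal quantiles can serve as genome-wide detection thresholds without
fitting any background model. The four contrasts are `z1` (center vs.
mean of both δ-flanks — equivalently, a significantly negative discrete
second derivative of the coverage profile), `z2`/`z3` (center vs. one
flank: rising/falling edges), and `z4` (library-scaled ChIP vs. control).
For `z4`, under rate equality `r·λ = μ`, `Var(r·C − B) = r²λ + μ =
μ(1 + r) = E[r·(C + B)]`, which fixes the denominator `sqrt(r·(C + B))`;
the analogous argument fixes the form-statistic denominators.

Detection proceeds per chromosome, strand and form: maximal runs of
positions with form-z and `z4` both strictly above `min.z` and width
strictly above `min.n`; then a per-strand enrichment cut-off `min.er`
(quantile of Form-1 center enrichment ratios) applied to all forms; an
optional replicate sign test; unique cross-strand overlap pairing within
form; a strict inter-strand lag threshold; Fisher-combined scoring
(`PEAK.NLP` is the sum of the two strand NLPs, so `2·ln10·PEAK.NLP` is a
χ² statistic on 4 df under the joint null); and finally form resolution
(Form-2/3 peaks overlapping a Form-1 peak are redundant and dropped;
overlapping Form-2 + Form-3 peaks merge into a Form-1 peak with summed
score and maximal lag; any residual overlap keeps the higher score).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 100 bp | fixed width every read is extended to before coverage accumulation; must be even |
| `delta` (δ) | 150 bp | spacing between center and flank test positions; must exceed `w`; comparable to nucleosomal DNA length |
| `min.z` | Φ⁻¹(0.9) ≈ 1.2816 | upper-tail z cut-off for all tests, parameterized by its tail probability p = 0.1 |
| `min.n` | 10 bp | minimum region width (strict) |
| `min.er` quantile | 3/8 | quantile of Form-1 enrichment ratios defining the per-strand ER cut-off; computed with the type-7 (linear interpolation) convention |
| `min.lag` | 10 bp | minimum inter-strand lag (strict) |
| `r` | computed | control/ChIP library-size ratio; overridable |

`min.er` exists because non-specific ChIP coverage typically exceeds the
control's, so `z4` alone under-filters; making it a quantile of the
Form-1 ER population adapts the cut-off to the data set. The choice of
quantile is not critical in signal-rich data, but see the caveat under
*Limitations*.

## Read extension anchor

"Symmetric extension to w" leaves open where the extended interval is
anchored; both midpoint anchoring and 5′-anchored directional extension
are common in ChIP-Seq tools, and the package implements both
(`Parameters.extension_anchor`). The default is **5′-anchored**: each
read is replaced by the `w`-bp window starting at its 5′ end and growing
in the read's direction, i.e. into the sequenced fragment. The reason is
geometric. For fragment length `F` and read length `L`, the forward and
reverse read-center clusters sit `F − L` apart (≈ 164 bp for `F = 200`,
`L = 36`). Midpoint anchoring keeps the extended coverage clusters at
that full separation, and with δ = 150 the detected per-strand regions
(half-width ≈ 75–85 bp at realistic depth) then usually fail to overlap
across strands, so pairing — and with it the whole caller — collapses;
measured end-to-end recall on simulated data was 0.16. The 5′ anchor
shifts each strand's cluster `(w − L)/2` toward the site, the profiles
end up `F − w` ≈ 100 bp apart, regions overlap around the site, and
recall on the same data is 1.00. A corollary is that the reported lag
concentrates near `F − w` (not `F − L`); the read-center separation
`F − L` remains visible in the unextended reads.

## Numerical choices

- NLP values are computed from the normal log-survival function, so
  z-scores of 40+ give finite scores instead of underflowing to an
  infinite `−log10 p`.
- All-zero count configurations map to z = 0 by convention (zero
  evidence), never NaN; strict `>` thresholds then correctly fail.
- Coverage tracks are run-length encoded over their nonzero support;
  statistics are evaluated densely only inside support windows (a
  position with zero ChIP coverage cannot pass any condition, so this
  sparsification is exact).
- The lag is the argmax over `k ∈ [0, min(range − 1, 2δ)]` of the raw
  sliding dot product between the strand profiles over the pair's
  δ-extended span; ties break toward the smallest lag, and the dot
  products are exact integer arithmetic. A constant-zero profile makes
  the lag undefined and the pair is dropped.
- Output ordering is descending `PEAK.NLP` with ties broken by
  (chromosome, start); detection is fully deterministic, so identical
  inputs give byte-identical peak tables.
- Span midpoints use floor division; the peak table is 1-based inclusive,
  BED output 0-based half-open.

## The simulator

`simulate_experiment` emulates exactly the structure the caller relies
on: per planted site, forward-read centers are drawn
`Normal(site − F/2 + L/2, σ)` and reverse-read centers mirrored
downstream (so fragment ends are sequenced, giving the strand shift);
per-site, per-strand read counts are Poisson; ChIP background and the
antibody-free control are uniform Poisson reads per strand; reads are
truncated at chromosome ends. Defaults — 2 Mb genome, 50 sites, `F =
200`, `L = 36`, 40 reads/site/strand, σ = 20 bp, background and control
at 0.005 reads/bp/strand — correspond to a well-powered TF experiment at
typical genome-wide depth (≈ 10⁷ reads per 3 Gb scales to 10⁴ per 2 Mb
strand). One seed sequence drives everything, with per-chromosome
substreams spawned deterministically.

What the simulator does *not* model: sequence content, mappability and
repeats, PCR duplicates, copy-number and chromatin-accessibility biases
in the control, overlapping/composite binding events, or fragment-length
dispersion beyond the per-read position jitter. Passing tests therefore
demonstrate the statistical machinery and the geometry of strand-aware
detection, not robustness to alignment artifacts; on real data those
artifacts are exactly where the control sample and the replicate filter
have to do their work.

`evaluate_calls` matches peaks to planted sites greedily in score order,
one-to-one, within a tolerance (default ±100 bp), reporting recall, the
false-discovery proportion and per-peak positional errors.

## Design choices where the design was open

- **Pairing scope**: cross-strand pairing is within the same form;
  any-form pairing is available (`same_form_pairing=False` /
  `--any-form-pairing`) but not default, as same-form pairing is the
  stricter and cleaner reading of "exactly one region on the opposite
  strand".
- **Merged-peak scoring**: a merged Form-2 + Form-3 peak sums its
  constituents' scores (keeping the Fisher interpretation, now over four
  strand tests) and takes the larger lag; merged peaks are not re-tested
  against the per-strand conditions their constituents already passed.
- **Peak span**: the union (not intersection) of the paired strand
  regions, so the reported midpoint is always defined and sits between
  the strand summits.
- **Strand-matched control**: `z4` at a forward-strand position uses
  forward-strand control coverage, mirroring the per-strand definition of
  every other statistic.
- **min.er two-pass**: Form-1 regions are detected first under the fixed
  conditions, their ER distribution defines `min.er`, and the filter is
  then applied to all forms — the cut-off has to come from detected
  regions, since it is defined in terms of them.

## Problem sizes

The test suite exercises the full caller on 300 kb–2 Mb simulated
genomes with 8–50 sites (seconds per run on one core); null-calibration
checks use 10⁵ Monte-Carlo draws. These sizes give stable estimates of
recall, FDP and positional error while keeping the whole suite around
half a minute; the caller itself is linear in coverage support and
handles full-genome BED inputs chromosome by chromosome.

## Limitations

- The adaptive `min.er` quantile presumes a Form-1 population dominated
  by weak background regions, which holds at realistic background
  density. In *signal-dominated* inputs (strong sites, almost no
  background) the quantile lands inside the true-peak ER distribution
  and removes real peaks; in *background-only* inputs it adapts downward
  and passes the upper tail of the noise, so a matched null experiment
  still yields a floor of roughly one spurious (low-NLP) peak per
  megabase at default thresholds. Ranking by `PEAK.NLP` separates these
  from real calls; a global significance floor is deliberately out of
  scope.
- No FDR/q-value estimation, artifact blacklists, or duplicate-read
  removal; input reads are taken as given.
- BED6 is the only read input format (SAM/BAM converters are
  one-liners with standard tools); no bigWig output.
- The method is designed for point-source TF binding; broad marks
  (chromatin-domain ChIP-Seq) violate the peak-shape model.
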