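# Methods

## Scope and model

`minichip` implements the data-preparation and data-analysis half of a
miniaturized promoter tiling-array ChIP–chip study: two-color arrays tiling
−8.2 kb/+3 kb windows around transcriptional start sites at ~100 bp probe
spacing, with a ChIP sample in one channel (R) and total input in the other
(G). The per-probe observable is the MA pair `M = log2(R/G)`,
`A = ½·log2(R·G)`; everything downstream of the scanner is modelled on the
M scale. Coordinates are 0-based half-open internally and in BED output;
GFF output is 1-based inclusive.

## Synthetic-data generator

The generator exists so that every pipeline contract can be tested against
known ground truth. It emulates, per array:

- a probe-intrinsic baseline log2 intensity (`baseline_a ~ N(10, 1)`),
  shared across replicates, standing in for sequence-dependent
  hybridization affinity; probe GC fraction is drawn tightly coupled to it
  so GC bins approximate A bins;
- mark-specific spatial enrichment profiles added to the true M of truly
  enriched promoters: a TSS-flanking double Gaussian with a trough at the
  TSS (H3K4me3-like), downstream gene-body bumps (H3K36me3/H3K79me2-like)
  and a broad multi-Gaussian plateau (H3K27me3/H3K9me3-like). Exact bump
  parameters are generator-private; only the qualitative contracts
  (trough at the TSS, downstream mass, broad span) are part of the API;
- a smooth quadratic-in-A dye-bias curve of configurable amplitude added to
  M — the minimal distortion producing the banana-shaped raw MA plot that
  within-array normalization must flatten; scanner physics is not modelled;
- a per-replicate scale shift (between-array batch effect) and i.i.d.
  Gaussian log2 probe noise.

Channels are back-computed as `R = 2^(A + M/2)`, `G = 2^(A − M/2)`, so with
all distortions at zero the MA transform recovers the true ratio exactly
(the round-trip anchor test).

Expression is a shared log-normal base per gene plus additive ±1.5 log2
units per truth mark (activating +, silencing −). A second cell type
re-draws each gene×mark truth value with probability 0.2 and recomputes
expression from its own truth, so expression fold changes between cell
types are coupled to chromatin changes — the structure the integration
stage is designed to detect.

Defaults (chosen once as field-plausible desk-scale conditions; the
literature gives no canonical values for these magnitudes): probe noise SD
0.35 log2, dye-bias amplitude 0.5 log2, replicate scale shifts ≤ 0.3 log2,
mark effect sizes 1.5–2.5 log2, enriched-gene fractions 0.15–0.40,
200 genes × 3 replicates for simulation studies. All randomness flows from
a single integer seed through `numpy.random.SeedSequence` spawn keys;
identical seeds give bit-identical outputs.

What the generator does **not** emulate: probe sequence design,
cross-hybridization, whole-genome-amplification bias, spatial slide
artifacts, heavy-tailed outlier spots. Passing tests therefore demonstrate
that the procedure behaves as specified under its own assumptions, not
that those assumptions hold for any particular real dataset.

## Normalization

Within-array correction offers two methods. `a_lowess` subtracts a lowess
trend of M on A (`frac = 0.3`, with the `delta` interpolation shortcut set
to 1 % of the A range so the fit stays linear-time on full-size arrays).
`gc_bins` robustly standardizes M within 20 probe-GC bins (subtract bin
median, divide by bin MAD, restore the global MAD scale); it requires probe
GC annotations and is the closer analogue of model-based GC normalization.
The acceptance contract for either method is MA flatness: |median M| per
A-decile below 0.05 (configurable) after correction.

Quantile normalization operates on M values (the peak caller consumes M,
and per-channel quantile alignment would not guarantee aligned ratio
distributions). It is restricted to replicates of one mark in one cell
type; crossing cell types would erase biological differences and is a hard
error. Ties receive the mean of the tied ranks' quantile means
(deterministic and permutation-invariant). Replicate averaging is the
per-probe arithmetic mean of M (and A).

## Peak calling

A window of 500 bp is *hit* when it contains ≥ 4 above-cutoff probes that
are adjacent — consecutive in array layout with an inter-probe gap of at
most 2× the probe spacing (larger gaps break adjacency; the spacing is
inferred as the median inter-probe gap per chromosome). Overlapping hit
windows are merged and each merged span becomes a region running between
its outermost above-cutoff probes (end = last probe start + spacing).
These exact semantics are pinned by a brute-force enumeration oracle over
all window placements in the test suite; note they can trim or split a
long adjacency run where no single window holds four above-cutoff probes.

The "theoretical maximum enrichment value" anchoring the cutoff ramp is
`mean(M) + 6·sd(M)` by default (`max_observed` is available); cutoffs sweep
90 % down to 15 % of it in 5 % steps (16 levels). Final peaks are the
regions at the lowest cutoff, scored by the highest level at which any
sub-region is still detected; the score is stored both as that percentage
and as the corresponding log2 threshold (used downstream).

FDR: the M values are permuted (within chromosomes by default, preserving
per-chromosome probe counts; permutation is distribution-preserving, so the
theoretical maximum is unchanged by construction) and the full sweep re-run
20 times. For each score level s,
`FDR(s) = mean permuted peak count at score ≥ s / observed count at ≥ s`,
clipped to [0, 1] and made monotone non-increasing in s by a running
minimum from low to high scores. With 20 permutations the estimates are
Monte-Carlo; the reported strict-tier behaviour is validated empirically
(≥ 50-simulation null studies in the acceptance suite) rather than assumed
exact. Tiers: strict FDR ≤ 0.05 (drives all present/absent calls), relaxed
0.05 < FDR ≤ 0.2 (quality control only), else discarded.

A diagnostic `merge_fragmented_peaks` joins peaks separated by ≤ a gap
threshold, reflecting that hybridization artifacts fragment single enriched
regions — which is also why all quantitative summaries use bound area ×
score rather than peak count.

## Annotation and integration

Promoter windows are applied in transcription orientation (upstream means
5′ of the TSS on the gene's strand). A peak's reference point is its
midpoint (an any-overlap mode exists); among genes whose window contains
it, the nearest TSS wins, with exact distance ties resolved toward the gene
earlier in coordinate order — deterministic and logged. Enrichment is
present/absent: ≥ 1 strict peak.

Net enrichment per gene: each polarity's Σ(bound area × log2 score) over
strict peaks is divided by the number of that polarity's marks present
(≥ 1 strict peak) at the promoter, and the silencing quotient is
subtracted. The per-polarity normalization keeps promoters assayed with
more marks from dominating; an unnormalized variant is switchable. The
statistic is additive in peaks: splitting a peak with conserved total
area × score leaves it unchanged.

Expression binning sorts genes by expression and forms consecutive bins of
100 (short final bin flagged); the cross-bin association is summarized by
Spearman rank correlation. The fold-change analysis contrasts two cell
types at thresholds 1.5–7.0 in 0.5 steps (12 categories per direction),
using per-mark max strict log2 peak score (0 when absent) and a
pseudocount of 1 expression unit in the fold-change ratio.

## qPCR

Percent input uses the dilution-corrected convention
`100 · 2^[(Ct_input − log2(1/f)) − Ct_chip]` with input fraction `f`
(default 0.1): one PCR cycle is exactly a factor of two, and equal Ct gives
`100·f` %. A `formula="literal"` switch evaluates the uncorrected
expression `100 · 2^(Ct_chip − Ct_input·(1/f))` for comparison only — with
the dilution factor multiplying a cycle number inside the exponent it
produces absurd magnitudes and is never used by the pipeline. Triplicate
Cts are averaged on the Ct scale before the formula, with the replicate SD
propagated as a log2 uncertainty. Primer qualification fits Ct against
log2 template mass by least squares, requires the slope within a tolerance
of −1 (efficiency `2^(−1/slope) − 1`) and a single melt-curve amplicon.

## Quality control

Every QC verdict is a pure function of its inputs and explicit thresholds:
MA flatness per A-decile (fail above 0.05 after correction), pairwise
replicate Pearson r on M (warn threshold 0.4 by default — probe-level
correlations on noisy miniaturized arrays sit well below gene-level ones —
on a seeded 10,000-probe subsample for large arrays), identity of
five-number summaries after quantile normalization, convergence of
strict-tier bound bp across replicates (outlier factor 2× from the median
flags failed ChIPs), and TSS-distance histograms in 500 bp bins matching
the detection window. The battery detects injected dye bias, between-array
scale shifts and dead replicates in ≥ 95 % of seeded simulations (tested).

## Problem sizes

Simulation studies in the tests and the acceptance script use 20–400 genes
(2,240–44,800 probes), 2–3 replicates and 20 FDR permutations — sizes
chosen so a complete study runs in seconds while leaving every contract
(window geometry, FDR behaviour, truth recovery, expression coupling)
statistically resolvable. The null-FDR experiment uses 50 independent
200-gene studies.

## Known limitations

- The FDR estimator is Monte-Carlo over few permutations and score levels;
  it is validated as an operating characteristic, not as an exact per-peak
  probability.
- Broad silencing domains are handled by the same window rule as sharp
  peaks; no segmentation model (HMM/wavelet) is provided.
- Cross-cell-type comparability is deliberately out of scope beyond the
  refusal to quantile-normalize across cell types; the housekeeping-panel
  check is exposed only as data (per-gene bound bp), with no pass/fail
  rule.
- Missing-probe handling is minimal: failed spots are rejected at the MA
  transform (hard error above 5 %); tracks entering quantile normalization
  must share a complete probe set.
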