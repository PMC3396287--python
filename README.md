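# minichip

Analysis pipeline for two-color **promoter tiling-array ChIP–chip** data from
miniaturized (≈10,000-cell) chromatin immunoprecipitation experiments. The
package covers the full data path from raw two-channel probe intensities to
per-promoter chromatin state and its relation to gene expression, and ships a
synthetic-data generator that emulates the array structure so every stage is
testable without any external download.

It is written for epigenomics analysts who need a transparent, reproducible
reference implementation of the classic promoter-array workflow:

1. **Within-array normalization** — each array's probe ratios are put on the
   MA scale, `M = log2(R/G)`, `A = ½·log2(R·G)` (R = ChIP channel,
   G = input channel), and the intensity-dependent dye bias is removed by
   A-lowess or GC-binned robust standardization; success is judged by the
   MA-plot contract (median M per A-decile ≈ 0).
2. **Between-array quantile normalization** — across replicate arrays of one
   mark in one cell type only (never across cell types), each rank's values
   are replaced by the cross-array mean at that rank; replicates are then
   averaged per probe.
3. **Peak calling** — regions of ≥ 4 adjacent probes above a cutoff inside a
   sliding 500 bp window; cutoffs sweep 90 % → 15 % of a theoretical maximum
   enrichment value (mean(M) + 6·sd(M) by default) in 5 % steps. A peak's
   score is the highest cutoff at which it is still detected.
4. **Permutation FDR** — the ratio data are permuted (within chromosomes)
   and the full sweep re-run; peaks are tiered strict (FDR ≤ 0.05, used for
   all present/absent calls) or relaxed (0.05 < FDR ≤ 0.2, QC only).
5. **Promoter annotation** — each peak is uniquely linked to the most
   proximate TSS whose strand-oriented −8.2 kb/+3 kb window contains its
   midpoint; a promoter is *enriched* for a mark iff ≥ 1 strict peak is
   assigned.
6. **Net enrichment** — per gene,
   `net = S_act / max(1, n_act) − S_sil / max(1, n_sil)` where `S` sums
   bound-area × peak-score over strict peaks of activating
   (H3K4me3, H3ac, H3K79me2, PolII) or silencing (H3K27me3, H3K9me3) marks
   and `n` counts the present marks of each polarity; genes are binned by
   expression (100 per bin) and contrasted across expression fold-change
   categories between cell types.
7. **qPCR** — percent-input quantification,
   `% input = 100 · 2^[(Ct_input − log2(1/f)) − Ct_chip]` for input fraction
   `f`, plus primer standard-curve qualification.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(300 promoters, five marks, two cell types, triplicate arrays; the heavy
run directory goes to `scratch/study/`, summary tables to `results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_normalize_arrays.py
python analysis/03_call_peaks.py
python analysis/04_annotate_promoters.py
python analysis/05_integrate_expression.py
python analysis/06_qc_report.py
```

Representative output (seed 2024):

```
stem/H3K4me3: |median M| per A-decile 1.293 -> 0.029
stem/H3K4me3: 116 peaks (116 strict, 0 relaxed), 199300 bp bound at FDR<=0.05
 H3K4me3  stem  300  116  0.386667   0.386667     # called vs true occupancy
stem: Spearman(bin mean net enrichment, bin mean expression) = 1.000 over 3 bins of 100
```

Reading: the A-lowess step flattens a raw dye bias of ~1.3 log2 units to
under 0.03; the caller recovers essentially one strict peak per truly
enriched promoter, so the called occupancy fraction matches the simulation
ground truth; and binned net enrichment rises monotonically with binned
expression, the expected activating-vs-silencing signature.

The same stages are available as a CLI
(`minichip simulate|normalize|callpeaks|annotate|integrate|qc|qpcr|run`)
and as a resumable end-to-end pipeline (`minichip run --outdir RUN --seed N`).

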