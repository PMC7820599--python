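# superchrom

Desk-scale analysis of super-enhancer landscapes in chromatin profiling
data, built around the workflow used to dissect lineage-determining
transcription-factor function in mast cells: which genes carry
super-enhancers, how densely those enhancers are bound by a factor such as
GATA2, and what happens to accessibility, histone marks and expression when
the factor is removed or the cells are activated.

It is aimed at computational biologists who have peak-level ChIP-seq /
ATAC-seq data (BED with signal), a gene table with expression, and motif
matrices — and who want the downstream enhancer analysis without a cluster:
everything here runs in seconds on one CPU. A built-in simulator generates
complete landscapes with known ground truth, so every stage of the pipeline
can be validated quantitatively before it touches real data.

## What it computes

- **Enhancer definition and SE calling (ROSE-style).** Potential enhancers
  are H3K27ac peaks that also carry H3K4me1. Peaks wholly inside TSS ± 2.5 kb
  are removed, the rest are stitched when gaps are ≤ 12.5 kb, and stitched
  regions are ranked by combined H3K27ac signal. With rank and signal
  rescaled to [0, 1], the SE/TE threshold sits at the inflection point where
  a line of slope 1 is tangent to the ranked curve; enhancers above it are
  super-enhancers (SE), the rest typical enhancers (TE).
- **Gene assignment (GREAT basal-plus-extension).** Each gene owns a basal
  domain (TSS −5 kb / +1 kb, strand-aware) extended up to 100 kb but
  truncated at the nearest neighbouring basal domain; enhancers are assigned
  to every expressed gene (RPKM > 30) whose extended domain they overlap.
- **Regulatory potential (BETA-minus).** For gene *g* with peaks *i* within
  100 kb of the TSS,
  `S_g = Σ_i exp(−(0.5 + 4Δ_i))`, `Δ_i = |center_i − TSS| / 100 kb`.
- **Occupancy metrics.** Reads at enhancers per gene (replicate-averaged,
  paired-end-halved), TF-bound sites per gene, and per-kilobase densities
  normalized by the mean assigned-enhancer size; 10-kb binned Pearson
  reproducibility; strand-aware TSS meta-profiles.
- **Motif counting (FIMO-style).** PWM log-odds scanning of both strands
  with *exact* null p-values from a dynamic-programming convolution of the
  discretized score distribution (1/1000-bit grid), plus IUPAC consensus
  counting (e.g. WGATAR).
- **Activation and knockout contrasts.** Fold-class induction labels
  (highly induced > 10×, induced 2–10×, unchanged 0.5–2×, repressed < 0.5×,
  FPKM < 30 filtered), detection of activation-increased regions by a
  declared fold rule, intersection into activation-induced enhancers, SE
  enrichment folds, and per-gene-class percent reductions after knockout.

## Worked example

Simulate a resting landscape with planted ground truth and run the identity
analysis:

```python
import superchrom as sc

bundle = sc.generate_landscape(seed=7)
result = sc.run_identity_analysis(
    genes=bundle.genes, k27ac=bundle.k27ac, k4me1=bundle.k4me1,
    atac=bundle.atac, gata2=bundle.gata2, sequences=bundle.sequences,
    chrom_sizes=bundle.chrom_sizes,
)
s = result["summary"]
print(f"stitched enhancers: {s['n_stitched_enhancers']} "
      f"({s['n_super_enhancers']} SE, {s['n_typical_enhancers']} TE)")
```

prints, for this seed:

```
stitched enhancers: 280 (30 SE, 250 TE)
SE/TE mean length ratio:   11.7
ID-gene SE association:    0.40 vs 0.040 (fold 10.1)
GATA2 site density SE/TE:  2.18
GATA motif count SE/TE:    3.09
expression (median FPKM):  SE genes 1721669, TE genes 43 (rank test p = 4.54e-16)
```

Reading the numbers: the stitcher recovered 280 enhancers and the ranked-curve
tangency split off 30 super-enhancers (the generator planted SEs at ~11% of
expressed genes). Super-enhancers are ~12× longer than typical enhancers,
identity genes are ~10-fold more likely to carry one, GATA2-bound-site
density per kb is about twice as high inside them, GATA motifs are ~3× more
frequent per gene, and SE genes are expressed far above TE genes — the
structure the generator plants and the pipeline is designed to measure.
(Expression is simulated on an exponential scale from regulatory potential,
so absolute FPKM values for SE genes are extreme; the rank test, not the
magnitude, is the meaningful readout.)

The same analyses are available from the shell:

```bash
superchrom simulate --out sim/            # bundle + knockout/ + stimulated/
superchrom call-se --k27ac sim/h3k27ac.bed --k4me1 sim/h3k4me1.bed \
                   --genes sim/genes.tsv --out enhancers.bed
superchrom run-identity --dir sim/ --out report/
superchrom run-knockout --wt-dir sim/ --ko-dir sim/knockout --out ko_report/
```

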