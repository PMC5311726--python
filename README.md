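# nucrnai

Binned quantification and differential statistics for nuclear-RNAi-style
chromatin genomics: weighted ChIP-seq / Pol II / pre-mRNA coverage on a
fixed 1-kb bin grid, mutant-vs-WT ratio tracks with exact count-based
fold-change/FDR boundary curves, dependency-region calling, percentile
region classes with group-level boxplot/Welch statistics, ddCT qPCR fold
changes, and a synthetic-data generator that drives every stage without any
external download.

## What's inside

| module | role |
| --- | --- |
| `nucrnai.layout` | chromosomes + fixed-width bin grid (the shared coordinate system) |
| `nucrnai.coverage` | 1/N multi-mapper weighting, bin counting, depth / background-median normalization, 50-kb moving average, stranded coverage |
| `nucrnai.samio` | SAM (pysam, `NH` tag) and BED6 read dialects, chrom.sizes |
| `nucrnai.differential` | ratio tracks, conditional-binomial bin test, BH-corrected fold-change calls with boundary curves, dependency regions, kb Venn overlaps |
| `nucrnai.regionstats` | top-percentile / background-band region classes, group boxplot stats, Welch t test |
| `nucrnai.qpcr` | ddCT fold changes and multigenerational heritable-silencing profiles |
| `nucrnai.simulate` | synthetic genomes, planted enriched domains, aligned reads (incl. multi-mappers), stranded pre-mRNA, qPCR plates — with ground-truth BEDs |
| `nucrnai.pipeline` / `nucrnai.cli` | end-to-end orchestration, manifest, figures |

## CLI

```sh
nucrnai run-all --seed 1 --out demo_run        # full synthetic pipeline
nucrnai simulate --seed 1 --genotype WT --genotype mut --out sim/
nucrnai coverage --alignments sim/H3K9me3_WT_rep1.sam \
    --chrom-sizes sim/chrom.sizes --bin-size 1000 --out wt_cov
nucrnai diff --mutant m1.sam,m2.sam --wt w1.sam,w2.sam \
    --chrom-sizes sim/chrom.sizes --fold 2 --alpha 0.05 --max-delta 0.5 --out diff
nucrnai regions --wt-track w1.sam --chrom-sizes sim/chrom.sizes \
    --top-pct 5 --band 5,25 --out classes
nucrnai groupstats --ratio diff.scatter.tsv --chrom-sizes sim/chrom.sizes \
    --regions grts.bed,grh.bed --ref-regions classes.negative.bed --out stats.tsv
nucrnai qpcr --plates plates/ --out profile.tsv
```

Exit codes: 0 success, 2 validation/configuration error, 1 runtime failure.
`run-all` writes a `manifest.json` with a SHA-256 per output; identical
config + seed reproduces byte-identical data files.

## Method notes

- A read aligned to N loci contributes weight 1/N at each placement, so a
  raw track's total equals the distinct read count (checked by a mass-
  conservation property test).
- Per-bin significance is a conditional binomial test — given a bin's
  pooled count n, the count in library A is Binomial(n, depth_A /
  (depth_A + depth_B)) under the null — with Benjamini–Hochberg correction
  over non-empty bins, combined with a hard fold cutoff. The scatter-plot
  boundary curve is the exact frontier of that joint rule.
- Dependency regions require ratio ≤ 0.5 with adjusted p < 0.05 in every
  replicate pair; adjacent qualifying bins merge, and totals are reported
  in kb.
- Background-median normalization re-anchors heterochromatin-mark tracks on
  a background region class so genome-wide signal loss does not inflate the
  apparent mutant background.

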