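# genelen

Gene-length-dependent expression analysis for bulk and single-cell
transcriptomes.

Neurons preferentially express long genes, and several brain conditions
shift expression as a function of gene length — up-regulation of long genes
within cells, down-regulation of long genes at the tissue level when
long-gene-rich cell types are lost. Detecting such effects needs a
statistic that is a *function of length*, not a single number. `genelen`
implements the standard recipe:

1. **Length-ordered sliding-window curve.** After platform normalization
   (probe collapsing for microarray intensities, exon-density
   normalization for RNA-seq counts, then quantile normalization across
   samples), compute the per-gene log2 fold change between conditions,
   `logFC_g = mean(case) − mean(control)` with variance
   `var(case) + var(control)`. Sort genes by genomic length and average
   `logFC` over windows of 200 consecutive genes advanced in steps of 40;
   plot the window mean (± s.e.m.) against the mean window length.
2. **Shuffle null envelope.** Under the null that expression change is
   independent of length, randomly re-pair the per-gene statistics with
   the gene lengths, recompute the curve, and repeat (default 100
   iterations). The pointwise 2.5%/97.5% quantiles across iterations form
   a 95% null band; observed windows strictly outside it are flagged.
3. **DE length-shift test.** Call differentially expressed genes with an
   uncorrected per-gene two-sample t-test (p < 0.01), then compare the
   lengths of the up- and down-regulated sets with the lengths of all
   analyzed genes by a two-sample t-test, Bonferroni-corrected over the
   family of tests.

A fully synthetic data generator plants known length slopes
(log2-fold-change units per log10 bp) and cell-type composition shifts, so
every stage is testable end-to-end without any external data.

## Worked example

Simulate a 3,000-gene two-condition dataset with a planted slope of
+0.4 log2 units per log10 bp, then run the full pipeline:

```python
from genelen import (SyntheticConfig, RunConfig, write_fixture_bundle,
                     run_pipeline, curve_slope)

cfg = SyntheticConfig(n_genes=3000, beta=0.4, noise_sd=0.5,
                      n_case=8, n_control=8, seed=11)
bundle = write_fixture_bundle("demo", cfg)
rc = RunConfig(matrix=str(bundle["matrix"]),
               annotation=str(bundle["annotation"]),
               condition_map=str(bundle["conditions"]),
               outdir="demo/out", seed=11)
result = run_pipeline(rc)
print(curve_slope(result.curve))
```

The run log records every stage:

```
loaded matrix: 3000 genes x 16 samples (intensity)
protein-coding filter -> 3000 genes
quantile normalization on log2 intensities
fold change: 3000 genes, 8 case vs 8 control
binned curve: 71 windows (window=200, step=40)
envelope flags: {'below': 30, 'above': 30, 'inside': 11}; mean exceedance -0.0006289
DE: 63 up, 67 down at p < 0.01
```

Because the planted slope is centered on the mean log10 length, short-gene
windows fall *below* the null envelope and long-gene windows *above* it
(30 windows each here — a strong length effect in both tails), and the
recovered curve slope is `0.394` against the planted `0.4`. The DE sets
show the matching length shift — up-regulated genes are long, down-regulated
genes short:

```
direction  n_set  mean_length_set  mean_length_all   p_bonferroni
up            63        210800.73         45849.78   9.6e-10
down          67          4815.33         45849.78   6.2e-129
```

The same analysis is available from the shell:

```sh
genelen simulate --out demo --seed 11 --n-genes 3000 --beta 0.4
genelen curve --matrix demo/matrix.tsv --annotation demo/annotation.tsv \
              --conditions demo/conditions.tsv --out demo/curve.tsv
genelen bootstrap --matrix demo/matrix.tsv --annotation demo/annotation.tsv \
              --conditions demo/conditions.tsv --seed 11 --out demo/env.tsv
genelen run --config run.yaml
```

Gene lengths can be supplied as a TSV (`gene_id, gene_length[,
exon_length, biotype]`) or derived from an Ensembl-dialect GTF
(genomic span of the gene feature; exon length as the merged exon-interval
union).

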