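# Methods

## The statistic

The pipeline asks whether expression change depends on gene length. For a
case/control contrast on log2 expression, the per-gene statistic is

    logFC_g = mean(case_g) − mean(control_g)
    var_g   = var(case_g) + var(control_g)      (ddof = 1; 0 when n = 1)

Genes are sorted ascending by genomic length (ties broken by gene id,
stable) and logFC is averaged over sliding windows of `window = 200`
consecutive genes advanced by `step = 40`. A trailing partial window is
dropped: every emitted window has exactly `window` members, so the number
of windows is `floor((n − window)/step) + 1` (493 for 19,881 genes). Each
window reports the mean member length in bp (mean, not median — recorded
in output headers), the mean logFC, and the s.e.m. computed from the
dispersion of the window's per-gene logFC values (sample sd / √window);
the per-gene variance field is carried through outputs but does not enter
the s.e.m. The same binning with a different windowed statistic (per-gene
mean log expression within a sample group) produces per-cell-type
mean-expression curves with no contrast.

Fold changes are computed in log2 throughout; a log10 rendering of a curve
is a display-scale choice, not a different statistic.

## Null envelope

The null — expression change independent of length — is emulated by
re-pairing the vector of per-gene statistics with the vector of lengths
uniformly at random. Both marginal multisets are preserved exactly; only
the pairing is destroyed. Each of `n_iterations = 100` iterations
recomputes the window means over the same length-sorted window grid; the
pointwise `(1−ci)/2` and `1−(1−ci)/2` empirical quantiles across
iterations (default `ci = 0.95`) form the envelope.

Numerical choices:

* The default re-pairing samples **without** replacement (a permutation).
  A with-replacement resampling mode is available behind
  `with_replacement=True` for comparison; it is not the default because
  the permutation preserves the statistic's empirical distribution
  exactly.
* Quantiles use linear interpolation between order statistics with the
  Weibull plotting position, so at 100 iterations the 2.5%/97.5% bounds
  interpolate between the 2nd–3rd and 98th–99th order statistics and a
  null draw escapes each side with probability ≈ 2.5%. (The numpy default
  position would make the envelope anti-conservative at ~3.4% per side.)
* Window flags use strict inequalities: a window mean exactly on a bound
  is `inside`.
* Envelopes are pointwise, per window; no simultaneous (max-statistic)
  band is computed. Overlapping windows share 160 of 200 genes, so
  exceedances are strongly correlated across neighboring windows — the
  *fraction* of windows outside the envelope is calibrated (≈5% under the
  null) but its replicate-to-replicate variance is large, and the band
  must not be read as a family-wise test.
* The shuffle acts on the final per-gene (logFC, length) pairing. Shuffling
  before the fold-change computation would be equivalent for this
  statistic, since logFC is computed per gene independently of length.
* The `envelope_distance` summary (mean signed exceedance over windows)
  measures how far a curve escapes the band; with a centered planted
  slope, below-band and above-band exceedances partially cancel in the
  mean, so its magnitude is most useful for one-sided effects.
* Every stochastic operation takes an explicit seed, which is recorded in
  the envelope TSV header; the full pipeline is byte-reproducible for a
  fixed seed.

## Normalization

* **Probe collapsing** (microarray): probes mapping to more than one gene
  are discarded; each gene's log2 row is the arithmetic mean of its
  remaining probes' rows. The input must already be on log2 scale.
* **Exon density** (RNA-seq): counts divided by the exon-union length in
  bp (reads per exonic base), a per-gene length normalization applied
  before any cross-sample normalization.
* **Quantile normalization**: every sample is forced onto the across-sample
  mean of order statistics; ties within a sample receive the mean of the
  reference values over their tied rank span (ties=average). Within-sample
  ranks are preserved; for tie-free data the operation is idempotent and
  all post-normalization sorted columns are identical to machine
  precision. Intensity data are quantile-normalized on the log2 scale;
  count data on the linear exon-density scale and then log2-transformed
  (pseudocount 1 for counts, 0 for intensity data, configurable); the
  applied order is recorded in the run log and is switchable via
  `quantile_on`.

## DE length-shift test

Per-gene DE calling uses a two-sided two-sample t-test at an uncorrected
`de_alpha = 0.01`, splitting significant genes by the sign of the mean
difference. Welch's unequal-variance form is the default for both the
per-gene test and the length comparison (`equal_var=True` gives the pooled
form); a gene with zero variance in both groups gets p = 1 when the means
are equal and p = 0 otherwise. The length-shift test compares each set's
lengths against **all** analyzed genes (the set included in the
reference); the overlap makes the test slightly conservative for large
sets, and a set-vs-complement variant is available. Bonferroni correction
multiplies by the family size, which defaults to the 2 direction tests of
a single contrast and should be overridden when several contrasts form one
family (e.g. 6 for two directions × three brain regions). Lengths enter
the t-test in bp by default; a log-length option exists because length
distributions are heavy-tailed. Boxplot summaries use type-7 (linear
interpolation) quartiles, whiskers at the most extreme datum within
1.5×IQR, and notch half-width 1.58×IQR/√n.

## Gene lengths and filtering

`gene_length` is the genomic span of the gene feature (end − start + 1,
strand ignored; lengths are strand-symmetric); `exon_length` is the union
of the gene's exon intervals with overlaps merged. Both can be read from a
delimited table or derived from an Ensembl-dialect GTF. Analysis is
restricted to protein-coding genes (biotype `protein_coding`) present in
both matrix and annotation; genes without annotation are dropped with a
logged count, and the run log records the gene count surviving every
stage.

## Synthetic data

The generator targets the statistical structure the analysis assumes, not
the empirical distributions of any real dataset.

* **Lengths**: truncated log-normal, log10 mean 4.3, log10 sd 0.6,
  truncated to [1 kb, 1 Mb] — spanning the range of human protein-coding
  genes with a median near 20 kb. Exon length is a uniform fraction
  (0.02–1.0) of the gene length.
* **Expression**: per-gene baseline log2 expression N(6, 1.5²); the case
  condition adds `beta · (log10 L − center)` with the center at the mean
  log10 length, so the planted logFC slope is `beta` (log2 units per
  log10 bp) and the mean logFC is ~0. Linear-in-log10-length is the
  simplest structure consistent with a monotone length effect; it is a
  modeling choice of this package. Noise is Gaussian on the log2 scale
  (sd 0.5 by default, n = 10 + 10 samples) for the intensity platform;
  the counts platform exponentiates, rescales each sample to an expected
  depth (default 2×10⁶, with expected totals linear in depth), multiplies
  by exon length so that exon-density normalization recovers the planted
  per-base profile, and draws Poisson counts.
* **Cell mixtures**: each cell type has its own length slope on a shared
  baseline (e.g. neuron +1, glia 0 log2 per log10 bp); tissue samples are
  proportion-weighted sums of the cell-type profiles **on the linear
  scale** (physical mRNA pools add linearly), then logged. Dropping the
  neuron fraction from 0.5 to 0.3 in the case condition produces a
  tissue-level logFC curve that decreases with length, while a planted
  within-neuron `case_shift_slope` of +0.3 makes the neuron-level contrast
  increase with length — the composition-vs-transcription sign reversal in
  one joint simulation.

What passing tests on this generator do **not** show: robustness to
empirical count overdispersion beyond Poisson, probe-level artifacts,
batch effects, correlated genes, or non-monotone length effects. The
generator exists to verify the statistical machinery, not to certify
behavior on any particular real dataset.

## Problem sizes

The test suite and the acceptance script run the calibrations at desk
scale, chosen as the smallest sizes at which the quantities of interest
are stable: 2,000 genes × (5+5) samples × 200 replicates for null
envelope coverage, 5,000 genes × (10+10) × 20 seeds for slope recovery,
4,000 genes for the mixture sign reversal, 10,000 genes for t-test
calibration and the length-shift null (500 subset draws of 300 genes —
small relative to the 10,000-gene reference, keeping the set-vs-all
overlap distortion negligible).

## Known limitations

* The envelope is a visual/pointwise significance device; no family-wise
  error control across windows.
* Quantile normalization's fixed-point property holds exactly only for
  tie-free data; heavy ties (e.g. zero-inflated single-cell counts) leave
  tie-group means that differ slightly across samples.
* The protein-coding filter trusts the annotation's biotype labels; no
  identifier normalization (versioned vs unversioned Ensembl ids) is
  attempted.
* `sem` assumes within-window independence of per-gene logFC values.
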