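# chipquant

Quantitative ChIP-seq peak calling and differential binding for
paired-end fragment data, built for experiments in which a treatment
changes *global* chromatin occupancy of the immunoprecipitated factor —
e.g. ligand-induced recruitment of a ubiquitin ligase to nuclear hormone
receptors on chromatin.  In that regime simple depth normalization fails:
when a large share of reads moves into (or out of) peaks, total counts no
longer reflect sequencing depth, and standard pipelines mis-scale the
samples before comparing them.  `chipquant` instead estimates per-sample
scale factors from adaptively merged *background* bins and carries those
factors through peak calling and differential testing.

## Method

Inputs are paired-end **fragments** (BEDPE or fragment BED), one ChIP and
one matched Input per condition/replicate, an exclusion-list BED, and a
chromosome-sizes table.  The pipeline:

1. **Filter** — drop fragments fully contained in an exclusion region,
   exact positional duplicates, and fragments > 1,000 bp.
2. **Merge replicates** — down-sample every replicate to the depth of the
   smallest, then pool, for peak discovery.
3. **Normalize** — count fragments in 75-bp bins, greedily merge
   neighboring bins whose pooled per-bp densities differ by < 33%
   (background merges into long bins; peak edges break the merge), then
   apply median-of-ratios: per bin the pseudo-reference is the geometric
   mean across samples, and a sample's factor is the median of its
   density/reference ratios, rescaled to geometric mean 1.  Normalized
   signal is raw signal divided by the factor.
4. **Background model** — from the matched Input, a multiscale local
   Poisson rate: the pointwise maximum of read-start pileups extended to
   the median fragment length *d*, ±500 bp (rescaled by *d*/(2·500)), and
   ±5,000 bp (rescaled by *d*/(2·5,000)), bounded below by the global rate
   λ_bg = n_reads · *d* / effective genome size, scale-normalized, and
   floored at 2 so that reported peaks clear an absolute signal bar.
5. **Score and call** — per base, p = P(X ≥ chip | X ~ Poisson(noise));
   Benjamini–Hochberg over the genome with each constant interval
   weighted by its width in bases gives q-values; bases at q ≤ 0.01 form
   peaks (gaps ≤ 75 bp bridged, peaks shorter than *d* dropped).
6. **Consensus and test** — peaks pooled across conditions and
   union-merged; per-replicate fragment counts in consensus peaks are
   compared between conditions with a negative-binomial Wald test using
   the custom scale factors (moment dispersion stabilized across peaks,
   normal Wald p, BH adjustment).

A synthetic-data module generates complete two-condition experiments with
known peaks, enrichment folds, depth multipliers, duplicates and
exclusion regions, so the whole pipeline is testable without downloads.

## Worked example

Simulate a 1 Mb two-condition experiment (2 ChIP + 2 Input replicates per
condition, 20 peaks at 8-fold enrichment, 20% of them with 4-fold higher
occupancy in condition B), then run the pipeline:

```sh
chipquant simulate --outdir sim --seed 7 --n-peaks 20 \
    --db-fraction 0.2 --chrom-length 1000000
# write samples.tsv (sample_id/role/condition/replicate/path) and config.yaml:
#   sample_sheet: samples.tsv
#   chrom_sizes: sim/chrom.sizes
#   exclusion_bed: sim/exclusion.bed
#   outdir: out
#   seed: 1
chipquant run config.yaml
```

```
wrote 8 samples and truth files to sim
pipeline complete: 20 outputs
```

`out/scale_factors.tsv` holds the per-replicate ChIP factors (all near 1
here because the simulated depths are equal):

```
sample        factor
A_ChIP_rep1   0.9831538517
A_ChIP_rep2   0.9828740458
B_ChIP_rep1   1.013986445
B_ChIP_rep2   1.020583397
```

All 20 true peaks are recovered and merged across conditions
(`out/consensus_peaks.bed`):

```
chrSim  35639   36280   A,B
chrSim  82534   83089   A,B
chrSim  120541  121161  A,B
```

and `out/differential_binding.tsv` reports, per consensus peak, the mean
normalized count, log2 fold change (condition B over A), Wald statistic
and BH-adjusted p-value:

```
chrom   start   end     baseMean   log2FoldChange  lfcSE       stat          pvalue      padj
chrSim  35639   36280   102.99537  -0.0072130108   0.14181287  -0.050862878  0.95943479  0.95943479
chrSim  82534   83089   88.536487  -0.064893282    0.15293277  -0.42432556   0.6713284   0.74592045
```

Exactly the 4 simulated differential peaks reach `padj <= 0.05` (4 of 20
tested).  A `manifest.json` records every parameter, seed, and per-stage
record count needed to reproduce the run; rerunning with the same config
and seed yields byte-identical outputs.

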