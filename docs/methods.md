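# Methods

This note documents the statistical model behind `chipquant`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Data model and conventions

The unit of evidence is the *fragment*: the interval spanned by one
sequenced paired-end molecule, 0-based half-open, validated against a
`GenomeLayout` (ordered chromosome names, lengths, and an effective
genome size — the mappable length used to convert total read mass into a
global rate; for synthetic genomes it equals the full length).  Fragment
sets are multisets: duplicates are legal on input and removed by the
filter stage.  All genome-wide signals (pileups, noise, p/q tracks) are
`StepTrack`s — piecewise-constant nonnegative functions stored as
breakpoint/value arrays per chromosome, built by exact sweep-line
accumulation over integer event positions.  Pileup values are accumulated
as integers before any scaling, so the conservation identity
∫pileup = Σ fragment lengths holds in integer arithmetic.

## Quality filters

Three rules, order-independent by construction: (i) a fragment is removed
when a *single* exclusion interval fully contains it (checked per
interval, not against the union, via a prefix-max sweep); (ii) fragments
strictly longer than 1,000 bp are removed (length exactly 1,000 is
kept); (iii) exact positional duplicates beyond the first copy are
removed after the other two rules — identical coordinates share their
fate under rules (i) and (ii), so the result equals any application
order.  Duplicate detection is positional, not flag-based; mate
orientation is not modelled at the fragment level.

## Replicate merging

For peak discovery, replicates of one condition/role are pooled after
down-sampling every replicate (seeded, without replacement) to the depth
of the smallest, so a deep replicate cannot dominate the pooled
evidence.  The merged-set size is exactly n_replicates × min size.  The
differential test deliberately does *not* use merged sets (see below).

## Scale-factor estimation

Total-count scaling is biased when occupancy itself differs between
samples, so factors are estimated from background only:

1. Fragments are tabulated in fixed 75-bp bins.  A fragment counts in
   **every bin it overlaps**.  This choice is load-bearing: adjacent bins
   then share most of their fragments, so neighboring per-bp densities
   are strongly correlated and the merge step below can cascade through
   flat background.  With one-bin-per-fragment (midpoint) assignment —
   available as `mode="midpoint"`, which makes bin totals an exact
   partition of the sample — typical depths (~1.5 fragments/bin/sample)
   leave merged bins so count-poor that the median of ratios collapses
   onto coarse fractions and depth recovery fails; this was measured, not
   assumed.
2. One greedy left-to-right pass per chromosome merges the current bin
   run with the next bin iff the relative change |a−b|/max(a,b) of pooled
   (summed-across-samples) per-bp densities is below 0.33, with a
   recomputed after every absorption and a=b=0 treated as no change.
   Pooled densities drive merging so all samples share merged boundaries,
   which per-bin cross-sample ratios require.  Peak edges change density
   several-fold and break the merge, so the threshold implicitly
   separates peak from background bins.  The denominator max(a,b) makes
   the change symmetric and bounded in [0,1].
3. Median-of-ratios over merged bins: drop bins where any sample is zero
   (geometric mean undefined) or pooled density ≤ `min_pooled_density`
   (default 0; an optional `min_merged_length` filter further restricts
   to long background-like bins and is off by default); per bin the
   pseudo-reference is the geometric mean across samples of per-bp
   densities; a sample's factor is the median of its density/reference
   ratios.  Factors are rescaled to geometric mean 1 — a convention, not
   a statement about absolute depth — and normalized signal is defined as
   raw/factor.  Ratios are computed on length-normalized counts; with
   shared merged boundaries the bins compared are one-to-one across
   samples, so this only rescales numerator and denominator identically.

ChIP samples and Input samples are normalized as separate pulldown
groups: the two pulldowns measure different material and their
backgrounds need not be comparable.  Two estimations are run in the
pipeline: one over the down-sample-merged per-condition samples (these
factors normalize the discovery tracks — they are the samples actually
compared during discovery), and one over the per-replicate ChIP samples
(attached to the differential count matrix, which requires per-replicate
factors).

## Background model and peak calling

The noise track for a condition is built from its (merged) Input.  Read
starts — both endpoints of each fragment, which is why all pileups carry
a factor 0.5 against double counting — are extended to centered windows
at three scales: the median fragment length *d* (rounded half-up; for
even counts the two central order statistics are averaged first), ±500 bp
with correction *d*/(2·500), and ±5,000 bp with correction *d*/(2·5,000),
so all three carry the same expected mass.  The merged noise is the
pointwise maximum of the three pileups and the global rate
λ_bg = n_reads·*d*/effective genome size (n_reads = 2·n_fragments), is
divided by the Input's scale factor, and is floored at 2.  The floor
means a peak must clear an absolute normalized depth of ~2, suppressing
significant-but-tiny calls in read-poor regions.  Which factor
normalizes the noise track is genuinely open; the Input's own factor is
the default (`input_scale_factor`), and callers can pass the matched
ChIP's factor instead.

Scoring: per base, p = P(X ≥ round(chip) | X ~ Poisson(noise)), with
half-up rounding of the (real-valued, normalized) chip signal; a
continuous alternative via the regularized incomplete gamma function is
available and off by default.  Q-values are Benjamini–Hochberg over the
whole genome with each constant interval weighted by its width in bases:
every base is one hypothesis, constant intervals just carry many
identical copies, and the weighted computation equals per-base-expanded
classical BH exactly (tested to float equality).  Peaks are maximal runs
of q ≤ 0.01, bridged across gaps ≤ `max_gap` (default 75 bp, the bin
width) and filtered to length ≥ `min_length` (default *d*; the study
parameters behind these two defaults are not externally fixed, so both
are configurable and recorded in the manifest).  The summit is the
leftmost base attaining the maximum chip signal in the peak.  Peaks are
pooled across conditions and union-merged (strict overlap; abutting
half-open intervals stay separate) into consensus peaks with provenance.

## Differential binding

Per-replicate fragment counts in consensus peaks (overlap counting by
default: a fragment counts once in every peak it overlaps ≥ 1 bp;
midpoint counting assigns each fragment to ≤ 1 peak) are tested between
exactly two conditions with ≥ 2 replicates each.  Counts are divided by
the sample's scale factor; group means with a 0.5 pseudo-count give
log2FC (alphabetically first condition is the reference); the NB variance
Var = μ + αμ² enters a delta-method Wald SE on the log means; p-values
are two-sided normal and BH-adjusted.

Dispersion: per peak, the pooled within-group residual variance s²
(denominator n−2) gives the moment estimate max(0, (s²−ȳ)/ȳ²); the
test uses the **median of these estimates across peaks** (floored at
1e-8) as a common dispersion.  With 2–3 replicates a per-peak 4-df
estimate is far too noisy for a normal reference (measured null
rejection ~12% at p < 0.05; the across-peak median brings it to 6–8%
with ≥ 99% power against 4-fold changes at these depths).  This is a
deliberate simplification of shrinkage-based pipelines: no
empirical-Bayes dispersion shrinkage and no effect-size/false-sign-rate
shrinkage are applied, so q-values here control FDR, not false sign
rate, and peaks with strongly atypical dispersion are tested against a
slightly wrong α.  Counting uses per-replicate samples because a
replicated test needs within-group variation; the merged sets exist only
for discovery.

## Synthetic data

The generator emulates exactly the structure the method assumes: per
sample, background fragment *midpoints* are a Poisson process at
`background_density × depth_multiplier` (midpoints, not starts, so
pileups are symmetric around peak centers); ChIP samples add peak
fragments at rate `background_density × (fold−1) × multiplier` uniform
in each peak; fragment lengths are truncated-normal (mean 200, sd 20,
floor 50 — boundary fragments are shifted inward, not clipped, so the
length distribution is exact); a `duplicate_rate` fraction of fragments
is re-emitted; exclusion regions are placed clear of peaks.  Each sample
draws from its own generator derived from the master seed by fixed
offsets, so adding replicates never perturbs existing samples.  Defaults
describe the benchmark conditions used throughout: one 2 Mb chromosome,
density 0.02 fragments/bp (~4× mean coverage), 2 conditions × 2
replicates, 50 peaks of ~500 ± 100 bp at 8-fold occupancy, 5%
duplicates, four 2-kb exclusion regions; differential peaks multiply the
second condition's fold by 4.

Not modelled: sequence content, mappability/GC bias, chromatin-dependent
background autocorrelation, inter-chromosomal artifacts.  Passing
benchmarks therefore demonstrate correctness of the algorithms under the
stated stochastic model and calibration of the statistics against it —
not performance on any particular real dataset, where background
smoothness and artifact structure differ.

## Numerical choices

* Poisson tails via `scipy.stats.poisson.sf` (verified against direct
  pmf summation to < 1e-13 absolute over chip ≤ 200, noise ≤ 50).
* The weighted BH uses the arithmetic order p·N_bp/rank with a reverse
  cumulative minimum, capped at 1, which reproduces per-base expansion
  bit-for-bit.
* Track normalization divides values (rather than multiplying by a
  reciprocal) so the noise floor identity min = max(floor, λ_bg/factor)
  holds exactly.
* Degenerate inputs: empty fragment sets are errors where a statistic is
  undefined (median length, noise building, down-sampling) and benign
  elsewhere (empty tracks, zero counts); all-zero peaks test at p = 1
  with log2FC = 0; summit ties break leftmost.
* Benchmark problem sizes (2 Mb genomes, 10–20 simulation replicates,
  2,000-peak count matrices) were chosen so the full suite and the
  acceptance script each complete in well under a minute on one CPU
  while keeping Monte-Carlo bands comfortably away from their thresholds.
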