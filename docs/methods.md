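# Methods

## Interval model

All coordinates are 0-based, half-open (the BED convention). A peak is an
interval [s, e) on a named chromosome of a `GenomeModel` (an ordered
name→length table, read from UCSC chrom.sizes). Peak sets are stored sorted
by (chromosome order, start, end); that global order is the peak index used
in every report. BED3–BED6 is accepted on input (extra columns ignored,
`track`/`browser`/`#` lines skipped); BED3/BED4 is written, and
read∘write is an identity on coordinates and order. Unknown chromosomes in
BED input are an error by default, or dropped with a warning
(`unknown_chrom="drop"`) since real peak files often carry scaffolds absent
from an analysis genome.

## Overlap rule

Two peaks overlap when the shared span I covers at least a fraction t of a
peak's width; t defaults to 0.25 and the comparison is inclusive (≥), so
"at least 25%" admits exactly 25%. Three modes exist because the rule is
phrased both reciprocally and one-sidedly in the literature: `reciprocal`
(both fractions ≥ t; the default, and the rule used for origin
classification), `query_fraction`, and `reference_fraction`. Counting uses a
per-chromosome sorted sweep (searchsorted windows bounded by the maximum
reference width); the test suite asserts exact agreement with the all-pairs
brute force across modes and thresholds, and monotonicity of all counts as t
decreases.

## Nearest-peak distances

For each query peak the nearest same-chromosome reference peak is found by
|midpoint distance|, midpoints being floor((s+e)/2). The emitted distance is
signed (reference − query), chosen for symmetry of the distribution around
zero; an absolute-value output is available. Ties in |distance| resolve to
the reference peak with the smaller start. Query peaks on chromosomes with
no reference peak are omitted from the distance list and tallied separately
rather than being assigned an infinite distance.

## Randomization null and permutation test

The null model re-places one peak set (the reference by default) at random
positions *within the same chromosome*: each start is drawn uniformly from
the integers [0, L − w], so the per-chromosome peak count and the
per-chromosome width multiset are preserved exactly. Randomized peaks may
overlap one another — the null imposes no exclusion; a rejection-sampling
variant without self-overlap exists behind a flag for sensitivity analysis
only. Each of the N iterations uses an RNG substream derived from
(seed, iteration), so results are bit-reproducible and independent of
evaluation order.

The test statistic is, by default, the number of query peaks overlapped by
at least one reference peak (the reference-side count and the pair count are
selectable). The primary p-value is the add-one estimator with ties counted,
p = (#{null ≥ observed} + 1)/(N + 1), which is valid and never zero; the
strict exceedance count is reported for direct comparison with "never
exceeded in N randomizations" statements, and when it is zero the bound
p < 1/N is also emitted. N defaults to 10,000, with 2,000 commonly used for
quick runs; both conventions appear in published work and the choice is
exposed rather than resolved.

Calibration: because the overlap count is integer-valued, the add-one
estimator is conservative in sparse regimes where the null distribution
concentrates on a few values (ties inflate p). The type-I calibration test
therefore uses a deliberately dense configuration (5 × 2 Mb genome, 2,000
peaks per set, ≈120 expected chance overlaps) where the statistic takes many
values; there the rejection rate at α = 0.05 over 500 independent datasets
falls inside the exact binomial 99% interval. In sparser settings users
should expect p-values biased upward, never downward.

## Distance narrowness

Colocalization also shows as a nearest-distance distribution much narrower
than after randomization. The report quantifies this with (i) the ratio of
the observed IQR to the median of the per-permutation null IQRs and (ii) a
two-sample Kolmogorov–Smirnov statistic comparing the observed and
pooled-null **absolute** distances. Absolute values are used because both
distributions are symmetric around zero, which caps the KS distance of the
signed distributions near 0.5 no matter how narrow the observed one is; on
|distance| the statistic approaches 1 under strong colocalization. No fixed
significance cutoff is imposed — the criterion is descriptive, with shared
distance histograms exported for plotting.

## Origin classification

Licensed origins are Mcm5 peaks; an origin is *active* when it reciprocally
overlaps (t = 0.25, both spans) a PCNA peak and *dormant* otherwise. The
partition is exact and order-preserving. Coverage of a class by a further
factor is, by default, the fraction of class peaks overlapped by ≥1 factor
peak (`direction="class"`); the opposite direction is available because
published coverage percentages do not always state theirs. An empty class
reports coverage 0 with an explicit flag.

## Cohort 2×2 test

`chi2_2x2` is Pearson's chi-squared with df = 1 via
`scipy.stats.chi2_contingency`, without continuity correction by default —
on the packaged ovarian-cohort cross-tab ([[38, 19], [79, 11]]) the
uncorrected recomputation gives χ² = 9.575, p = 1.97 × 10⁻³ versus
3.92 × 10⁻³ with Yates; the value printed in the source cohort report
(2.2 × 10⁻³) matches neither exactly, which this package documents rather
than reconciles (the tested cohort may have differed slightly from the
printed subgroup counts: 57 + 90 = 147 of 154 patients). The independent
check is a Monte-Carlo label permutation: with all margins fixed, permuting
group labels makes the a-cell hypergeometric, so the null is sampled by
hypergeometric draws and the statistic recomputed from the margins — exactly
equivalent to shuffling the label column, at far lower cost. Zero cells make
the odds ratio degenerate (0 or ∞), which is flagged rather than hidden.

## Synthetic data generator

The generator emulates the structure of real ChIP-seq peak lists, not their
sequence content:

- **Genome**: default 5 chromosomes × 50 Mb — sparse enough that chance
  overlap between ~10³ peaks of ~200 bp is rare, small enough for
  seconds-scale permutation runs.
- **Widths**: lognormal, median ≈ 200 bp (anchored to typical ChIP fragment
  sizes), log-SD 0.35 (a realistic within-set spread), clipped to
  [50, 10000] bp.
- **Anchors**: chromosomes chosen with probability proportional to length
  (uniform-per-chromosome would distort per-chromosome counts), starts
  uniform in [0, L − w]. A density warning fires above 1 peak / 10 kb.
- **Query peaks**: exactly round(ρ·n) peaks planted at uniformly chosen
  anchors with midpoint offset Normal(0, offset_sd) (default 100 bp) and
  width drawn from the width law; the rest placed independently. Planted
  peaks are clamped into their chromosome (never wrapped); clamping events
  are counted and stay ≪ 1% at defaults. Truth flags follow the emitted
  sorted peak order.
- **Origin scenarios**: n origins (default 1,000) placed as anchors; a
  uniformly chosen subset of exactly round(fraction_active·n) origins
  (default 60%) receives a planted PCNA peak of *matched width* at offset
  Normal(0, offset_sd); optional independent PCNA background peaks.

What the generator does **not** emulate: mappability and assembly gaps,
GC-dependent peak density, clustered/bursty binding, peak-width/score
correlation, inter-chromosomal contamination. Passing recovery tests
therefore show the statistics are correct for idealized interval data; they
do not certify behavior under real-genome artifacts (a mappability-aware
null is explicitly out of scope).

Expected recovery under planting jitter has a closed form used as the test
oracle: a planted matched-width peak of width w at offset d ~ N(0, σ) passes
the reciprocal 25% rule iff |d| ≤ 0.75 w, so the detection probability is
E_w[2Φ(0.75 w/σ) − 1] over the width law. At σ = 100 bp and the default
width law this is ≈ 0.84 — hence, e.g., an origin scenario with 60% truly
active origins classifies ≈ 0.90 of origins correctly, and a ρ = 0.8 query
set shows ≈ 0.66–0.68 of peaks overlapped. Recovery tests assert agreement
with this expectation (binomial bands), not with the nominal planted
fraction.

## Numerical and design choices

- Integer arithmetic throughout the interval layer; midpoints floor.
- Per-iteration RNG substreams from `SeedSequence(seed, spawn_key=(i,))`.
- Empirical p never below 1/(N+1) and never above 1 by construction.
- IQR ratio with a zero null median reports 0 when the observed IQR is also
  0 (coincident sets) and ∞ otherwise.
- The CLI is a thin wrapper over the library; equivalence is tested.
  `full-run` re-emits its resolved configuration and a SHA-256 manifest, so
  reruns with the same config are verifiably identical.

## Problem sizes used in the shipped checks

Headline significance: 1,000 + 1,000 peaks, ρ = 0.8, 2,000 randomizations.
Type-I calibration: 500 datasets × 199 randomizations at 2,000 + 2,000 peaks
on 10 Mb. Sweep-vs-brute-force: 1,000 instances at n, m ≤ 50. Randomization
contract: 10,000 draws of a 120-peak set. These sizes were chosen to give
stable statistical verdicts at seconds-to-minutes scale on one CPU.

## Known limitations

- The null keeps peaks on their chromosome but ignores mappability, gaps and
  chromatin accessibility; on real genomes it is anti-conservative to the
  extent that callable space is smaller than chromosome length.
- The add-one p cannot go below 1/(N+1); claims like "p < 0.0005" require
  N ≥ 2,000.
- Origin classification is a hard threshold on a single overlap rule; peaks
  near the 25% boundary flip class under small coordinate changes.
- The chi-squared test assumes independent patients and fixed margins; the
  Monte-Carlo check shares the fixed-margin assumption.
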