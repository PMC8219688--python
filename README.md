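# peakcoloc

Colocalization statistics for ChIP-seq peak sets.

When two chromatin factors are mapped by ChIP-seq, a basic question is whether
their binding sites (called peaks) tend to fall in the same genomic regions
more often than chance placement would produce. `peakcoloc` answers it for
interval-level peak data (BED files plus a chrom.sizes table) with:

- **Fractional span overlap.** Peaks *a* and *b* overlap when the shared span
  *I* = max(0, min(e<sub>a</sub>, e<sub>b</sub>) − max(s<sub>a</sub>, s<sub>b</sub>))
  covers at least a threshold fraction *t* (default 0.25) of a peak's width —
  reciprocally (*I*/w<sub>a</sub> ≥ *t* **and** *I*/w<sub>b</sub> ≥ *t*, the
  default) or one-sided.
- **A within-chromosome randomization null.** One peak set is re-placed at
  uniformly random positions on its own chromosomes, preserving the
  per-chromosome peak count and every peak's width, *N* times (default
  10,000). The empirical p-value for the observed overlap count *S* uses the
  add-one estimator p = (#{S<sub>null</sub> ≥ S} + 1)/(N + 1); the strict
  exceedance count is reported alongside, and zero strict exceedances also
  yields the bound p < 1/N.
- **Nearest-peak distance distributions.** Signed midpoint distance from each
  query peak to its closest same-chromosome reference peak, compared with the
  randomized null via an IQR ratio and a Kolmogorov–Smirnov statistic on
  |distance| ("narrowness": colocalized sets give IQR ratio ≪ 1, KS → 1).
- **Replication-origin classification.** Licensed origins (Mcm5 peaks) are
  split into *active* (reciprocally overlapping a PCNA peak — the clamp is
  loaded at fired origins) and *dormant* (the rest), with coverage reports
  for any further factor against each class.
- **Cohort cross-tabulation.** A 2×2 Pearson chi-squared test (optional Yates
  correction, odds ratio, per-group proportions) for marker-level cohort
  tables, with a Monte-Carlo label-permutation p-value as an independent
  check.
- **A synthetic-data generator** producing genomes and peak sets with a known
  colocalization fraction ρ, planted-offset SD, lognormal widths (median
  ~200 bp, mimicking ChIP fragment sizes), and origin scenarios with known
  active fractions — so every statistic can be validated by parameter
  recovery without external downloads.

## Worked example

```python
import peakcoloc as pc

cfg = pc.SyntheticConfig(seed=11)            # 5 x 50 Mb genome, 1000+1000 peaks, rho=0.8
anchors = pc.generate_anchor_peaks(cfg)
query, truth = pc.generate_query_peaks(anchors, cfg)

res = pc.count_overlapped(query, anchors)    # reciprocal >= 25% by default
print(res.n_query_overlapped)                # 658 of 1000 query peaks overlapped

perm = pc.permutation_test(query, anchors, cfg.genome,
                           pcfg=pc.PermutationConfig(n_perm=2000, seed=12))
print(perm.observed, perm.null_stats.max(), perm.p_add_one, perm.p_bound)
# 658 7 0.0005 <0.0005
```

The observed count (658) reflects the planted 80% colocalization minus
planting jitter; random re-placement of 1000 ~200 bp peaks on 250 Mb rarely
produces more than a handful of chance overlaps (null maximum 7 here), so
none of the 2000 randomizations reaches the observed count and the add-one
p-value is 1/2001 ≈ 0.0005.

```python
nar = pc.distance_narrowness(query, anchors, cfg.genome,
                             pc.PermutationConfig(n_perm=100, seed=13))
print(nar.observed_iqr, nar.iqr_ratio, nar.ks_statistic)
# 182.0 0.00104 0.799   (observed spread ~180 bp vs ~175 kb under the null)

mcm, pcna, otruth = pc.generate_origin_scenario(cfg)   # 1000 origins, 60% active
cls = pc.classify_origins(mcm, pcna)
print(cls.n_active, cls.n_dormant)           # 506 494  (planting jitter hides some)

table = pc.ContingencyTable2x2(38, 19, 79, 11,
                               row_labels=("low_TUBG", "high_TUBG"))
r = pc.chi2_2x2(table)
print(round(r.statistic, 3), f"{r.p_value:.2e}")       # 9.575 1.97e-03
```

## Command line

Each stage is also a subcommand of the `peakcoloc` executable:

```sh
peakcoloc simulate --outdir sim --seed 42          # fixture set + truth + config
peakcoloc overlap  sim/query.bed sim/anchors.bed sim/genome.chrom.sizes
peakcoloc permtest sim/query.bed sim/anchors.bed sim/genome.chrom.sizes \
    --n-perm 2000 --seed 7
peakcoloc distances sim/query.bed sim/anchors.bed sim/genome.chrom.sizes --n-perm 100
peakcoloc origins  sim/mcm.bed sim/pcna.bed sim/genome.chrom.sizes \
    --query-bed sim/query.bed --outdir origins_out
peakcoloc cohort   table.csv
peakcoloc full-run run.yaml                        # config-driven pipeline + manifest
```

Reports are TSV/JSON with the seed and configuration embedded; `full-run`
writes a checksummed manifest so identical configs give identical outputs.

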