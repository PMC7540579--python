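# sgscan — shared genomic segment analysis with equivalence testing

`sgscan` maps dominantly inherited disease variants by testing whether
*candidate* variant positions, estimated independently in each affected
individual, co-locate in the genome more often than chance allows.  It is
aimed at the highly heterogeneous setting where different individuals carry
*different* pathogenic variants in the same gene, so single-variant
case–control tests have little power but positional sharing is still
informative.

## The method

1. **Heterozygosity scan.**  DNA variants near a rare dominant trait
   variant show a heterozygote excess: a flanking variant with minor allele
   frequency *f* is heterozygous in a carrier with probability exceeding
   1 − *f*, against a population heterozygosity of 2*f*(1 − *f*).  For each
   individual, a window of 2*m* + 1 adjacent variants (default *m* = 50)
   slides along each chromosome, and the window-average heterozygosity
   *H* = *h*/(*g* + *h*) is computed (*h*, *g* = heterozygous and homozygous
   genotypes in the window; missing genotypes excluded).  Runs of increasing
   *H* up to a maximum *H*<sub>max</sub> followed by decreasing *H* are
   extracted; the *k* peak positions per individual are that individual's
   candidate disease-variant locations.  Monomorphic variants and common
   variants (MAF > 0.05) are removed beforehand.
2. **Sharing statistic.**  For every variant *v* and half-width *d* (kb),
   *N*<sub>f</sub>(*v*) counts the individuals with at least one candidate
   within ±*d* kb of *v* (closed interval; each individual counted once).
3. **Permutation null (equivalence testing).**  The null hypothesis is
   *heterogeneity*: a candidate position can fall anywhere, so each
   individual's *k* candidates are re-drawn uniformly without replacement
   from the variant universe, independently across individuals.  Pooling
   pseudo-*N*<sub>f</sub> over variants and permutation samples yields one
   empirical p-value per (*N*<sub>f</sub>, *d*); with *n*<sub>perm</sub>
   samples including the observed data the smallest attainable p is
   1/*n*<sub>perm</sub> (read as "< 1/*n*<sub>perm</sub>").
4. **Significant runs.**  *N*<sub>crit</sub>(*d*) is the smallest
   *N*<sub>f</sub> with p < 0.05, floored at 3.  Maximal runs of consecutive
   variants with *N*<sub>f</sub> ≥ *N*<sub>crit</sub> are reported with
   their span, peak sharing *N*, total significant-variant count
   *N*<sub>var</sub>, and overlap with a region of interest (e.g. a gene
   ± 1 Mb).

## Worked example

Simulate five carriers of a fully penetrant dominant variant (heterozygosity
halo of ±1 Mb around position 10 Mb, background MAF *f* = 0.01) on a 20 Mb
chromosome with 20,000 variants, then run the full analysis:

```python
from sgscan import (SimConfig, simulate_genotypes, SharedSegmentModel,
                    RegionOfInterest)

cfg = SimConfig(n_variants=20_000, chrom_length_bp=20_000_000, n_carriers=5,
                maf_dist=("fixed", 0.01), elevation_halfwidth_bp=1_000_000,
                p_het_near=1.0, seed=7)
gm, truth = simulate_genotypes(cfg)
model = SharedSegmentModel.from_genotypes(gm, m=50, d_grid=(10, 50, 100),
                                          n_perm=2000)
res = model.fit(seed=1)
roi = RegionOfInterest(truth["chrom"], truth["window_start"], truth["window_end"])
print(res.summary(roi=roi))
```

```
Shared genomic segment analysis (equivalence test)
==========================================================
Individuals:          5
Candidate positions:  5 total (k from 1 to 1, mean 1.0)
Variant universe:     20000 positions on 1 chromosome(s)
Permutation samples:  2000 (seed 1; min attainable p = 0.0005)
Null mode:            pooled
Variant filtering:    20000 loaded, 0 monomorphic removed, 0 common removed, 20000 kept

Empirical significance levels p(N_f, d)  [p at 0.0005 means < 0.0005]
      d=10kb   d=50kb  d=100kb
N_f
1     0.0050   0.0244   0.0485
2    <0.0005  <0.0005   0.0011
3    <0.0005  <0.0005  <0.0005
4    <0.0005  <0.0005  <0.0005
5    <0.0005  <0.0005  <0.0005

Significant runs per d (N_crit floored at 3):
   d_kb  N_crit  N_r  L_avg_kb  N_var  L_roi_kb
 10.000       3    1    19.001     20    19.001
 50.000       3    1    98.005     99    98.005
100.000       3    1   198.010    199   198.010
```

Each carrier's scan yields a single H<sub>max</sub> peak inside the
implanted halo, so all five individuals share the same locus: the p-value
for *N*<sub>f</sub> = 5 is at the permutation floor for every *d*, and at
each *d* exactly one significant run is found.  Its coordinates recover the
implanted region:

```python
print(res.run_table(50, roi=roi).to_string(index=False))
```

```
 run chrom  start_pos  end_pos  n_variants  N  length_kb  in_roi
   1  chr1    9001450  9099455          99  5     98.005    True
```

The run's 99 variants all lie within the implanted window (which spans
9–11 Mb), it captures all *N* = 5 carriers, and it is flagged as
overlapping the region of interest.  As *d* grows, more variants capture
the carriers' candidates and the run widens — the usual trade-off between
capture width and the sharing level needed for significance.

The same analysis is available from the shell
(`sgscan simulate | scan | share | runs`, or `sgscan pipeline` end to end);
every output directory carries a `manifest.json` with parameters and input
checksums, and identical seeds reproduce outputs bit for bit.

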