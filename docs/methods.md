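# Methods

This note documents the statistical model implemented by `sgscan`, the
choices made where the design was genuinely open, and what the simulation
studies in the test suite do and do not demonstrate.

## Model and procedure

**Heterozygote excess near dominant variants.**  Consider carriers of a
rare dominantly inherited variant.  A nearby DNA variant with minor
population allele frequency *f* is heterozygous in a carrier with
probability greater than 1 − *f* (the carrier holds the disease haplotype
plus a population draw), whereas an unlinked variant is heterozygous with
the population rate 2*f*(1 − *f*).  For small *f* the contrast is large,
which makes local average heterozygosity a usable localization signal for
a *single* affected individual — no controls, no family data.

**Sliding-window heterozygosity.**  For one individual, each chromosome is
scanned with a window of 2*m* + 1 adjacent variants, stepping one variant
at a time.  The window statistic is H = h/(g + h), with h and g the counts
of heterozygous and homozygous genotypes among the window's called
genotypes; missing genotypes reduce the denominator (they are excluded
from both counts, not imputed).  H is undefined at the m variants on each
chromosome end and wherever g + h = 0.  The default m = 50 balances
variance of H against positional resolution; it is user-configurable, and
a per-position vector of half-widths can be supplied as an extension hook
for dynamically chosen window sizes.  Analyses run on filtered variants:
monomorphic sites are removed first, then sites with sample MAF > 0.05
(strict inequality — MAF exactly 0.05 is kept).

**Peak extraction.**  Candidate disease positions are the peaks
(H_max) of maximal rising-then-falling runs of H.  Because window averages
change slowly, plateaus are common; the run definition therefore allows
non-strict monotonicity, and a peak plateau is represented by its first
variant.  Three noise controls decide which runs count, since raw
unimodal runs on noisy data are legion: a minimum number of strict
increases before the peak (`min_rise`, default 3), a minimum number of
strict decreases after it (`min_fall`, default 3), and a minimum
prominence of the peak over the larger endpoint H (`min_prominence`,
default 0.1, on the H scale).  The defaults keep per-individual candidate
counts in the tens on realistic chromosome-scale inputs; all three are
tunable and should be reported with results.

**Sharing statistic.**  Given candidate sets C_1..C_N for N individuals
and a half-width d in kb, the statistic at variant v is

    N_f(v) = #{ i : exists c in C_i with chrom(c) = chrom(v) and
                               |pos(c) − pos(v)| <= 1000·d }

Intervals are closed on both ends and the kb→bp conversion is exact.  An
individual contributes at most one to any variant regardless of how many
candidates fall in the window; the implementation merges each individual's
overlapping windows before stamping coverage, which makes the count equal
to an interval-union oracle by construction.

**Permutation null and empirical p-values.**  The test reverses the usual
roles of null and alternative (equivalence testing): the null hypothesis
is heterogeneity — each individual's candidates may fall anywhere in the
variant universe — and co-location across individuals is the alternative
of interest.  The null is realized by re-drawing, for each individual
independently, k_i positions uniformly without replacement from the
variant table (equivalent to permuting the position labels and reading off
that individual's candidates; k_i is preserved).  Each permutation sample
yields pseudo-N_f values at every variant.  p-values pool pseudo-N_f over
variants and samples, giving one p per (N_f, d) — the shape of the
published significance tables for this method, whose N_f = 1 column
matches the marginal probability that a random variant captures at least
one individual.  A per-variant mode (one pseudo-N_f per sample at a single
target variant) is available behind a flag; it is the construction under
which the "smallest possible significance level = 1/n_perm" reading is
exact.  In both modes the observed data may be counted as one of the
n_perm samples (default), and reported p-values are floored at 1/n_perm; a
value at the floor is to be read as "< 1/n_perm".  No further
multiple-testing correction is applied — the permutation construction is
the correction.

Randomness derives from per-(individual, sample) streams seeded by
(seed, individual index, permutation index), so results are independent
of evaluation order and reproduce exactly for a given seed.

**Significant runs.**  For each d, N_crit(d) = max(floor, smallest t with
p(t, d) < 0.05), with floor 3 by default: requiring at least three
individuals guards against chance pairs even where the permutation p for
t = 2 dips below 0.05.  Runs are maximal stretches of consecutive variants
(chromosome order) with N_f >= N_crit; strict adjacency defines a run (no
gap tolerance — adjacency is the minimal reading of "runs of variants",
and a gap rule would add a parameter with no principled default).  A run
is summarized by its variant count, its span from first to last variant
(kb; single-variant runs span 0 but still count in N_r), and its maximal
N_f.  Region-of-interest overlap uses closed-interval intersection;
coordinates are 1-based base pairs everywhere, converted to 0-based
half-open only in BED output.

## Synthetic data

The generator produces what the method assumes and nothing more:

* a variant grid (uniform or uniformly random positions) on one
  chromosome, with per-variant MAF f fixed or drawn from a (log-)uniform
  range in (0, 0.05];
* carrier genotypes i.i.d. across variants — HET with probability
  2f(1 − f) in the background and p_het_near within ±w bp of the implanted
  disease position.  The step-function halo is a minimal model; the decay
  of heterozygote excess with distance in real data is gradual and
  recombination-driven, and is not modeled.  Configurations that claim an
  implanted signal must satisfy p_het_near > 1 − f; explicit no-signal
  configurations (p_het_near equal to the background rate) are allowed for
  null-calibration runs;
* directly drawn candidate sets (k per individual uniform in a range,
  positions without replacement, optionally n individuals forced to share
  a position near a designated locus) for testing the sharing stage in
  isolation.

Because genotypes are i.i.d. across variants, there is no linkage
disequilibrium; the method operates one variant at a time and makes no use
of LD, so this does not limit what the correctness tests show.  What the
simulations do **not** establish is performance on real cohorts, where
candidate counts, halo widths and the decay of heterozygote excess depend
on penetrance, allele frequencies and local recombination; the recovery
studies here are correctness checks of the machinery under the model's own
assumptions, not power estimates.

Defaults (M = 20,000 variants on a 20 Mb grid, 5 carriers, f = 0.01,
w = 1 Mb, p_het_near = 1) correspond to the deterministic-core recovery
setting: the implanted halo forces H = 1 across its interior, so a correct
implementation must recover it in every replicate.

## Numerical and I/O choices

* Genotypes are collapsed at load time to HOM / HET / MISSING; any two
  distinct called alleles are HET (multi-allelic sites included), any
  uncalled allele is MISSING, phasing is ignored.  Non-diploid records are
  an error naming the record.
* Unsorted VCF positions are sorted with a warning; duplicate (chrom, pos)
  records keep the first occurrence with a warning (the scan needs a
  strictly ordered position vector).
* MAF is recomputed from the loaded sample.  From VCF it uses called
  allele counts (folded at 0.5).  The plain-TSV genotype dialect stores
  only het/hom codes, so MAF is estimated as h/(2(g + h)), which assumes
  no minor-allele homozygotes — the right regime for the rare variants the
  filter retains, but biased for common variants; VCF input is preferred
  when allele counts matter.
* Candidate re-draws without replacement use rejection sampling when
  k ≪ M (expected O(k) draws) and a full permutation otherwise.
* Monte-Carlo standard errors of pooled exceedance probabilities treat the
  per-sample pooled proportions as i.i.d. replicates (pseudo-N_f values
  are correlated across variants within a sample, so the naive
  binomial s.e. would be badly anticonservative).
* The closed-form oracle used in testing — on a uniform grid an individual
  with k candidates hits the ±d window of variant i with probability
  q_i = 1 − C(M − w_i, k)/C(M, k), and N_f ~ Binomial(N, q_i) — is
  averaged exactly over variants, including the truncated windows
  (w_i < 2r + 1) near chromosome ends, rather than using the
  interior-window approximation; at M = 50,000 the edge correction is of
  the same order as the Monte-Carlo error and matters for a 3-s.e. check.

## Problem sizes used in the checks

The statistical checks run at deliberately moderate scale so the whole
suite completes in about a minute: the closed-form agreement study uses
M = 50,000 variants, N = 20 individuals, k = 10 and 2,000 permutation
samples; recovery uses 20 replicates of the default recovery setting with
500 permutation samples; null calibration uses M = 20,000 and N = 20 with
candidate counts 9–17.  These sizes give Monte-Carlo standard errors small
enough for the 3-s.e. criteria while remaining desk-scale; all constants
live in the tests and the acceptance script and scale up directly.

## Known limitations

* Candidate H_max values are used only through their positions; weighting
  sharing by peak height is deliberately not implemented.
* Segment-emergence thresholds (`min_rise`, `min_fall`, `min_prominence`)
  approximate a criterion that in the original workflow lives in a
  separate peak-calling program; on real data the extracted segments can
  be wide and overlapping, and this package does not attempt to reproduce
  overlapping-segment behavior — only the peak positions feed the test.
* No recessive-trait mode, no sex-chromosome handling, no imputation, and
  no analytical p-values in the main path (the closed form holds only for
  uniform grids with fixed k and is used as a test oracle).
* Run-length summaries depend on local variant density; spans are reported
  in kb of physical distance, not variant counts, so sparse regions yield
  long runs of few variants.
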