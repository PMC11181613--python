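# Methods

## The problem and the model

The pipeline screens a two-population diploid cohort for genomic regions
under recent divergent selection. A selective sweep in one population leaves
three footprints in windowed summary statistics: elevated allele-frequency
differentiation between the populations (F_ST), reduced nucleotide
diversity in the swept population relative to the other (large
π_other/π_target), and an excess of rare variants at the partially swept
sites (negative Tajima's D). Candidate regions are windows extreme in these
statistics simultaneously, and candidate genes are the genes those regions
overlap.

## Statistics

**Weir–Cockerham F_ST.** Per site, the two-population variance components
a (among populations), b (among individuals within populations) and
c (within individuals) are computed with site-specific sample sizes and the
*observed* heterozygote frequency, so neither Hardy–Weinberg equilibrium
nor complete genotyping is assumed. The window estimate is the ratio of
sums Σa/Σ(a+b+c), which is the standard way to stabilize the per-site
estimator over a window. Negative window values are kept — clamping would
distort the empirical quantiles used for candidate calling. A known
property worth remembering when reading small-sample output: if the two
populations contain *literally identical* genotype columns, the estimate is
deterministically slightly negative (≈ −0.03 at n = 20 + 20), because the
between-population variance is exactly zero while the finite-sample
correction term is not; two *independent* samples from one population give
estimates centered on zero.

**Nucleotide diversity.** Per site, the unbiased pairwise diversity is
(m/(m−1))·2p̂(1−p̂) with m the non-missing chromosome count; window π is the
sum over sites divided by the *physical* window length (clipped windows
divide by the clipped length). The diversity ratio is oriented
π_other/π_target so that both the F_ST scan and the π-ratio scan use a
"highest q" rule; the direction is set per contrast by naming the target
population. π_target = 0 with π_other > 0 yields +inf, which deliberately
ranks above every finite ratio; 0/0 marks the window invalid for the ratio.

**Tajima's D.** Computed within the target population only. S counts sites
segregating among the non-missing genotypes; θ_π is the summed per-site
unbiased diversity on the count scale (not divided by window length, so it
is commensurable with S/a₁); the constants a₁…e₂ follow the standard
definitions for n chromosomes. Under missing data each site has its own m,
and a single n per window is required by the constants: the median m over
the window's segregating sites is used. This is a documented pragmatic rule
for handling per-site missingness, not a claim about any particular
existing implementation; with the simulator's low missing rates the median
and any reasonable alternative (mean, mode) coincide. S = 0 or n < 4 makes
D undefined and excludes the window from the D quantile.

**Candidate calling.** Quantiles are empirical order statistics over valid
windows (≥ `min_snps` SNPs, default 10, and a defined F_ST denominator);
ties at the cutoff are included, so a constant statistic selects everything
at that value rather than an arbitrary subset. The joint set intersects the
top-q F_ST and top-q π-ratio windows; the Tajima set takes the bottom q of
D. SNPs inside selected windows become candidate loci; each is extended
± 50 kb (a 1-based site p → [p−1−flank, p+flank) 0-based half-open, clipped
at the chromosome) and overlapping or book-ended intervals are merged.

## Population structure

LD pruning follows PLINK `--indep-pairwise` sliding semantics (the greedy
within-window removal repeats until no retained pair exceeds r², dropping
the lower-MAF member, then the window advances by the step). r² is the
squared Pearson correlation of dosages over pairwise-complete observations
(composite LD — correct for unphased data). PCA mean-imputes missing
dosages and normalizes each site by √(2p̂(1−p̂)) (Patterson scaling), then
eigendecomposes the sample covariance; component signs are fixed by making
the first nonzero coordinate positive. The NJ tree uses Saitou–Nei neighbor
joining on allele-sharing distances d = 1 − IBS; which distance the
original structure analyses of such cohorts use is usually unstated, and
allele-sharing is chosen as a reproducible, missing-data-tolerant default.
Negative NJ branch lengths are clamped to zero and flagged. The admixture
model (dose ~ Binomial(2, Σₖ q_ik f_kj)) is fitted by plain EM with
missing genotypes skipped in the likelihood; K is assessed by masking
random non-missing genotypes fold-wise and scoring the refit's predicted
doses by mean squared error.

## The synthetic cohort

The generator draws independent biallelic SNPs under the Balding–Nichols
model: ancestral frequency p ~ Uniform(maf_floor, 1−maf_floor), population
frequencies p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, p_k),
then a per-genotype missing mask. The model was chosen over a coalescent
simulation because it gives an exact, dependency-free null whose expected
Weir–Cockerham F_ST equals F (verified to three decimals in the tests), so
calibration statements are closed-form rather than empirical. Defaults
mirror a balanced two-color resequencing design: 20 + 20 diploid males, two
2 Mb chromosomes at 1 SNP/kb (roughly the SNP density of a filtered
whole-genome panel), F = 0.05 (weak within-breed divergence), 2% missing
calls, maf_floor 0.05.

Sweeps operate on the frequency track: inside the interval the target
population's frequencies move toward the nearer of {0, 1} by the factor s
(p' = p(1−s) for p < 0.5, else p + (1−p)s) and genotypes are redrawn,
keeping the original missing mask. Strength 1 forces fixation (window
π = 0); strength 0 is the identity and performs no redraw.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: linkage (sites are independent, so sweep
detection works through frequency shifts alone, not haplotype structure),
mutation-spectrum bias (ref/alt pairs are uniform, so the expected Ts/Tv is
4/8 = 0.5 rather than the ≈ 2 of real resequencing panels), demographic
history, and sequencing/genotyping error beyond random missingness.

## Numerical and design choices

- MAF filtering pools both populations (one shared filter before the
  per-population counts), with "removed if missing rate > 0.20" strict and
  "kept if MAF ≥ 0.05" inclusive; half-calls count as missing
  (conservative). Filtering is idempotent and order-stable.
- Admixture F entries are clipped to [1e−6, 1−1e−6] and the likelihood uses
  a matching floor, so log terms stay finite; EM stops when the log
  likelihood improves by < tol (default 1e−6) or at max_iter.
- LD-pruning ties (equal MAF) drop the larger site index; NJ Q-criterion
  ties take the smallest (i, j) pair — both make reruns bit-identical.
- Quantile cutoffs use k = ⌈q·n⌉ order statistics with ties included.
- All output files omit timestamps, so identical config + seed reproduces
  identical bytes end to end.

## Problem sizes in the test and acceptance studies

Monte-Carlo studies use 2 Mb chromosomes at 1 SNP/kb with 20 + 20 samples —
the cohort's design size with a desk-scale genome — and 10–20 seeded
replicates per study. Null-calibration bounds account for the 10×
overlap of 100 kb/10 kb sliding windows: adjacent windows share 90% of
their SNPs, so the effective number of independent windows per chromosome
is ≈ length/window_size (20 per 2 Mb), and binomial standard errors are
computed on that effective count. The observed null joint fraction
(≈ 0.005 vs q² = 0.0025) shows the expected mild positive excess: a window
where one population drifts to low diversity raises F_ST and π ratio
together, so the two rankings are not fully independent even at F = 0.

## Known limitations

- No haplotype-based statistics (XP-EHH, iHS); the scan is frequency-based.
- The simulator's independent-sites assumption makes power estimates
  optimistic relative to real linked data at equal SNP counts.
- Functional consequence annotation (exonic/splicing classes) is out of
  scope; annotation is pure interval overlap.
- The admixture EM is a straightforward ascent; for K > 2 on weakly
  structured data it can stop at max_iter before strict convergence, which
  the output flags.
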