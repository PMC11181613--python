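# sweepscan

Genome-wide selection-signature scanning for two-population diploid
resequencing cohorts — e.g. two color morphs of one livestock breed — built
to find genomic regions under recent divergent selection and the genes they
contain.

The pipeline starts from a multi-sample VCF and a sample→population table
and runs:

1. **SNP QC** — remove sites with > 20% missing calls, then sites with
   pooled minor allele frequency < 5%; report the Ts/Tv ratio and
   per-population polymorphic counts.
2. **Population structure** — LD pruning (sliding 25-SNP windows, 5-SNP
   step, r² > 0.05), PCA with Patterson scaling, a neighbor-joining tree
   over allele-sharing distances, and an admixture-style binomial mixture
   fitted by EM for K = 1…4 with cross-validated prediction error.
3. **Selection scan** — in 100 kb windows sliding by 10 kb:
   - Weir–Cockerham F_ST from per-site variance components a, b, c,
     combined per window as Σa / Σ(a+b+c);
   - nucleotide diversity π per population (per-site unbiased
     heterozygosity (m/(m−1))·2p̂q̂ summed over the window, divided by window
     length) and the ratio π_other/π_target, so large values flag diversity
     loss in the putatively selected population;
   - Tajima's D in the target population,
     D = (θ_π − S/a₁) / √(e₁S + e₂S(S−1)).
4. **Candidate calling** — windows in the top 5% of *both* F_ST and π ratio
   (joint set), and windows in the bottom 5% of D; SNPs inside candidate
   windows are extended ± 50 kb and merged into candidate regions.
5. **Gene annotation** — regions → overlapping genes (GFF3, ≥ 1 bp), Venn
   intersection of the two methods' gene lists per contrast, and the shared
   genes between the two contrast directions.
6. **Enrichment** — one-sided hypergeometric over-representation of the
   final gene list against GMT gene sets, background = the full annotation,
   with BH-adjusted p values reported alongside.

A Balding–Nichols simulator with injectable selective sweeps generates
complete synthetic cohorts (VCF + population map + GFF3 + GMT + truth BED),
so the whole pipeline is testable offline with known ground truth.

## Worked example

The bundled demo simulates 20 + 20 diploid samples on two 2 Mb chromosomes
(~1 SNP/kb, background F = 0.05) with one 100 kb sweep per contrast
direction, then runs every stage:

```sh
sweepscan run --demo-dir results/demo --seed 1
```

or stage by stage with the numbered drivers:

```sh
cd analysis && python 01_simulate.py && python 02_qc.py && ...
```

Typical output (seed 1):

```
sites in: 4000, removed by missing-rate filter: 0, by MAF filter: 211, retained: 3789
contrast targeting GBB:
  fst_pi_joint: 12 windows, 176 candidate SNPs, 1 merged regions
    joint region chr1:790334-1099535 (176 SNPs)
contrast targeting GBB: 7 genes from the joint scan, 9 from Tajima's D, 7 in the final Venn list
  final: G00016, G00017, G00018, G00019, G00020, G00021, G00022
```

The single joint candidate region on chr1 covers the injected sweep
(chr1:900001–1000000 targeting the GBB population), and the final Venn gene
list contains the two genes that truly overlap it (G00019, G00020) plus
their ± 50 kb flank neighbors — exactly what the ± flank extension is meant
to capture. The reciprocal contrast (GBW) recovers the chr2 sweep the same
way, and the two final lists share no genes because the two sweeps are on
different chromosomes.

`analysis/07_calibration_power.py` quantifies the caller: under F = 0 the
joint top-5% window fraction sits near q² = 0.0025 (0.0055 observed, the
mild excess being the expected positive correlation between F_ST and
π ratio) and the Tajima bottom-5% fraction at 0.0501; the injected sweep is
detected in 20/20 replicates.

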