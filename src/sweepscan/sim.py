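"""Two-population diploid genotype simulator with injectable selective sweeps.

The generator draws independent biallelic SNPs under the Balding-Nichols
model: an ancestral allele frequency p ~ Uniform(maf_floor, 1 - maf_floor),
then each population's frequency p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) where F
is the divergence parameter (p_k = p exactly when F = 0), and genotypes
~ Binomial(2, p_k). This gives an exact, closed-form null for the windowed
differentiation statistics: the expected Weir-Cockerham F_ST equals F.

Sweeps operate on the frequency track, not on haplotypes: inside the swept
interval the target population's frequencies are pushed toward the nearer of
{0, 1} and genotypes are redrawn, producing the classic sweep signature the
scan screens for — elevated F_ST, elevated diversity ratio, and an excess of
rare variants (negative Tajima's D) in the swept population. Linkage is not
simulated; windows detect sweeps through the per-site frequency shifts alone.

The default cohort mirrors a balanced two-color resequencing design: two
populations of 20 diploid males each, a few Mb of genome at roughly one SNP
per kb, weak background divergence and a small missing-call rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, SITE_COLUMNS, GenotypeMatrix, PopulationAssignment
from .qc import write_vcf

_BASES = np.array(["A", "C", "G", "T"])


def _default_chroms() -> dict[str, int]:
    return {"chr1": 2_000_000, "chr2": 2_000_000}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-population genotype simulation.

    Parameters
    ----------
    n_pop1, n_pop2 : int
        Diploid sample sizes (>= 2 each). Default 20 + 20.
    chrom_lengths : dict
        Chromosome name -> length in bp.
    snp_density : float
        Expected SNPs per bp (default 1e-3, ~one SNP per kb).
    baseline_F : float
        Balding-Nichols divergence parameter in [0, 1).
    missing_rate : float
        Per-genotype missing probability in [0, 1).
    maf_floor : float
        Minimum ancestral allele frequency in [0, 0.5).
    seed : int
        RNG seed; identical config + seed gives bit-identical output.
    """

    n_pop1: int = 20
    n_pop2: int = 20
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    snp_density: float = 1e-3
    baseline_F: float = 0.05
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    seed: int = 0
    pop1_label: str = "pop1"
    pop2_label: str = "pop2"

    def validate(self) -> None:
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ValueError("need at least 2 diploid samples per population")
        if not (0.0 <= self.baseline_F < 1.0):
            raise ValueError("baseline_F must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if all(int(round(self.snp_density * l)) == 0 for l in self.chrom_lengths.values()):
            raise ValueError("snp_density implies zero simulated sites")
        if self.pop1_label == self.pop2_label:
            raise ValueError("population labels must differ")


@dataclass(frozen=True)
class SweepSpec:
    """A localized selective sweep to inject into one population.

    ``sweep_strength`` s in [0, 1] moves each target-population allele
    frequency toward the nearer of {0, 1}: p' = p(1-s) if p < 0.5 else
    p + (1-p)s. s = 1 forces fixation (window diversity 0); s = 0 is the
    identity and leaves genotypes untouched.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    target_pop: str
    sweep_strength: float = 0.9

    def validate(self, chrom_lengths: dict[str, int], pop_labels: list[str]) -> None:
        if self.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if not (1 <= self.start <= self.end <= chrom_lengths[self.chrom]):
            raise ValueError("sweep interval outside chromosome")
        if self.target_pop not in pop_labels:
            raise ValueError(f"unknown target population {self.target_pop!r}")
        if not (0.0 <= self.sweep_strength <= 1.0):
            raise ValueError("sweep_strength must be in [0, 1]")


@dataclass
class TruthTrack:
    """Ground truth recorded by the simulator, for power/calibration studies.

    ``pop_freqs`` has shape (2, n_sites): realized allele frequencies per
    population, aligned with the genotype matrix's sites. ``is_transition``
    records which ref/alt pairs are transitions (A<->G, C<->T).
    """

    sweeps: list[SweepSpec]
    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray
    is_transition: np.ndarray
    pop_labels: list[str]

    def validate(self) -> None:
        if ((self.pop_freqs < 0) | (self.pop_freqs > 1)).any():
            raise ValueError("population frequencies outside [0, 1]")


def simulate_two_pop(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PopulationAssignment, TruthTrack]:
    """Simulate the two-population cohort under the Balding-Nichols model.

    Sample order is all of population 1 followed by all of population 2;
    site positions are strictly increasing within each chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_pop1, config.n_pop2
    F = config.baseline_F

    chroms_col: list[str] = []
    pos_col: list[np.ndarray] = []
    ref_col: list[np.ndarray] = []
    alt_col: list[np.ndarray] = []
    p1_parts: list[np.ndarray] = []
    p2_parts: list[np.ndarray] = []
    panc_parts: list[np.ndarray] = []
    ts_parts: list[np.ndarray] = []
    dose_parts: list[np.ndarray] = []

    for chrom, length in config.chrom_lengths.items():
        n_sites = int(round(config.snp_density * length))
        if n_sites == 0:
            continue
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, n_sites)
        if F > 0:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p1 = rng.beta(a, b)
            p2 = rng.beta(a, b)
        else:
            p1 = p_anc.copy()
            p2 = p_anc.copy()
        dose = np.concatenate(
            [
                rng.binomial(2, p1, size=(n1, n_sites)),
                rng.binomial(2, p2, size=(n2, n_sites)),
            ],
            axis=0,
        ).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng.random(dose.shape) < config.missing_rate
            dose[mask] = MISSING
        ref_idx = rng.integers(0, 4, n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
        # with bases ordered A,C,G,T a transition is exactly ref_idx XOR alt_idx == 2
        is_ts = (ref_idx ^ alt_idx) == 2

        chroms_col.extend([chrom] * n_sites)
        pos_col.append(pos)
        ref_col.append(_BASES[ref_idx])
        alt_col.append(_BASES[alt_idx])
        p1_parts.append(p1)
        p2_parts.append(p2)
        panc_parts.append(p_anc)
        ts_parts.append(is_ts)
        dose_parts.append(dose)

    sites = pd.DataFrame(
        {
            "chrom": chroms_col,
            "pos": np.concatenate(pos_col),
            "ref": np.concatenate(ref_col),
            "alt": np.concatenate(alt_col),
        },
        columns=SITE_COLUMNS,
    )
    dosage = np.concatenate(dose_parts, axis=1)
    sample_ids = [f"{config.pop1_label}_{i+1:02d}" for i in range(n1)] + [
        f"{config.pop2_label}_{i+1:02d}" for i in range(n2)
    ]
    g = GenotypeMatrix(sample_ids, sites, dosage, dict(config.chrom_lengths))
    pops = PopulationAssignment(
        {s: (config.pop1_label if i < n1 else config.pop2_label)
         for i, s in enumerate(sample_ids)}
    )
    truth = TruthTrack(
        sweeps=[],
        ancestral_freqs=np.concatenate(panc_parts),
        pop_freqs=np.stack([np.concatenate(p1_parts), np.concatenate(p2_parts)]),
        is_transition=np.concatenate(ts_parts),
        pop_labels=[config.pop1_label, config.pop2_label],
    )
    return g, pops, truth


def inject_sweep(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    truth: TruthTrack,
    spec: SweepSpec,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthTrack]:
    """Push target-population frequencies toward fixation inside an interval
    and redraw the affected genotypes (missing calls stay missing).

    Returns new objects; inputs are not modified. ``sweep_strength = 0`` is
    the identity and performs no redraw.
    """
    spec.validate(g.chrom_lengths, truth.pop_labels)
    new_truth = TruthTrack(
        sweeps=truth.sweeps + [spec],
        ancestral_freqs=truth.ancestral_freqs.copy(),
        pop_freqs=truth.pop_freqs.copy(),
        is_transition=truth.is_transition.copy(),
        pop_labels=list(truth.pop_labels),
    )
    g_new = GenotypeMatrix(
        list(g.sample_ids), g.sites.copy(), g.dosage.copy(), dict(g.chrom_lengths)
    )
    s = spec.sweep_strength
    if s == 0.0:
        return g_new, new_truth

    site_mask = (
        (g.sites["chrom"] == spec.chrom)
        & (g.sites["pos"] >= spec.start)
        & (g.sites["pos"] <= spec.end)
    ).to_numpy()
    k = truth.pop_labels.index(spec.target_pop)
    p = truth.pop_freqs[k, site_mask]
    p_new = np.where(p < 0.5, p * (1.0 - s), p + (1.0 - p) * s)
    new_truth.pop_freqs[k, site_mask] = p_new

    rows = pops.indices(g, spec.target_pop)
    rng = np.random.default_rng(seed)
    redraw = rng.binomial(2, p_new, size=(len(rows), int(site_mask.sum()))).astype(np.int8)
    block = g_new.dosage[np.ix_(rows, np.flatnonzero(site_mask))]
    redraw[block == MISSING] = MISSING
    g_new.dosage[np.ix_(rows, np.flatnonzero(site_mask))] = redraw
    return g_new, new_truth


def make_gene_models(
    chrom_lengths: dict[str, int],
    gene_length: int = 40_000,
    gene_spacing: int = 50_000,
) -> pd.DataFrame:
    """Non-overlapping genes tiling each chromosome (1-based inclusive)."""
    rows = []
    counter = 0
    for chrom, length in chrom_lengths.items():
        start = 5_001
        i = 0
        while start + gene_length - 1 <= length:
            counter += 1
            rows.append(
                {
                    "gene_id": f"G{counter:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_length - 1,
                    "strand": "+" if i % 2 == 0 else "-",
                }
            )
            i += 1
            start += gene_spacing
    return pd.DataFrame(rows)


def _genes_overlapping(genes: pd.DataFrame, chrom: str, start: int, end: int) -> list[str]:
    m = (genes["chrom"] == chrom) & (genes["start"] <= end) & (genes["end"] >= start)
    return genes.loc[m, "gene_id"].tolist()


def write_fixture_bundle(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    truth: TruthTrack,
    outdir,
    seed: int = 0,
    n_decoy_sets: int = 20,
    decoy_set_size: int = 20,
) -> dict[str, str]:
    """Write the simulated cohort as standard files.

    Emits a GT-only VCF v4.2, a two-column sample/population TSV, a GFF3 of
    non-overlapping genes tiling each chromosome, a GMT of gene sets — the
    first set contains every gene overlapping a sweep interval, so it is
    enriched among sweep-region genes by construction — and a BED
    (0-based half-open) of the true sweep intervals. No timestamps are
    written, so repeated calls are byte-identical.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "popmap": os.path.join(outdir, "populations.tsv"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "gmt": os.path.join(outdir, "genesets.gmt"),
        "truth_bed": os.path.join(outdir, "truth_sweeps.bed"),
    }
    write_vcf(g, paths["vcf"])
    pops.to_tsv(paths["popmap"])

    genes = make_gene_models(g.chrom_lengths)
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write(
                f"{row.chrom}\tsweepscan_sim\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )

    rng = np.random.default_rng(seed)
    all_ids = genes["gene_id"].tolist()
    sweep_genes: list[str] = []
    for sw in truth.sweeps:
        sweep_genes.extend(_genes_overlapping(genes, sw.chrom, sw.start, sw.end))
    sweep_genes = sorted(set(sweep_genes))
    sets: list[tuple[str, list[str]]] = []
    if sweep_genes:
        padded = list(sweep_genes)
        if len(padded) < decoy_set_size:
            pool = [x for x in all_ids if x not in set(padded)]
            extra = rng.choice(pool, size=decoy_set_size - len(padded), replace=False)
            padded += sorted(extra.tolist())
        sets.append(("sweep_region_set", padded))
    for i in range(n_decoy_sets):
        members = rng.choice(all_ids, size=min(decoy_set_size, len(all_ids)), replace=False)
        sets.append((f"decoy_set_{i+1:02d}", sorted(members.tolist())))
    with open(paths["gmt"], "w") as fh:
        for name, members in sets:
            fh.write(name + "\tsimulated gene set\t" + "\t".join(members) + "\n")

    with open(paths["truth_bed"], "w") as fh:
        for sw in truth.sweeps:
            fh.write(f"{sw.chrom}\t{sw.start - 1}\t{sw.end}\t{sw.target_pop}\n")
    return paths
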