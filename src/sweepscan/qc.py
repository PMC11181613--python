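"""VCF input/output and SNP-level quality control.

The pipeline starts from a multi-sample VCF of diploid genotypes. Sites are
filtered the way short-read resequencing panels are usually cleaned before a
selection scan: drop loci with a high missing-call rate, then drop loci whose
pooled minor allele frequency is too low to be informative. The transition /
transversion ratio of the retained panel is reported as a global sanity check
(whole-genome panels typically land a little above 2).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import MISSING, SITE_COLUMNS, GenotypeMatrix, PopulationAssignment

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


def read_vcf(path, population_map=None) -> tuple[GenotypeMatrix, PopulationAssignment | None]:
    """Read a VCF (v4.2, GT field) into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multiallelic or non-SNP records are
    skipped and their count logged. Phased and unphased genotypes are treated
    identically; any genotype with a missing allele (``./.`` or half-calls)
    becomes :data:`MISSING`.

    Parameters
    ----------
    path : str
        VCF file path (plain text or bgzipped).
    population_map : str, dict or PopulationAssignment, optional
        Sample -> population assignment. When given, the sample sets of the
        VCF and the map must match exactly.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)

    pops: PopulationAssignment | None = None
    if population_map is not None:
        if isinstance(population_map, PopulationAssignment):
            pops = population_map
        elif isinstance(population_map, dict):
            pops = PopulationAssignment(dict(population_map))
        else:
            pops = PopulationAssignment.from_tsv(population_map)
        missing_from_vcf = set(pops.mapping) - set(samples)
        if missing_from_vcf:
            raise ValueError(
                f"samples in population map absent from VCF: {sorted(missing_from_vcf)}"
            )
        unassigned = set(samples) - set(pops.mapping)
        if unassigned:
            raise ValueError(f"VCF samples missing from population map: {sorted(unassigned)}")

    chrom_lengths: dict[str, int] = {}
    try:
        chrom_lengths = {c: int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)}
    except Exception:  # header without contig lengths
        chrom_lengths = {}

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        alt = v.ALT
        if len(alt) != 1 or len(v.REF) != 1 or len(alt[0]) != 1 \
                or v.REF not in _BASES or alt[0] not in _BASES:
            n_skipped += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dose = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2 or min(alleles) < 0:
                dose[i] = MISSING
            else:
                dose[i] = alleles[0] + alleles[1]
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(alt[0])
        rows.append(dose)
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts},
        columns=SITE_COLUMNS,
    )
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    g = GenotypeMatrix(samples, sites, dosage, chrom_lengths)
    return g, pops


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2. No timestamps, so output is reproducible."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lengths = dict(g.chrom_lengths)
    for chrom, grp in g.sites.groupby("chrom", sort=False):
        lengths.setdefault(chrom, int(grp["pos"].max()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        sites = g.sites
        for j in range(g.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(code[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


@dataclass
class QcReport:
    """Bookkeeping for one round of site filtering.

    Invariant: ``n_sites_out == n_sites_in - n_removed_missing - n_removed_maf``.
    """

    n_sites_in: int
    n_removed_missing: int
    n_removed_maf: int
    n_sites_out: int
    ts_tv_ratio: float
    per_pop_polymorphic: dict[str, int]
    shared_polymorphic: int

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        if math.isinf(d["ts_tv_ratio"]):
            d["ts_tv_ratio"] = "inf"
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        d = dataclasses.asdict(self)
        pops = d.pop("per_pop_polymorphic")
        for k, v in pops.items():
            d[f"polymorphic_{k}"] = v
        pd.DataFrame([d]).to_csv(path, sep="\t", index=False)


def _allele_stats(dosage: np.ndarray):
    """Per-site (non-missing diploid count, ALT allele frequency)."""
    obs = dosage != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    return n, p


def _polymorphic(dosage: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Boolean mask of sites segregating within the given sample rows."""
    sub = dosage[idx]
    obs = sub != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, sub, 0).sum(axis=0)
    return (alt > 0) & (alt < 2 * n)


def filter_sites(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    pops: PopulationAssignment | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply missing-rate and pooled-MAF site filters.

    A site is removed if its missing fraction (over all samples) exceeds
    ``max_missing`` (strict), then removed if its minor allele frequency over
    the remaining non-missing alleles — both populations pooled — is below
    ``min_maf`` (kept when exactly equal). A site with every genotype missing
    has undefined MAF and falls under the MAF rule.
    """
    if not (0 <= max_missing < 1):
        raise ValueError("max_missing must be in [0, 1)")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")

    miss_frac = (g.dosage == MISSING).mean(axis=0)
    pass_missing = miss_frac <= max_missing

    n_obs, p = _allele_stats(g.dosage)
    maf = np.minimum(p, 1.0 - p)
    pass_maf = (n_obs > 0) & (maf >= min_maf)

    keep = pass_missing & pass_maf
    n_removed_missing = int((~pass_missing).sum())
    n_removed_maf = int((pass_missing & ~pass_maf).sum())

    out = g.take_sites(np.flatnonzero(keep))

    per_pop: dict[str, int] = {}
    shared = 0
    if pops is not None:
        masks = []
        for pop in pops.labels:
            mask = _polymorphic(out.dosage, pops.indices(out, pop))
            per_pop[pop] = int(mask.sum())
            masks.append(mask)
        if masks:
            shared = int(np.logical_and.reduce(masks).sum())

    report = QcReport(
        n_sites_in=g.n_sites,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
        n_sites_out=out.n_sites,
        ts_tv_ratio=ts_tv(out) if out.n_sites else float("nan"),
        per_pop_polymorphic=per_pop,
        shared_polymorphic=shared,
    )
    return out, report


def ts_tv(g: GenotypeMatrix) -> float:
    """Transition/transversion ratio over sites.

    Transitions are A<->G and C<->T; everything else is a transversion.
    Returns ``inf`` when there are transitions but no transversions.
    """
    if g.n_sites == 0:
        raise ValueError("ts_tv requires at least one site")
    pairs = list(zip(g.sites["ref"], g.sites["alt"]))
    ts = sum(p in TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        return float("inf")
    return ts / tv
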