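"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as allele-dose codes: 0/1/2 copies of the ALT allele,
with ``MISSING`` (-1) for uncalled genotypes. Sites carry 1-based positions
as in VCF; interval outputs (BED, candidate regions) are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP allele-dose matrix with per-site metadata.

    Attributes
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows of ``dosage``).
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; positions strictly increasing within each chromosome.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        ALT-allele dose in {0, 1, 2} or ``MISSING``.
    chrom_lengths : dict
        Chromosome name -> length in bp (from VCF contig headers or the
        simulator); used for windowing and interval clipping.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset sites by positional index, preserving order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            sites=self.sites,
            dosage=self.dosage[index, :],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def validate(self) -> None:
        """Check container invariants; raises ValueError on violation."""
        d = self.dosage
        bad = ~np.isin(d, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage codes outside {0,1,2,missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref == alt at some site")


@dataclass
class PopulationAssignment:
    """Mapping sample id -> population label, order-preserving."""

    mapping: dict[str, str]

    @property
    def labels(self) -> list[str]:
        """Population labels in first-seen order."""
        seen: list[str] = []
        for p in self.mapping.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, pop: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == pop]

    def indices(self, g: GenotypeMatrix, pop: str) -> np.ndarray:
        """Row indices of ``pop``'s samples in ``g``."""
        if pop not in self.labels:
            raise KeyError(f"unknown population: {pop!r}")
        members = set(self.samples(pop))
        return np.array(
            [i for i, s in enumerate(g.sample_ids) if s in members], dtype=int
        )

    @classmethod
    def from_tsv(cls, path) -> "PopulationAssignment":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"population map line has <2 columns: {line!r}")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")
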