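"""Map candidate regions to genes and intersect per-method gene lists.

Annotation here is pure region <-> gene interval overlap: a gene is reported
for a region when their intervals share at least one bp (gene coordinates
are 1-based inclusive as in GFF3; regions are 0-based half-open). The final
candidate list for a contrast is the Venn intersection of the gene lists
found by the joint F_ST/pi-ratio scan and by the Tajima's D scan; genes in
the final lists of both contrast directions are the shared genes.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Parse gene features from a GFF3 file.

    Only features whose type column equals ``feature_type`` are kept; the
    gene identifier is taken from the ``ID`` attribute. Coordinates stay
    1-based inclusive. Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature_type:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start > end")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: feature has no ID attribute")
            rows.append((gene_id, chrom, start_i, end_i, strand))
    if not rows:
        logger.warning("read_gff3: no %r features found in %s", feature_type, path)
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene ID {dup!r} in {path}")
    return df


def regions_to_genes(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    min_overlap: int = 1,
) -> list[str]:
    """Genes whose interval overlaps any candidate region by >= min_overlap bp.

    Gene [start, end] (1-based inclusive) converts to [start-1, end) 0-based
    half-open; overlap length with region [rs, re) is
    min(end, re) - max(start-1, rs). The result is deduplicated and sorted.
    """
    hits: set[str] = set()
    for chrom, rgrp in regions.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        gs = gsub["start"].to_numpy() - 1
        ge = gsub["end"].to_numpy()
        ids = gsub["gene_id"].to_numpy()
        for row in rgrp.itertuples():
            ov = (
                pd.Series(ge).clip(upper=row.end).to_numpy()
                - pd.Series(gs).clip(lower=row.start).to_numpy()
            )
            hits.update(ids[ov >= min_overlap])
    return sorted(hits)


def venn_final(method_gene_lists: dict[str, list[str]]) -> list[str]:
    """Final candidate list: intersection of the per-method gene lists."""
    if len(method_gene_lists) < 2:
        raise ValueError("need at least two method gene lists")
    sets = [set(v) for v in method_gene_lists.values()]
    final = set.intersection(*sets)
    return sorted(final)


def shared_genes(final_contrast1: list[str], final_contrast2: list[str]) -> list[str]:
    """Genes appearing in the final candidate lists of both contrasts."""
    return sorted(set(final_contrast1) & set(final_contrast2))


def venn_counts(method_gene_lists: dict[str, list[str]]) -> dict[str, int]:
    """Per-method sizes plus the intersection size, for reporting."""
    out = {name: len(set(v)) for name, v in method_gene_lists.items()}
    out["intersection"] = len(venn_final(method_gene_lists))
    return out
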