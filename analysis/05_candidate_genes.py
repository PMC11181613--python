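#!/usr/bin/env python
"""Candidate genes: overlap the merged candidate regions with the gene
models, intersect the joint-scan and Tajima gene lists per contrast (Venn),
and intersect the two contrasts' final lists into shared genes.

Writes results/demo/genes/."""

import json

from common import get_config, get_manifest
from sweepscan.pipeline import run_stage


def main():
    cfg = get_config()
    manifest = get_manifest(cfg)
    run_stage("annotate", cfg, manifest)
    for target in cfg.contrasts:
        with open(cfg.path("genes", target, "venn_counts.json")) as fh:
            counts = json.load(fh)
        print(f"contrast targeting {target}: "
              f"{counts['fst_pi_joint']} genes from the joint scan, "
              f"{counts['tajima_low']} from Tajima's D, "
              f"{counts['intersection']} in the final Venn list")
        with open(cfg.path("genes", target, "genes_final.txt")) as fh:
            final = fh.read().split()
        print(f"  final: {', '.join(final) if final else '(none)'}")
    with open(cfg.path("genes", "shared_genes.txt")) as fh:
        shared = fh.read().split()
    print(f"shared between contrasts: {len(shared)} gene(s)"
          + (f": {', '.join(shared)}" if shared else ""))


if __name__ == "__main__":
    main()
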