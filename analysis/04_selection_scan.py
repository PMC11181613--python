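#!/usr/bin/env python
"""Selection scan: windowed Weir-Cockerham F_ST, pi ratio and Tajima's D in
100 kb windows sliding by 10 kb, for both contrast directions; candidate
windows from the top-5% joint F_ST & pi-ratio rule and the bottom-5%
Tajima's D rule; candidate SNPs extended +/- 50 kb and merged into regions.

Writes results/demo/scan/<target>/ for target in {GBB, GBW}."""

import pandas as pd

from common import get_config, get_manifest
from sweepscan.pipeline import run_stage


def main():
    cfg = get_config()
    manifest = get_manifest(cfg)
    run_stage("scan", cfg, manifest)
    for target in cfg.contrasts:
        print(f"contrast targeting {target}:")
        for method in ("fst_pi_joint", "tajima_low"):
            nw = manifest.row_counts[f"{target}_{method}_windows"]
            ns = manifest.row_counts[f"{target}_{method}_sites"]
            nr = manifest.row_counts[f"{target}_{method}_regions"]
            print(f"  {method}: {nw} windows, {ns} candidate SNPs, "
                  f"{nr} merged regions")
        bed = pd.read_csv(
            cfg.path("scan", target, "regions_fst_pi_joint.bed"), sep="\t",
            header=None, names=["chrom", "start", "end", "method", "n_sites"],
        )
        for row in bed.itertuples():
            print(f"    joint region {row.chrom}:{row.start}-{row.end} "
                  f"({row.n_sites} SNPs)")


if __name__ == "__main__":
    main()
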