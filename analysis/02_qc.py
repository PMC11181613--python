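#!/usr/bin/env python
"""SNP quality control: drop sites with > 20% missing calls, then sites with
pooled MAF < 5%; report Ts/Tv and per-population polymorphic counts.

Reads results/demo/data/cohort.vcf, writes results/demo/qc/."""

import json

from common import get_config, get_manifest
from sweepscan.pipeline import run_stage


def main():
    cfg = get_config()
    manifest = get_manifest(cfg)
    run_stage("qc", cfg, manifest)
    with open(cfg.path("qc", "qc_report.json")) as fh:
        rep = json.load(fh)
    print(f"sites in: {rep['n_sites_in']}, removed by missing-rate filter: "
          f"{rep['n_removed_missing']}, by MAF filter: {rep['n_removed_maf']}, "
          f"retained: {rep['n_sites_out']}")
    print(f"Ts/Tv of retained panel: {rep['ts_tv_ratio']:.3f} "
          "(the simulator draws alleles uniformly, so ~0.5 is expected)")
    for pop, n in rep["per_pop_polymorphic"].items():
        print(f"  polymorphic in {pop}: {n}")
    print(f"  polymorphic in both: {rep['shared_polymorphic']}")


if __name__ == "__main__":
    main()
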