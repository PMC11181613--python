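"""Shared setup for the numbered analysis drivers: one demo cohort
(2 chromosomes x 2 Mb, 20 black + 20 white diploid samples, one injected
sweep per contrast direction) analyzed stage by stage into results/demo."""

import os

from sweepscan.pipeline import RunManifest, demo_config

SEED = 1
OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "demo")


def get_config():
    return demo_config(os.path.abspath(OUTDIR), seed=SEED)


def get_manifest(cfg):
    return RunManifest(config_hash=cfg.config_hash(), software_version="analysis")
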