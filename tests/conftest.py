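import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sweepscan.sim import SimConfig, SweepSpec, inject_sweep, simulate_two_pop
from sweepscan.types import GenotypeMatrix, PopulationAssignment

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_matrix(dosage, chrom="chr1", positions=None, chrom_length=None,
                sample_prefix="s"):
    """GenotypeMatrix from a raw dosage array (samples x sites)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    length = chrom_length or int(max(positions, default=1)) + 100
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n_samples)], sites, dosage,
        {chrom: length},
    )


def two_pop_assignment(g, n1):
    return PopulationAssignment(
        {s: ("pop1" if i < n1 else "pop2") for i, s in enumerate(g.sample_ids)}
    )


@pytest.fixture(scope="session")
def small_cohort():
    """20+20 samples, one 1 Mb chromosome, moderate divergence."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 1_000_000}, snp_density=1e-3,
        baseline_F=0.1, missing_rate=0.02, seed=42,
    )
    g, pops, truth = simulate_two_pop(cfg)
    return cfg, g, pops, truth


@pytest.fixture(scope="session")
def sweep_cohort():
    """Two chromosomes with a strong sweep in pop1 on chr1."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        baseline_F=0.05, missing_rate=0.02, seed=7,
    )
    g, pops, truth = simulate_two_pop(cfg)
    sweep = SweepSpec("chr1", 900_001, 1_000_000, "pop1", 0.9)
    g, truth = inject_sweep(g, pops, truth, sweep, seed=77)
    return cfg, g, pops, truth, sweep
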