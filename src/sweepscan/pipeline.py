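"""Config-driven orchestration: simulate -> qc -> structure -> scan ->
annotate -> enrich, with a JSON manifest for deterministic reruns.

Each stage reads the previous stage's interface files from the run directory
and writes its own, so stages can also be invoked independently (see
:mod:`sweepscan.cli`). All randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version

import pandas as pd
import yaml

from . import annotate as ann
from . import enrich as enr
from . import popstruct as ps
from . import qc as qcmod
from . import scan as scanmod
from . import sim as simmod
from .types import GenotypeMatrix, PopulationAssignment

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Either ``simulation`` (a SimConfig plus sweep specs) or ``inputs`` (paths
    to VCF / population map / GFF3 / GMT) must be present. ``contrasts``
    lists the target population of each contrast direction; with two
    populations both directions are usually run.
    """

    outdir: str
    seed: int = 0
    simulation: simmod.SimConfig | None = None
    sweeps: list[simmod.SweepSpec] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    contrasts: list[str] = field(default_factory=list)
    max_missing: float = 0.20
    min_maf: float = 0.05
    prune_window_snps: int = 25
    prune_step_snps: int = 5
    prune_r2_max: float = 0.05
    pca_components: int = 5
    k_values: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    cv_folds: int = 5
    window_size: int = 100_000
    window_step: int = 10_000
    min_snps: int = 10
    quantile: float = 0.05
    flank: int = 50_000
    alpha: float = 0.05

    def validate(self) -> None:
        if self.simulation is None and not self.inputs:
            raise ValueError("config needs a simulation block or input paths")
        if self.simulation is not None:
            self.simulation.validate()
            labels = [self.simulation.pop1_label, self.simulation.pop2_label]
            for sw in self.sweeps:
                sw.validate(self.simulation.chrom_lengths, labels)
        if not self.contrasts:
            raise ValueError("at least one contrast (target population) required")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim_cfg = None
        sweeps: list[simmod.SweepSpec] = []
        if "simulation" in raw:
            sim_raw = dict(raw.pop("simulation"))
            for sw in sim_raw.pop("sweeps", []):
                sweeps.append(simmod.SweepSpec(**sw))
            sim_raw.setdefault("seed", raw.get("seed", 0))
            sim_cfg = simmod.SimConfig(**sim_raw)
        cfg = cls(
            outdir=raw.pop("outdir"),
            seed=raw.pop("seed", 0),
            simulation=sim_cfg,
            sweeps=sweeps,
            inputs=raw.pop("inputs", {}),
            contrasts=raw.pop("contrasts", []),
            **{k: v for k, v in raw.items()},
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir, "seed": self.seed,
            "contrasts": list(self.contrasts), "inputs": dict(self.inputs),
            "max_missing": self.max_missing, "min_maf": self.min_maf,
            "prune_window_snps": self.prune_window_snps,
            "prune_step_snps": self.prune_step_snps,
            "prune_r2_max": self.prune_r2_max,
            "pca_components": self.pca_components,
            "k_values": list(self.k_values), "cv_folds": self.cv_folds,
            "window_size": self.window_size, "window_step": self.window_step,
            "min_snps": self.min_snps, "quantile": self.quantile,
            "flank": self.flank, "alpha": self.alpha,
        }
        if self.simulation is not None:
            sim_d = {
                "n_pop1": self.simulation.n_pop1,
                "n_pop2": self.simulation.n_pop2,
                "chrom_lengths": dict(self.simulation.chrom_lengths),
                "snp_density": self.simulation.snp_density,
                "baseline_F": self.simulation.baseline_F,
                "missing_rate": self.simulation.missing_rate,
                "maf_floor": self.simulation.maf_floor,
                "seed": self.simulation.seed,
                "pop1_label": self.simulation.pop1_label,
                "pop2_label": self.simulation.pop2_label,
                "sweeps": [vars(sw) if not hasattr(sw, "__dataclass_fields__")
                           else {f: getattr(sw, f) for f in
                                 ("chrom", "start", "end", "target_pop", "sweep_strength")}
                           for sw in self.sweeps],
            }
            d["simulation"] = sim_d
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # conventional stage file paths -------------------------------------
    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)

    @property
    def vcf_path(self) -> str:
        return self.inputs.get("vcf", self.path("data", "cohort.vcf"))

    @property
    def popmap_path(self) -> str:
        return self.inputs.get("popmap", self.path("data", "populations.tsv"))

    @property
    def gff3_path(self) -> str:
        return self.inputs.get("gff3", self.path("data", "genes.gff3"))

    @property
    def gmt_path(self) -> str:
        return self.inputs.get("gmt", self.path("data", "genesets.gmt"))

    @property
    def filtered_vcf_path(self) -> str:
        return self.path("qc", "filtered.vcf")


def demo_config(outdir: str, seed: int = 1) -> RunConfig:
    """The bundled demo: 2 chromosomes x 2 Mb, 20+20 samples, one sweep per
    contrast direction."""
    sim_cfg = simmod.SimConfig(
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        baseline_F=0.05, seed=seed,
        pop1_label="GBB", pop2_label="GBW",
    )
    sweeps = [
        simmod.SweepSpec("chr1", 900_001, 1_000_000, "GBB", 0.9),
        simmod.SweepSpec("chr2", 500_001, 600_000, "GBW", 0.9),
    ]
    cfg = RunConfig(
        outdir=outdir, seed=seed, simulation=sim_cfg, sweeps=sweeps,
        contrasts=["GBB", "GBW"],
    )
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "software_version": self.software_version,
                    "row_counts": self.row_counts,
                    "stage_seconds": self.stage_seconds,
                },
                fh, indent=2,
            )
            fh.write("\n")


def _require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise StageError(f"missing upstream file {path!r}; run the {producer} stage first")
    return path


def _load_filtered(cfg: RunConfig) -> tuple[GenotypeMatrix, PopulationAssignment]:
    g, pops = qcmod.read_vcf(
        _require(cfg.filtered_vcf_path, "qc"),
        _require(cfg.popmap_path, "simulate"),
    )
    return g, pops


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, manifest: RunManifest) -> None:
    if cfg.simulation is None:
        logger.info("simulate: external inputs supplied, nothing to do")
        return
    g, pops, truth = simmod.simulate_two_pop(cfg.simulation)
    for i, sw in enumerate(cfg.sweeps):
        g, truth = simmod.inject_sweep(g, pops, truth, sw, seed=cfg.seed + 1000 + i)
    simmod.write_fixture_bundle(g, pops, truth, cfg.path("data"), seed=cfg.seed)
    manifest.row_counts["simulated_sites"] = g.n_sites
    manifest.row_counts["simulated_samples"] = g.n_samples


def stage_qc(cfg: RunConfig, manifest: RunManifest) -> None:
    g, pops = qcmod.read_vcf(
        _require(cfg.vcf_path, "simulate"), _require(cfg.popmap_path, "simulate")
    )
    if len(pops.labels) != 2:
        raise StageError(f"qc: expected exactly 2 populations, found {pops.labels}")
    filtered, report = qcmod.filter_sites(
        g, max_missing=cfg.max_missing, min_maf=cfg.min_maf, pops=pops
    )
    os.makedirs(cfg.path("qc"), exist_ok=True)
    qcmod.write_vcf(filtered, cfg.filtered_vcf_path)
    report.to_json(cfg.path("qc", "qc_report.json"))
    report.to_tsv(cfg.path("qc", "qc_report.tsv"))
    manifest.row_counts["qc_sites_in"] = report.n_sites_in
    manifest.row_counts["qc_sites_out"] = report.n_sites_out


def stage_structure(cfg: RunConfig, manifest: RunManifest) -> None:
    g, pops = _load_filtered(cfg)
    outdir = cfg.path("structure")
    os.makedirs(outdir, exist_ok=True)

    pruned = ps.ld_prune(
        g, cfg.prune_window_snps, cfg.prune_step_snps, cfg.prune_r2_max
    )
    pd.DataFrame({"site_index": pruned.indices}).to_csv(
        os.path.join(outdir, "pruned_sites.tsv"), sep="\t", index=False
    )

    pc = ps.pca(g, pruned, n_components=min(cfg.pca_components, g.n_samples - 1))
    coords = pd.DataFrame(
        pc.coords, columns=[f"PC{i+1}" for i in range(pc.coords.shape[1])]
    )
    coords.insert(0, "sample", g.sample_ids)
    coords.insert(1, "population", [pops.mapping[s] for s in g.sample_ids])
    coords.to_csv(os.path.join(outdir, "pca.tsv"), sep="\t", index=False)
    pd.DataFrame({"explained_variance_ratio": pc.explained_variance_ratio}).to_csv(
        os.path.join(outdir, "pca_evr.tsv"), sep="\t", index=False
    )

    dist = ps.distance_matrix(g)
    tree = ps.nj_build(dist, g.sample_ids)
    with open(os.path.join(outdir, "nj_tree.nwk"), "w") as fh:
        fh.write(tree.newick + "\n")

    cv_rows = []
    for K in cfg.k_values:
        fit = ps.admixture_em(g, pruned, K=K, seed=cfg.seed + 10 * K)
        qdf = pd.DataFrame(fit.Q, columns=[f"Q{k+1}" for k in range(K)])
        qdf.insert(0, "sample", g.sample_ids)
        qdf.to_csv(os.path.join(outdir, f"admixture_Q_K{K}.tsv"), sep="\t", index=False)
        err = ps.cv_error(
            g, pruned, K=K, n_folds=cfg.cv_folds, seed=cfg.seed + 100 + K
        ) if K >= 1 else float("nan")
        cv_rows.append((K, err, fit.loglik, fit.n_iter, fit.converged))
    pd.DataFrame(
        cv_rows, columns=["K", "cv_error", "loglik", "n_iter", "converged"]
    ).to_csv(os.path.join(outdir, "cv_error.tsv"), sep="\t", index=False)
    manifest.row_counts["pruned_sites"] = len(pruned.indices)


def stage_scan(cfg: RunConfig, manifest: RunManifest) -> None:
    g, pops = _load_filtered(cfg)
    spec = scanmod.WindowSpec(cfg.window_size, cfg.window_step)
    for target in cfg.contrasts:
        outdir = cfg.path("scan", target)
        os.makedirs(outdir, exist_ok=True)
        stats = scanmod.compute_window_stats(
            g, pops, target, spec, min_snps=cfg.min_snps
        )
        stats.to_csv(os.path.join(outdir, "windows.tsv"), sep="\t", index=False)
        joint, taj = scanmod.call_candidates(stats, g, q=cfg.quantile)
        for cs in (joint, taj):
            cs.sites.to_csv(
                os.path.join(outdir, f"candidate_sites_{cs.method}.tsv"),
                sep="\t", index=False,
            )
            regions = scanmod.extend_and_merge(cs, g.chrom_lengths, flank=cfg.flank)
            scanmod.write_regions_bed(
                regions, os.path.join(outdir, f"regions_{cs.method}.bed")
            )
            manifest.row_counts[f"{target}_{cs.method}_windows"] = len(cs.windows)
            manifest.row_counts[f"{target}_{cs.method}_sites"] = len(cs.sites)
            manifest.row_counts[f"{target}_{cs.method}_regions"] = len(regions)


def stage_annotate(cfg: RunConfig, manifest: RunManifest) -> None:
    genes = ann.read_gff3(_require(cfg.gff3_path, "simulate"))
    finals: dict[str, list[str]] = {}
    for target in cfg.contrasts:
        outdir = cfg.path("genes", target)
        os.makedirs(outdir, exist_ok=True)
        method_lists: dict[str, list[str]] = {}
        for method in ("fst_pi_joint", "tajima_low"):
            bed = _require(
                cfg.path("scan", target, f"regions_{method}.bed"), "scan"
            )
            regions = pd.read_csv(
                bed, sep="\t", header=None,
                names=["chrom", "start", "end", "methods", "n_sites"],
            )
            glist = ann.regions_to_genes(regions, genes)
            method_lists[method] = glist
            with open(os.path.join(outdir, f"genes_{method}.txt"), "w") as fh:
                fh.write("\n".join(glist) + ("\n" if glist else ""))
        final = ann.venn_final(method_lists)
        finals[target] = final
        with open(os.path.join(outdir, "genes_final.txt"), "w") as fh:
            fh.write("\n".join(final) + ("\n" if final else ""))
        with open(os.path.join(outdir, "venn_counts.json"), "w") as fh:
            json.dump(ann.venn_counts(method_lists), fh, indent=2)
            fh.write("\n")
        manifest.row_counts[f"{target}_final_genes"] = len(final)
    if len(cfg.contrasts) == 2:
        shared = ann.shared_genes(finals[cfg.contrasts[0]], finals[cfg.contrasts[1]])
        with open(cfg.path("genes", "shared_genes.txt"), "w") as fh:
            fh.write("\n".join(shared) + ("\n" if shared else ""))
        manifest.row_counts["shared_genes"] = len(shared)


def stage_enrich(cfg: RunConfig, manifest: RunManifest) -> None:
    genes = ann.read_gff3(_require(cfg.gff3_path, "simulate"))
    sets = enr.read_gmt(_require(cfg.gmt_path, "simulate"))
    collection = enr.GeneSetCollection.from_gmt(sets, genes["gene_id"])
    for target in cfg.contrasts:
        final_path = _require(cfg.path("genes", target, "genes_final.txt"), "annotate")
        with open(final_path) as fh:
            candidates = [l.strip() for l in fh if l.strip()]
        outdir = cfg.path("enrichment")
        os.makedirs(outdir, exist_ok=True)
        out_path = os.path.join(outdir, f"enrichment_{target}.tsv")
        if not candidates:
            logger.warning("enrich: empty candidate list for %s", target)
            pd.DataFrame(columns=enr.ENRICH_COLUMNS).to_csv(
                out_path, sep="\t", index=False
            )
            manifest.row_counts[f"{target}_enriched_sets"] = 0
            continue
        table = enr.enrich_all(candidates, collection, alpha=cfg.alpha)
        table.to_csv(out_path, sep="\t", index=False)
        manifest.row_counts[f"{target}_enriched_sets"] = int(table["significant"].sum())


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "structure": stage_structure,
    "scan": stage_scan,
    "annotate": stage_annotate,
    "enrich": stage_enrich,
}


def run_stage(name: str, cfg: RunConfig, manifest: RunManifest) -> None:
    t0 = time.perf_counter()
    try:
        STAGES[name](cfg, manifest)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s done in %.1fs", name, manifest.stage_seconds[name])


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run every stage in order and write ``manifest.json`` in the run dir."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        ver = _pkg_version("sweepscan")
    except Exception:
        ver = "unknown"
    manifest = RunManifest(config_hash=cfg.config_hash(), software_version=ver)
    for name in STAGES:
        run_stage(name, cfg, manifest)
    manifest.write(cfg.path("manifest.json"))
    return manifest
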