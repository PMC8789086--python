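"""End-to-end pipeline: one config drives QC, filtering and every analysis.

The config carries every threshold with the pipeline's standard defaults
(individual missingness 0.10, SNP missingness 0.05, rare-MAF 0.01, LD
r^2 0.2 in 50 kb windows stepping 10 kb, PI_HAT 0.375, focal-ancestry
minimum 0.99, IBD minimum 2 cM at LOD 3 with 0.6 cM gap merging, 5 cM
pair-average inclusion, period cuts at 8.4 and 28 cM, 28 years per
generation, the 50-SNP ROH window block, |Z| > 4 for f4 affinity
counting, worst |Z| < 3 for graph fits, and at least 5 samples for
founder-event dating) plus a master seed from which every stochastic
stage derives its own stream.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .amova import amova
from .demography import allele_sharing_decay, fit_founder_event, fit_ne_history
from .fstats import allele_frequencies, f_statistic, outgroup_f3_matrix
from .ibd import detect_ibd, merge_gaps, sharing_network
from .io import attach_metadata, read_metadata, read_panel
from .panel import GenotypePanel
from .qc import ld_prune, qc_filter
from .relatedness import max_unrelated_set, pairwise_pi_hat
from .roh import call_roh, covered_span, froh
from .structure import classical_mds, pca, supervised_ancestry

logger = logging.getLogger("popgenkit.pipeline")

STAGES = [
    "qc", "relate", "ancestry", "fstats", "ordinate",
    "ibd", "roh", "network", "founder", "ne", "amova",
]

# stages that cannot run when an upstream stage is toggled off
_DEPENDS = {
    "relate": ["qc"],
    "ancestry": ["qc"],
    "network": ["ibd"],
    "ne": ["ibd"],
}


@dataclass
class PipelineConfig:
    input_path: str = ""
    input_format: str = "vcf"
    metadata_path: str = ""
    output_dir: str = "popgenkit_out"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # QC
    ind_missing_max: float = 0.10
    snp_missing_max: float = 0.05
    maf_rare_threshold: float = 0.01
    ld_r2_max: float = 0.2
    ld_window_bp: int = 50_000
    ld_step_bp: int = 10_000
    # relatedness / ancestry filters
    pi_hat_threshold: float = 0.375
    ancestry_min_focal: float = 0.99
    focal_component: str = ""
    reference_populations: list[str] = field(default_factory=list)
    # IBD
    ibd_min_cm: float = 2.0
    ibd_min_support: float = 3.0
    ibd_max_gap_cm: float = 0.6
    ibd_pair_avg_min_cm: float = 5.0
    period_cut_precolumbian_cm: float = 8.4
    period_cut_colonial_cm: float = 28.0
    years_per_generation: float = 28.0
    # f-statistics
    outgroup: str = ""
    jackknife_block_cm: float = 5.0
    f4_z_threshold: float = 4.0
    graph_worst_z_good: float = 3.0
    # ROH (the standard 50-SNP window block)
    roh_window_snps: int = 50
    roh_max_het_per_window: int = 1
    roh_max_miss_per_window: int = 5
    roh_min_overlap_frac: float = 0.05
    roh_min_snp_density_kb: float = 50.0
    roh_max_gap_kb: float = 100.0
    roh_min_length_kb: float = 500.0
    # demography
    founder_min_samples: int = 5
    founder_outgroup_n: int = 15
    ne_horizon_generations: int = 100
    bootstrap_n: int = 100
    # AMOVA
    amova_n_perm: int = 999
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.random.SeedSequence([self.master_seed, STAGES.index(stage)])
        return int(h.generate_state(1)[0] % (2**31))

    # -- round trip ------------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def apply_overrides(self, overrides: list[str]) -> None:
        for item in overrides:
            key, _, value = item.partition("=")
            if not hasattr(self, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(self, key)
            if isinstance(current, bool):
                setattr(self, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(self, key, int(value))
            elif isinstance(current, float):
                setattr(self, key, float(value))
            else:
                setattr(self, key, value)


def run_pipeline(
    config: PipelineConfig, panel: GenotypePanel | None = None
) -> dict:
    """Run the enabled stages in dependency order; returns the manifest.

    ``panel`` may be passed directly (e.g. from the simulator); otherwise
    it is read from ``config.input_path``. Stage outputs are written as
    delimited tables under ``config.output_dir``.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    if panel is None:
        if not config.input_path:
            raise ValueError("no input panel: set input_path or pass panel=")
        panel = read_panel(config.input_path, config.input_format)
        if config.metadata_path:
            panel = attach_metadata(panel, read_metadata(config.metadata_path))
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stages": {},
        "input": {"n_samples": panel.n_samples, "n_snps": panel.n_snps},
    }

    enabled = dict(config.stages)
    for stage, deps in _DEPENDS.items():
        if enabled.get(stage) and not all(enabled.get(d) for d in deps):
            logger.warning("stage %s skipped: upstream %s disabled", stage, deps)
            enabled[stage] = False

    def out(name: str) -> str:
        return os.path.join(config.output_dir, name)

    pruned = panel
    if enabled.get("qc"):
        panel, report = qc_filter(
            panel,
            snp_missing_max=config.snp_missing_max,
            ind_missing_max=config.ind_missing_max,
            maf_rare_threshold=config.maf_rare_threshold,
        )
        pruned = ld_prune(
            panel, config.ld_r2_max, config.ld_window_bp, config.ld_step_bp
        )
        manifest["stages"]["qc"] = report.as_dict() | {
            "n_snps_pruned": pruned.n_snps
        }

    unrelated_ids = panel.sample_ids
    if enabled.get("relate"):
        kin = pairwise_pi_hat(pruned, warn_unpruned=False)
        kin.table.to_csv(out("kinship.tsv"), sep="\t", index=False)
        unrelated_ids, mode = max_unrelated_set(kin, config.pi_hat_threshold)
        manifest["stages"]["relate"] = {
            "n_unrelated": len(unrelated_ids),
            "mode": mode,
        }

    if enabled.get("ancestry") and config.reference_populations:
        ref_freqs = allele_frequencies(
            pruned.select_samples(
                [
                    s
                    for s, p in zip(
                        pruned.sample_table["id"], pruned.sample_table["population"]
                    )
                    if p in config.reference_populations
                ]
            )
        )
        props = supervised_ancestry(pruned, ref_freqs)
        props.to_frame().to_csv(out("ancestry.tsv"), sep="\t", index=False)
        n_admixed = 0
        if config.focal_component:
            flags = props.admixed_flags(
                config.focal_component, 1.0 - config.ancestry_min_focal
            )
            n_admixed = int(flags.sum())
        manifest["stages"]["ancestry"] = {"n_admixed": n_admixed}

    freqs = None
    if enabled.get("fstats") and config.outgroup:
        freqs = allele_frequencies(panel)
        dist = outgroup_f3_matrix(
            freqs, config.outgroup, block_size_cm=config.jackknife_block_cm
        )
        dist.to_frame().to_csv(out("outgroup_f3_distance.tsv"), sep="\t")
        manifest["stages"]["fstats"] = {"n_populations": len(dist.labels)}

    if enabled.get("ordinate"):
        ords = pca(pruned, n_components=4)
        np.savetxt(out("pca.tsv"), ords.coords, delimiter="\t")
        if freqs is not None and config.outgroup:
            dist = outgroup_f3_matrix(freqs, config.outgroup)
            mds = classical_mds(dist, k=min(2, len(dist.labels) - 1))
            np.savetxt(out("mds.tsv"), mds.coords, delimiter="\t")
        manifest["stages"]["ordinate"] = {"n_components": ords.coords.shape[1]}

    segments = None
    if enabled.get("ibd") and panel.phased:
        segments = merge_gaps(
            detect_ibd(
                panel,
                min_cm=config.ibd_min_cm,
                min_support=config.ibd_min_support,
            ),
            panel,
            max_gap_cm=config.ibd_max_gap_cm,
        )
        segments.table.to_csv(out("ibd_segments.tsv"), sep="\t", index=False)
        manifest["stages"]["ibd"] = {"n_segments": segments.n_segments}

    if enabled.get("roh"):
        rohs = call_roh(
            panel,
            window_snps=config.roh_window_snps,
            max_het_per_window=config.roh_max_het_per_window,
            max_miss_per_window=config.roh_max_miss_per_window,
            min_overlap_frac=config.roh_min_overlap_frac,
            min_snp_density_kb=config.roh_min_snp_density_kb,
            max_gap_kb=config.roh_max_gap_kb,
            min_length_kb=config.roh_min_length_kb,
        )
        rohs.table.to_csv(out("roh.tsv"), sep="\t", index=False)
        ftab = froh(rohs, covered_span(panel), panel)
        ftab.per_sample.to_csv(out("froh.tsv"), sep="\t", index=False)
        manifest["stages"]["roh"] = {"n_roh": len(rohs.table)}

    if enabled.get("network") and segments is not None:
        grouping = dict(
            zip(panel.sample_table["id"], panel.sample_table["population"])
        )
        net = sharing_network(
            segments,
            grouping,
            min_avg_cm=config.ibd_pair_avg_min_cm,
            min_len_cm=config.ibd_min_cm,
        )
        net.edges.to_csv(out("sharing_network.tsv"), sep="\t", index=False)
        manifest["stages"]["network"] = {"n_edges": len(net.edges)}

    if enabled.get("founder"):
        rng = np.random.default_rng(config.stage_seed("founder"))
        events = {}
        all_ids = panel.sample_ids
        for pop, sub in panel.sample_table.groupby("population"):
            if len(sub) < config.founder_min_samples:
                continue
            outg = [s for s in all_ids if s not in set(sub["id"])]
            if len(outg) > config.founder_outgroup_n:
                outg = list(
                    rng.choice(outg, size=config.founder_outgroup_n, replace=False)
                )
            if len(outg) < 2:
                continue
            curve = allele_sharing_decay(panel, pop, outg)
            ev = fit_founder_event(
                curve,
                bootstrap_n=config.bootstrap_n,
                seed=config.stage_seed("founder"),
            )
            events[pop] = {
                "fa_gen": ev.founder_age_gen,
                "fi_pct": ev.founder_intensity_pct,
                "fa_ci": list(ev.fa_ci),
            }
        with open(out("founder_events.json"), "w") as fh:
            json.dump(events, fh, indent=2)
        manifest["stages"]["founder"] = {"n_populations": len(events)}

    if enabled.get("ne") and segments is not None:
        genome_morgans = (
            sum(
                sub["cm"].max() - sub["cm"].min()
                for _, sub in panel.snp_table.groupby("chrom")
            )
            / 100.0
        )
        n_hap = 2 * panel.n_samples
        traj = fit_ne_history(
            segments,
            n_pairs=n_hap * (n_hap - 1) // 2,
            genome_morgans=genome_morgans,
            horizon_generations=config.ne_horizon_generations,
            bootstrap_n=config.bootstrap_n,
            seed=config.stage_seed("ne"),
        )
        np.savetxt(out("ne_trajectory.tsv"), traj.ne, delimiter="\t")
        manifest["stages"]["ne"] = {"horizon": len(traj.ne)}

    if enabled.get("amova") and panel.sample_table["major_group"].nunique() > 1:
        res = amova(
            panel, n_perm=config.amova_n_perm, seed=config.stage_seed("amova")
        )
        res.to_frame().to_csv(out("amova.tsv"), sep="\t", index=False)
        manifest["stages"]["amova"] = {
            "percent": res.percent_variation,
            "p_values": res.p_values,
        }

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
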