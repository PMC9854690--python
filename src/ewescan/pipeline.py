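"""End-to-end orchestration: simulate/load -> QC -> phenotype adjustment ->
groups -> PCA -> ROH scan -> FST scan -> candidate-gene annotation.

Every stage parameter defaults to the scan's canonical value (MAF 0.05,
HWE p 1e-6, call rate 0.90; ROH windowSize 15, threshold 0.05, minSNP 20,
maxOppWindow 1, maxMissWindow 1; consensus frequency 0.75 with >= 3 SNPs;
flank 50 kb; top fraction 0.20; k = 2 clusters).  Result tables are
stamped with the config hash and seed; deterministic stages re-run
bit-identically under the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import fst as fst_mod
from . import io as eio
from . import pca as pca_mod
from . import phenotypes as ph
from . import qc as qc_mod
from . import roh as roh_mod
from .roh import RohParams
from .simulate import SimulationConfig, simulate_gene_annotation, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (left None when simulating)
    ped_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "auto"
    outdir: str = "ewescan_out"
    seed: int = 0
    # stage parameters (canonical defaults)
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    hwe_exclude_above: bool = False
    call_rate_min: float = 0.90
    k: int = 2
    linkage: str = "complete"
    alpha: float = 0.05
    n_components: int = 10
    pca_scale: str = "unit"
    roh: RohParams = field(default_factory=RohParams)
    min_freq: float = 0.75
    min_snps: int = 3
    top_fraction: float = 0.20
    fst_stat: str = "theta"
    flank: int = 50_000
    merge_regions: bool = True
    min_overlap_bp: int = 1
    make_plots: bool = True
    # simulation (used by the simulate stage)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    def config_hash(self) -> str:
        """Hash of everything that shapes the results (output location
        excluded, so a rerun elsewhere stamps identically)."""
        blob = dataclasses.asdict(self)
        blob.pop("outdir", None)
        blob.pop("make_plots", None)
        return hashlib.sha1(json.dumps(blob, sort_keys=True,
                                       default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        roh_raw = raw.pop("roh", None)
        sim_raw = raw.pop("simulate", None)
        cfg = cls(**raw)
        if roh_raw:
            cfg.roh = RohParams(**roh_raw)
        if sim_raw:
            sim_raw = dict(sim_raw)
            for key in ("planted_roh", "planted_diff_snps"):
                if key in sim_raw:
                    sim_raw[key] = [tuple(x) for x in sim_raw[key]]
            cfg.simulate = SimulationConfig(**sim_raw)
        return cfg


@dataclass
class PipelineResult:
    qc_report: qc_mod.QcReport
    fit: ph.GlmFit
    groups: ph.GroupAssignment
    pca: pca_mod.PcaResult
    runs: list
    haplotypes: list
    fst: fst_mod.FstResult
    fst_candidates: pd.DataFrame
    regions: list
    candidate_genes: pd.DataFrame
    summary: pd.DataFrame


def run_simulate(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate and write the synthetic inputs under ``outdir``."""
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    matrix, marker_map, phenotypes, truth = simulate_population(sim)
    regions = [(chrom, s, e) for _, chrom, s, e in truth.planted_roh_regions]
    snp_pos = marker_map.set_index("snp")
    for snp in truth.planted_diff_snp_ids:
        row = snp_pos.loc[snp]
        regions.append((str(row["chrom"]), int(row["bp"]), int(row["bp"])))
    genes = simulate_gene_annotation(marker_map, n_genes=60, seed=config.seed + 1,
                                     cover_regions=regions)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "phenotypes": outdir / "phenotypes.tsv",
        "genes": outdir / "genes.gff3",
    }
    eio.write_ped_map(matrix, marker_map, paths["ped"], paths["map"])
    eio.write_tsv(phenotypes, paths["phenotypes"], seed=config.seed)
    eio.write_gff3(genes, paths["genes"], seed=config.seed)
    for name, frame in truth.to_frames().items():
        p = outdir / f"truth_{name}.tsv"
        eio.write_tsv(frame, p, seed=config.seed)
        paths[f"truth_{name}"] = p
    logger.info("simulated %d ewes x %d markers -> %s",
                matrix.n_individuals, matrix.n_markers, outdir)
    return paths


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the result bundle to config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.ped_path is None:
        paths = run_simulate(config, outdir / "inputs")
        ped, mapf = paths["ped"], paths["map"]
        pheno_path, annot_path = paths["phenotypes"], paths["genes"]
        annot_fmt = "gff3"
    else:
        for p, what in ((config.ped_path, "PED"), (config.map_path, "MAP"),
                        (config.phenotype_path, "phenotype"),
                        (config.annotation_path, "annotation")):
            if p is None or not os.path.exists(p):
                raise FileNotFoundError(f"{what} file not found: {p}")
        ped, mapf = config.ped_path, config.map_path
        pheno_path, annot_path = config.phenotype_path, config.annotation_path
        annot_fmt = config.annotation_format

    stamp = dict(seed=config.seed, extra=f"config={config.config_hash()}")

    matrix, marker_map = eio.read_ped_map(ped, mapf)
    phenotypes = eio.read_tsv(pheno_path)
    genes = eio.read_gene_annotation(annot_path, annot_fmt)

    # QC
    matrix_qc, report = qc_mod.apply_qc(
        matrix, maf_min=config.maf_min, hwe_p_min=config.hwe_p_min,
        call_rate_min=config.call_rate_min,
        hwe_exclude_above=config.hwe_exclude_above)
    map_qc = marker_map[marker_map["snp"].isin(report.surviving_ids)].reset_index(drop=True)
    eio.write_tsv(report.per_marker, outdir / "qc_report.tsv", **stamp)

    # phenotype adjustment + groups
    per_ewe = ph.aggregate_per_ewe(phenotypes)
    screening = ph.screen_covariates(per_ewe, alpha=config.alpha)
    logger.info("Wald screening retained covariates: %s", screening.retained)
    fit = ph.fit_final_model(per_ewe)
    adjusted = fit.fitted
    eio.write_tsv(
        pd.DataFrame({"ewe_id": adjusted.index, "adjusted": adjusted.to_numpy(),
                      "observed": per_ewe.set_index("ewe_id").loc[adjusted.index,
                                                                  "fecundity"].to_numpy()}),
        outdir / "adjusted_phenotypes.tsv", **stamp)
    groups = ph.assign_groups(adjusted, k=config.k, linkage=config.linkage)
    eio.write_tsv(pd.DataFrame({"ewe_id": groups.labels.index,
                                "group": groups.labels.to_numpy()}),
                  outdir / "groups.tsv", **stamp)
    (outdir / "dendrogram.nwk").write_text(
        ph.dendrogram_newick(groups, list(adjusted.index)) + "\n")

    # PCA
    pca = pca_mod.run_pca(matrix_qc, n_components=min(config.n_components,
                                                      matrix_qc.n_individuals - 1),
                          scale=config.pca_scale)
    overlay = pca_mod.group_overlay(pca, groups.labels)
    eio.write_tsv(overlay.reset_index(names="ewe_id"), outdir / "pca_scores.tsv", **stamp)

    # ROH scan
    runs = roh_mod.detect_runs(matrix_qc, map_qc, config.roh)
    eio.write_tsv(roh_mod.runs_to_frame(runs), outdir / "roh_runs.tsv", **stamp)
    freqs = roh_mod.snp_run_frequency(runs, groups.labels, map_qc)
    eio.write_tsv(freqs, outdir / "roh_snp_frequency.tsv", **stamp)
    haplotypes = roh_mod.call_candidate_haplotypes(freqs, map_qc,
                                                   min_freq=config.min_freq,
                                                   min_snps=config.min_snps)
    eio.write_tsv(roh_mod.haplotypes_to_frame(haplotypes),
                  outdir / "roh_candidate_haplotypes.tsv", **stamp)

    # FST scan
    fst = fst_mod.fst_scan(matrix_qc, map_qc, groups.labels)
    eio.write_tsv(fst.table, outdir / "fst_per_snp.tsv", **stamp)
    fst_cand = fst_mod.select_candidates(fst, fraction=config.top_fraction,
                                         stat=config.fst_stat)
    eio.write_tsv(fst_cand, outdir / "fst_candidates.tsv", **stamp)

    # annotation
    regions = ann.build_regions(fst_candidates=fst_cand, roh_candidates=haplotypes,
                                flank=config.flank, merge=config.merge_regions)
    eio.write_bed([(r.chrom, r.start, r.end, f"{r.method}_{r.group}")
                   for r in regions], outdir / "candidate_regions.bed",
                  seed=config.seed)
    gene_table = ann.intersect_genes(regions, genes,
                                     min_overlap_bp=config.min_overlap_bp)
    eio.write_tsv(gene_table, outdir / "candidate_genes.tsv", **stamp)
    summary = ann.summarize_counts(gene_table)
    eio.write_tsv(summary, outdir / "candidate_gene_counts.tsv", **stamp)

    if config.make_plots:
        try:
            pca_mod.plot_scores(overlay, pca.explained_variance,
                                str(outdir / "pca.png"))
            _manhattan(freqs, config.min_freq, str(outdir / "roh_manhattan.png"))
        except Exception:  # plotting must never sink the scan
            logger.exception("plotting failed; results tables are complete")

    logger.info("pipeline complete: %d/%d markers post-QC, %d runs, "
                "%d consensus haplotypes, %d FST candidates, %d candidate genes",
                matrix_qc.n_markers, matrix.n_markers, len(runs), len(haplotypes),
                len(fst_cand), len(gene_table))
    return PipelineResult(qc_report=report, fit=fit, groups=groups, pca=pca,
                          runs=runs, haplotypes=haplotypes, fst=fst,
                          fst_candidates=fst_cand, regions=regions,
                          candidate_genes=gene_table, summary=summary)


def _manhattan(freqs: pd.DataFrame, cutoff: float, path: str) -> None:
    """Manhattan-style plot of per-SNP in-ROH frequency per group with the
    consensus cutoff line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    chroms = freqs["chrom"].unique()
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += freqs.loc[freqs["chrom"] == c, "bp"].max()
    x = freqs["bp"].to_numpy() + np.array([offsets[c] for c in freqs["chrom"]])
    for ax, group in zip(axes, ("high", "low")):
        colors = [("tab:blue" if i % 2 == 0 else "tab:cyan")
                  for i, c in enumerate(chroms)
                  for _ in range((freqs["chrom"] == c).sum())]
        ax.scatter(x, freqs[f"freq_{group}"], s=4, c=colors)
        ax.axhline(cutoff, color="gold", linestyle="--")
        ax.set_ylabel(f"{group} in-ROH freq")
        ax.set_ylim(0, 1.05)
    axes[1].set_xlabel("genome position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
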