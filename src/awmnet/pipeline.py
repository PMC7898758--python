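"""End-to-end orchestration with a declarative YAML configuration.

Stages run in dependency order — simulate -> phenotypes -> gwas -> awm ->
rif -> pcit -> regseq -> report — handing flat files between stages so each
stage is independently re-runnable.  All thresholds default to the study's
stated values; all randomness flows from one master seed.  A JSON manifest
records the seed, configuration, input checksums and per-stage sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import awm as awm_mod
from . import gwas as gwas_mod
from . import phenotypes as phen_mod
from . import regseq as regseq_mod
from . import rif as rif_mod
from . import simulate as sim_mod
from .pcit_network import (
    extract_regulator_subnetwork,
    network_stats,
    pcit as run_pcit,
    row_correlations,
    write_edge_list,
    write_graphml,
    write_sif,
)
from .errors import ConfigError, DataError
from .panel import GenotypePanel, read_vcf

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotypes", "gwas", "awm", "rif", "pcit", "regseq")


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and file paths in one place.

    Threshold defaults are the study's: 10,000-read sample filter, ASV
    filter (3 samples / 0.005%), 10,000-read rarefaction, >60% genus
    prevalence, MAF >= 5%, missingness <= 10%, p < 0.05 association
    threshold, 5-kb gene window, |z| >= 1.96 RIF cut, |r| > 0.7 subnetwork
    cut, 1e-4 motif p-value.
    """

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # synthetic-data stage (scaled-down end-to-end default)
    sim: dict = field(default_factory=lambda: {
        "n_individuals": 200, "n_snps": 4000, "n_bacteria": 16,
        "n_protists": 4, "ld_block_size": 8,
    })
    # external inputs (used when the simulate stage is disabled)
    inputs: dict = field(default_factory=dict)
    # thresholds
    min_reads: int = 10000
    min_samples: int = 3
    min_total_frac: float = 0.00005
    rarefaction_depth: int = 10000
    min_prevalence: float = 0.60
    pseudocount: float = 1.0
    min_maf: float = 0.05
    max_missing: float = 0.10
    alpha: float = 0.05
    window: int = 5000
    z_cut: float = 1.96
    min_abs_r: float = 0.7
    p_threshold: float = 1e-4
    mirna_mature: str = "AAGUGCCGCCAUCUUUUGAGUGU"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig, outdir: str) -> dict:
    """Execute the enabled stages; returns (and writes) the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bad = [s for s in config.stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    enabled = [s for s in STAGES if s in config.stages]
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ---------------------------------------------------------------- inputs
    if "simulate" not in enabled:
        required = ["vcf", "counts", "taxonomy", "covariates", "gff3"]
        if "regseq" in enabled:
            required += ["promoters", "utrs"]
        missing = [k for k in required if k not in config.inputs
                   or not Path(config.inputs[k]).exists()]
        if missing:
            raise ConfigError(f"missing input file(s) for {missing}")
        for key, path in config.inputs.items():
            if Path(path).exists():
                manifest["inputs"][key] = _md5(Path(path))

    panel = counts = covariates = annotation = truth = None
    promoters = utrs = None
    pfms: list[regseq_mod.Pfm] = []

    # -------------------------------------------------------------- simulate
    if "simulate" in enabled:
        stage_dir = out / "sim"
        stage_dir.mkdir(exist_ok=True)
        cfg = sim_mod.SimConfig(seed=config.seed, **config.sim)
        panel = sim_mod.gen_genotypes(cfg)
        annotation = sim_mod.gen_gene_annotation(panel, seed=config.seed)
        counts, covariates, truth = sim_mod.gen_microbiome(panel, cfg)
        pfms = [_demo_pfm()]
        promoters, utrs, truth = sim_mod.gen_sequences(
            annotation, pfms, regseq_mod.SeedSpec(config.mirna_mature).site,
            truth=truth, seed=config.seed,
        )
        panel.to_vcf(str(stage_dir / "genotypes.vcf"))
        sim_mod.write_gff3(annotation, str(stage_dir / "annotation.gff3"))
        counts.to_tsv(str(stage_dir / "counts.tsv"), str(stage_dir / "taxonomy.tsv"))
        covariates.to_csv(stage_dir / "covariates.tsv", sep="\t",
                          index_label="sample")
        sim_mod.write_fasta(promoters, str(stage_dir / "promoters.fa"))
        sim_mod.write_fasta(utrs, str(stage_dir / "utrs.fa"))
        truth.to_json(str(stage_dir / "truth.json"))
        manifest["stages"]["simulate"] = {
            "n_individuals": panel.n_individuals, "n_snps": panel.n_snps,
            "n_asvs": counts.counts.shape[1],
        }
    else:
        panel = read_vcf(config.inputs["vcf"])
        counts = phen_mod.CountTable.from_tsv(config.inputs["counts"],
                                              config.inputs["taxonomy"])
        covariates = pd.read_csv(config.inputs["covariates"], sep="\t", index_col=0)
        annotation = sim_mod.read_gff3(config.inputs["gff3"])
        if "promoters" in config.inputs:
            promoters = sim_mod.read_fasta(config.inputs["promoters"])
        if "utrs" in config.inputs:
            utrs = sim_mod.read_fasta(config.inputs["utrs"])
        if "pfms" in config.inputs:
            pfms = regseq_mod.read_jaspar_pfms(config.inputs["pfms"])

    # ------------------------------------------------------------ phenotypes
    phen = None
    if "phenotypes" in enabled:
        stage_dir = out / "phen"
        stage_dir.mkdir(exist_ok=True)
        phen = phen_mod.build_phenotypes(
            counts, covariates,
            min_reads=config.min_reads, min_samples=config.min_samples,
            min_total_frac=config.min_total_frac,
            rarefaction_depth=config.rarefaction_depth,
            min_prevalence=config.min_prevalence,
            pseudocount=config.pseudocount, seed=config.seed,
        )
        phen.to_tsv(str(stage_dir / "phenotypes.tsv"))
        phen.meta.to_csv(stage_dir / "phenotype_meta.tsv", sep="\t", index=False)
        phen.covariates.to_csv(stage_dir / "covariates.tsv", sep="\t",
                               index_label="sample")
        manifest["stages"]["phenotypes"] = {
            "n_samples": len(phen.values), "n_phenotypes": phen.values.shape[1],
        }

    # ------------------------------------------------------------------ gwas
    results = None
    if "gwas" in enabled:
        stage_dir = out / "gwas"
        stage_dir.mkdir(exist_ok=True)
        keep = [s in set(phen.values.index) for s in panel.samples]
        if not all(keep):
            panel = GenotypePanel(
                panel.dosages[np.array(keep)], panel.snp_map,
                [s for s, k in zip(panel.samples, keep) if k],
            )
        filtered = gwas_mod.filter_snps(panel, config.min_maf, config.max_missing)
        results = gwas_mod.run_gwas(
            filtered, phen.values.loc[panel.samples],
            phen.covariates.loc[panel.samples, ["sex", "batch"]],
            phenotype_meta=phen.meta,
        )
        per_dir = stage_dir / "per_phenotype"
        per_dir.mkdir(exist_ok=True)
        for name in results.phenotypes:
            df = pd.DataFrame({
                "snp_id": results.effects.index,
                "chrom": results.snp_map["chrom"].to_numpy(),
                "bp": results.snp_map["bp"].to_numpy(),
                "effect": results.effects[name].to_numpy(),
                "se": results.se[name].to_numpy(),
                "p": results.pvalues[name].to_numpy(),
                "z": results.zscores[name].to_numpy(),
            })
            df.to_csv(per_dir / f"{name}.tsv", sep="\t", index=False)
        gwas_mod.fdr_summary(results).to_csv(stage_dir / "summary_fdr.tsv",
                                             sep="\t", index=False)
        results.varcomps.to_csv(stage_dir / "varcomps.tsv", sep="\t", index=False)
        manifest["stages"]["gwas"] = {
            "n_snps_tested": len(results.snp_map),
            "n_phenotypes": len(results.phenotypes),
        }

    # ------------------------------------------------------------------- awm
    matrix = anchors = assignments = None
    if "awm" in enabled:
        stage_dir = out / "awm"
        stage_dir.mkdir(exist_ok=True)
        assignments = awm_mod.map_snp_to_gene(results.snp_map, annotation,
                                              config.window)
        anchors = awm_mod.anchor_genes(assignments, results, alpha=config.alpha)
        matrix = awm_mod.select_rows(results, assignments, alpha=config.alpha)
        manifest["stages"]["awm"] = {
            "n_rows_provisional": len(matrix), "n_a": matrix.n_a,
        }

    # ------------------------------------------------------------------- rif
    rif = hits = None
    if "rif" in enabled:
        stage_dir = out / "rif"
        stage_dir.mkdir(exist_ok=True)
        gene_types = annotation.set_index("gene_id")["gene_type"]
        reg_genes = anchors.loc[
            anchors["gene_id"].map(gene_types).isin(["TF", "miRNA"])
        ]
        if reg_genes.empty:
            raise DataError("no TF/miRNA-annotated SNP-gene available for RIF")
        reg_entries = results.zscores.loc[reg_genes["snp_id"]].set_index(
            reg_genes["gene_id"]
        )
        group1 = [c for c in matrix.entries.columns
                  if c in set(phen.meta.loc[phen.meta["group"] == "bacteria",
                                            "phenotype"])]
        group2 = [c for c in matrix.entries.columns
                  if c in set(phen.meta.loc[phen.meta["group"] == "protist",
                                            "phenotype"])]
        rif = rif_mod.rif_scores(matrix.entries, reg_entries, group1, group2)
        hits = rif_mod.select_significant(rif, config.z_cut)
        rif.scores.to_csv(stage_dir / "rif_scores.tsv", sep="\t")
        hits.to_csv(stage_dir / "significant_regulators.tsv", sep="\t", index=False)
        matrix = awm_mod.add_regulators(matrix, hits, results, anchors)
        matrix.to_tsv(str(out / "awm" / "awm.tsv"))
        corr, linkage, order = awm_mod.phenotype_correlation_cluster(matrix)
        corr.to_csv(out / "awm" / "phenotype_correlations.tsv", sep="\t")
        (out / "awm" / "phenotype_dendrogram.nwk").write_text(
            awm_mod.linkage_to_newick(linkage, list(corr.index)) + "\n"
        )
        (out / "awm" / "leaf_order.txt").write_text("\n".join(order) + "\n")
        manifest["stages"]["rif"] = {
            "n_regulators_scored": len(rif.scores),
            "n_significant": len(hits),
            "n_awm_rows_final": len(matrix),
        }

    # ------------------------------------------------------------------ pcit
    net = node_stats = None
    if "pcit" in enabled:
        stage_dir = out / "pcit"
        stage_dir.mkdir(exist_ok=True)
        corr_rows = row_correlations(matrix.entries)
        net = run_pcit(corr_rows)
        node_stats = network_stats(net, matrix.entries, matrix.rows)
        write_edge_list(net, str(stage_dir / "edges.tsv"))
        write_sif(net, str(stage_dir / "network.sif"))
        write_graphml(net, str(stage_dir / "network.graphml"))
        node_stats.to_csv(stage_dir / "nodes.tsv", sep="\t", index=False)
        if hits is not None and len(hits):
            sub = extract_regulator_subnetwork(
                net, [g for g in hits["gene_id"] if g in net.graph],
                config.min_abs_r,
            )
            import networkx as nx
            nx.write_graphml(sub, stage_dir / "regulator_subnetwork.graphml")
        pos, neg = net.edge_sign_counts()
        manifest["stages"]["pcit"] = {
            "n_nodes": len(net.nodes), "n_edges": net.n_edges,
            "n_positive": pos, "n_negative": neg,
        }

    # ---------------------------------------------------------------- regseq
    if "regseq" in enabled:
        stage_dir = out / "regseq"
        stage_dir.mkdir(exist_ok=True)
        if promoters is None or utrs is None:
            raise ConfigError("regseq stage needs promoter and UTR FASTA inputs")
        background = regseq_mod.estimate_background(promoters)
        all_hits = []
        for pfm in pfms:
            pwm = regseq_mod.pfm_to_pwm(pfm, background)
            all_hits.append(regseq_mod.scan(
                promoters, pwm, background, config.p_threshold,
                motif_id=pfm.motif_id,
            ))
        hits_df = (pd.concat(all_hits, ignore_index=True) if all_hits
                   else pd.DataFrame(columns=["gene", "motif", "offset",
                                              "strand", "score", "p"]))
        hits_df.to_csv(stage_dir / "motif_hits.tsv", sep="\t", index=False)
        summary = (
            hits_df.groupby("motif")["gene"].nunique().rename("genes_with_hit")
            .reset_index()
            if len(hits_df) else pd.DataFrame(columns=["motif", "genes_with_hit"])
        )
        if len(summary):
            summary["fraction"] = summary["genes_with_hit"] / len(promoters)
        summary.to_csv(stage_dir / "motif_summary.tsv", sep="\t", index=False)

        spec = regseq_mod.SeedSpec(config.mirna_mature)
        sites = regseq_mod.find_seed_sites(utrs, spec)
        sites.to_csv(stage_dir / "seed_sites.tsv", sep="\t", index=False)
        enr = regseq_mod.seed_background_enrichment(utrs, spec)
        pd.DataFrame([dataclasses.asdict(enr)]).to_csv(
            stage_dir / "seed_enrichment.tsv", sep="\t", index=False
        )
        manifest["stages"]["regseq"] = {
            "n_motif_hits": len(hits_df),
            "n_seed_sites": int(sites["n_sites"].sum()),
            "fold_enrichment": enr.fold if np.isfinite(enr.fold) else None,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


def _demo_pfm() -> "regseq_mod.Pfm":
    """Synthetic demonstration PFM with a strong 8-bp consensus (TGACTCAG)."""
    consensus = "TGACTCAG"
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 18.0
    return regseq_mod.Pfm("DEMO_TGACTCAG", counts, pseudocount=0.5)


def report(run_dir: str) -> dict[str, pd.DataFrame]:
    """Assemble the summary tables of a completed run.

    Returns the per-phenotype significant-SNP/FDR table, the regulator table
    (RIF scores, pleiotropy, connections), and the phenotype correlation
    matrix with its dendrogram leaf order.  Missing artifacts raise.
    """
    run = Path(run_dir)
    needed = {
        "fdr": run / "gwas" / "summary_fdr.tsv",
        "rif": run / "rif" / "rif_scores.tsv",
        "significant": run / "rif" / "significant_regulators.tsv",
        "nodes": run / "pcit" / "nodes.tsv",
        "corr": run / "awm" / "phenotype_correlations.tsv",
        "order": run / "awm" / "leaf_order.txt",
    }
    missing = [str(p) for p in needed.values() if not p.exists()]
    if missing:
        raise DataError(f"incomplete run; missing artifacts: {missing}")
    fdr_table = pd.read_csv(needed["fdr"], sep="\t")
    rif_scores = pd.read_csv(needed["rif"], sep="\t")
    significant = pd.read_csv(needed["significant"], sep="\t")
    nodes = pd.read_csv(needed["nodes"], sep="\t")
    regulators = significant.merge(nodes, on="gene_id", how="left")
    corr = pd.read_csv(needed["corr"], sep="\t", index_col=0)
    order = needed["order"].read_text().split()
    out_dir = run / "report"
    out_dir.mkdir(exist_ok=True)
    fdr_table.to_csv(out_dir / "per_phenotype_fdr.tsv", sep="\t", index=False)
    regulators.to_csv(out_dir / "regulator_table.tsv", sep="\t", index=False)
    corr.loc[order, order].to_csv(out_dir / "phenotype_correlations_ordered.tsv",
                                  sep="\t")
    return {"fdr": fdr_table, "regulators": regulators, "correlations": corr,
            "leaf_order": order}
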