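"""From GWAS results to the AWM, RIF regulators and the PCIT network.

Runs the complete post-GWAS chain at a small scale: anchor SNPs to genes
(5-kb window), select AWM rows (diversity-associated, then pleiotropy >
N_A), score TF/miRNA genes with RIF1/RIF2 on the bacteria-vs-protist
contrast, and infer the gene co-association network with PCIT.
"""

from awmnet import gwas
from awmnet.awm import add_regulators, anchor_genes, map_snp_to_gene, \
    phenotype_correlation_cluster, select_rows
from awmnet.pcit_network import network_stats, pcit, row_correlations
from awmnet.phenotypes import build_phenotypes
from awmnet.rif import rif_scores, select_significant
from awmnet.simulate import SimConfig, gen_gene_annotation, gen_genotypes, \
    gen_microbiome

cfg = SimConfig(n_individuals=150, n_snps=1200, n_bacteria=10, n_protists=4,
                ld_block_size=5, seed=12)
panel = gen_genotypes(cfg)
annotation = gen_gene_annotation(panel, seed=12)
counts, covariates, truth = gen_microbiome(panel, cfg)
phen = build_phenotypes(counts, covariates, seed=12)
filtered = gwas.filter_snps(panel)
results = gwas.run_gwas(filtered, phen.values, covariates[["sex", "batch"]])

assignments = map_snp_to_gene(results.snp_map, annotation)
anchors = anchor_genes(assignments, results)
awm = select_rows(results, assignments)
print(f"provisional AWM: {len(awm)} gene rows, N_A = {awm.n_a:.2f}")

gene_types = annotation.set_index("gene_id")["gene_type"]
regs = anchors.loc[anchors["gene_id"].map(gene_types).isin(["TF", "miRNA"])]
reg_entries = results.zscores.loc[regs["snp_id"]].set_index(regs["gene_id"])
g1 = [c for c in awm.entries.columns if c == "AlphaBACT" or c.startswith("B_")]
g2 = [c for c in awm.entries.columns if c == "AlphaPROTO" or c.startswith("P_")]
rif = rif_scores(awm.entries, reg_entries, g1, g2)
hits = select_significant(rif)
awm = add_regulators(awm, hits, results, anchors)
print(f"RIF scored {len(rif.scores)} TF/miRNA genes; "
      f"{len(hits)} significant at |z| >= 1.96")

net = pcit(row_correlations(awm.entries))
pos, neg = net.edge_sign_counts()
stats = network_stats(net, awm.entries, awm.rows)
hub = stats.sort_values("connections", ascending=False).iloc[0]
print(f"PCIT network: {len(net.nodes)} nodes, {net.n_edges} edges "
      f"({pos} positive / {neg} negative)")
print(f"most connected gene: {hub['gene_id']} with {hub['connections']} "
      f"first neighbors (strongest association: {hub['top_association']})")
corr, _, order = phenotype_correlation_cluster(awm)
print(f"phenotype dendrogram leaf order starts with: {order[:4]}")
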