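"""Association Weight Matrix construction.

The AWM is a genes x phenotypes matrix of standardized SNP allele-
substitution effects.  Each row is a gene carrying exactly one anchoring SNP
(inside the gene or within 5 kb of it); rows enter by one of three rules:

* rule A (diversity-associated): the anchoring SNP is associated (p < alpha)
  with a key phenotype — the bacterial or protist Shannon alpha diversity;
* rule B (pleiotropic): the SNP is associated with strictly more than N_A
  phenotypes, where N_A is the mean pleiotropy count of the rule-A SNPs;
* regulator: the gene is a TF/miRNA scored significant by the RIF analysis,
  appended even with zero significant associations.

Labelling precedence is A > B > regulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError
from .gwas import GwasResultSet

__all__ = [
    "map_snp_to_gene",
    "anchor_genes",
    "select_rows",
    "add_regulators",
    "phenotype_correlation_cluster",
    "AwmMatrix",
    "KEY_PHENOTYPES",
]

logger = logging.getLogger(__name__)

KEY_PHENOTYPES = ("AlphaBACT", "AlphaPROTO")


@dataclass
class AwmMatrix:
    """Selected gene rows x phenotype columns of standardized effects.

    ``rows`` carries per-gene metadata: anchoring SNP, distance to the gene,
    selection class, pleiotropy count.  ``n_a`` is the rule-B threshold.
    """

    entries: pd.DataFrame           # index gene_id, columns phenotypes
    rows: pd.DataFrame              # gene_id, snp_id, distance, cls, pleiotropy
    n_a: float
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str) -> None:
        out = self.rows.set_index("gene_id").join(self.entries)
        out.to_csv(path, sep="\t")


def map_snp_to_gene(
    snp_map: pd.DataFrame, annotation: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """Assign each SNP to its nearest gene within ``window`` bp.

    Distance is 0 inside the gene span, otherwise base pairs to the nearest
    gene end.  A SNP equidistant from two genes yields one assignment row per
    gene (both eligible).  Unassignable SNPs are absent from the result.
    Returns columns snp_id, bp, gene_id, distance.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in annotation.iterrows():
        tree = trees.setdefault(str(gene["chrom"]), IntervalTree())
        lo = max(int(gene["start"]) - window, 0)
        hi = int(gene["end"]) + window + 1
        tree.addi(lo, hi, idx)

    out = []
    for _, snp in snp_map.iterrows():
        tree = trees.get(str(snp["chrom"]))
        if tree is None:
            continue
        bp = int(snp["bp"])
        hits = tree[bp]
        if not hits:
            continue
        dists = []
        for interval in hits:
            gene = annotation.loc[interval.data]
            if gene["start"] <= bp <= gene["end"]:
                dist = 0
            elif bp < gene["start"]:
                dist = int(gene["start"]) - bp
            else:
                dist = bp - int(gene["end"])
            dists.append((dist, interval.data))
        best = min(d for d, _ in dists)
        for dist, gidx in dists:
            if dist == best:
                out.append(
                    {
                        "snp_id": snp["snp_id"],
                        "bp": bp,
                        "gene_id": annotation.at[gidx, "gene_id"],
                        "distance": dist,
                    }
                )
    return pd.DataFrame(out, columns=["snp_id", "bp", "gene_id", "distance"])


def anchor_genes(
    assignments: pd.DataFrame,
    results: GwasResultSet,
    key_phenotypes: tuple[str, str] = KEY_PHENOTYPES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Choose one anchoring SNP per gene.

    Selection: smallest key-phenotype p-value (minimum over the alpha-
    diversity columns); ties broken by higher pleiotropy count, then smaller
    bp.  Pleiotropy of a SNP = number of phenotypes with p < ``alpha``.
    Returns one row per gene: gene_id, snp_id, distance, key_p, pleiotropy.
    """
    pv = results.pvalues
    missing = [k for k in key_phenotypes if k not in pv.columns]
    if missing:
        raise DataError(f"key phenotypes absent from the GWAS results: {missing}")
    key_p = pv[list(key_phenotypes)].min(axis=1)
    pleio = (pv < alpha).sum(axis=1)

    df = assignments.merge(
        pd.DataFrame({"snp_id": pv.index, "key_p": key_p.to_numpy(),
                      "pleiotropy": pleio.to_numpy()}),
        on="snp_id",
        how="inner",
    )
    df = df.sort_values(
        ["gene_id", "key_p", "pleiotropy", "bp"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return df.groupby("gene_id", sort=True).head(1).reset_index(drop=True)


def select_rows(
    results: GwasResultSet,
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    key_phenotypes: tuple[str, str] = KEY_PHENOTYPES,
) -> AwmMatrix:
    """Provisional AWM from rules A (diversity) and B (pleiotropy > N_A)."""
    if results.zscores is None:
        raise DataError("standardize_effects must run before AWM selection")
    anchors = anchor_genes(assignments, results, key_phenotypes, alpha)
    rule_a = anchors["key_p"] < alpha
    if not rule_a.any():
        raise DataError("no SNP-gene is associated with a key phenotype (rule A)")
    n_a = float(anchors.loc[rule_a, "pleiotropy"].mean())
    rule_b = ~rule_a & (anchors["pleiotropy"] > n_a)

    selected = anchors.loc[rule_a | rule_b].copy()
    selected["cls"] = np.where(rule_a[rule_a | rule_b], "diversity", "pleiotropic")
    entries = results.zscores.loc[selected["snp_id"]].set_index(
        selected["gene_id"]
    )
    rows = selected[["gene_id", "snp_id", "distance", "cls", "pleiotropy"]].reset_index(
        drop=True
    )
    inside = (rows["distance"] == 0).mean() if len(rows) else float("nan")
    logger.info("AWM anchoring: %.2f%% of selected SNPs inside genes", 100 * inside)
    return AwmMatrix(entries=entries, rows=rows, n_a=n_a, alpha=alpha)


def add_regulators(
    awm: AwmMatrix,
    rif_hits: pd.DataFrame,
    results: GwasResultSet,
    anchors: pd.DataFrame,
) -> AwmMatrix:
    """Append RIF-significant regulator genes as rows of class ``regulator``.

    ``rif_hits`` needs a ``gene_id`` column (the output of
    :func:`awmnet.rif.select_significant`); regulators already selected by
    rule A/B keep their class and the row count is unchanged.  Regulators
    with zero significant phenotype associations still enter.
    """
    if rif_hits is None or len(rif_hits) == 0:
        return awm
    present = set(awm.rows["gene_id"])
    new = anchors.loc[
        anchors["gene_id"].isin(set(rif_hits["gene_id"]) - present)
    ].copy()
    if new.empty:
        return awm
    new["cls"] = "regulator"
    entries = pd.concat(
        [awm.entries, results.zscores.loc[new["snp_id"]].set_index(new["gene_id"])]
    )
    rows = pd.concat(
        [awm.rows, new[["gene_id", "snp_id", "distance", "cls", "pleiotropy"]]],
        ignore_index=True,
    )
    return AwmMatrix(entries=entries, rows=rows, n_a=awm.n_a, alpha=awm.alpha)


def phenotype_correlation_cluster(
    awm: AwmMatrix,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pearson correlations between phenotype columns + average-linkage tree.

    Returns (correlation matrix, scipy linkage matrix, leaf order).  The
    distance is 1 - r.
    """
    if len(awm) < 3:
        raise DataError("phenotype clustering needs at least 3 AWM rows")
    mat = awm.entries.to_numpy(dtype=float)
    sds = mat.std(axis=0)
    if (sds == 0).any():
        bad = awm.entries.columns[sds == 0][0]
        raise DataError(f"phenotype column {bad} is constant across AWM rows")
    corr = np.corrcoef(mat, rowvar=False)
    names = list(awm.entries.columns)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    linkage = hierarchy.average(dist)
    order = [names[i] for i in hierarchy.leaves_list(linkage)]
    return pd.DataFrame(corr, index=names, columns=names), linkage, order


def linkage_to_newick(linkage: np.ndarray, names: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, names)
    return str(tree)
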