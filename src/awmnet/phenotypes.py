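"""From amplicon count tables to the 39 analysis phenotypes.

The processing order is fixed: sample read-depth filter, ASV filter, then two
branches — a rarefied copy for the two Shannon alpha diversities (bacteria
and protists separately, natural log) and the unrarefied filtered table for
genus aggregation, prevalence filtering and the centred log-ratio (clr)
transform.  clr is computed within each kingdom block, so the bacterial and
protist columns each sum to zero per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import DataError

__all__ = [
    "CountTable",
    "PhenotypeTable",
    "filter_samples",
    "filter_asvs",
    "rarefy",
    "shannon",
    "aggregate_and_prevalence_filter",
    "clr_transform",
    "build_phenotypes",
]

KINGDOMS = ("bacteria", "protist")
DIVERSITY_NAMES = {"bacteria": "AlphaBACT", "protist": "AlphaPROTO"}
ABUNDANCE_PREFIX = {"bacteria": "B_", "protist": "P_"}


@dataclass
class CountTable:
    """Non-negative integer counts, samples x features, plus taxonomy.

    ``taxonomy`` maps feature ids to (genus, kingdom); kingdom must be one of
    ``bacteria`` / ``protist``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame   # index feature_id, columns genus, kingdom

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise DataError("sample and feature identifiers must be unique")
        values = self.counts.to_numpy()
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            raise DataError("counts must be non-negative integers")
        bad = self.taxonomy.loc[
            ~self.taxonomy["kingdom"].isin(KINGDOMS)
        ]
        if len(bad):
            raise DataError(f"unknown kingdom labels: {sorted(set(bad['kingdom']))}")

    def features_of_kingdom(self, kingdom: str) -> list[str]:
        known = self.taxonomy.index
        return [
            f
            for f in self.counts.columns
            if f in known and self.taxonomy.loc[f, "kingdom"] == kingdom
        ]

    @classmethod
    def from_tsv(cls, counts_path: str, taxonomy_path: str) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        return cls(counts, taxonomy)

    def to_tsv(self, counts_path: str, taxonomy_path: str | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample")
        if taxonomy_path:
            self.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="feature_id")


@dataclass
class PhenotypeTable:
    """Samples x phenotypes matrix with per-phenotype metadata and covariates.

    ``meta`` columns: ``phenotype``, ``group`` (bacteria/protist), ``kind``
    (diversity/abundance).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    covariates: pd.DataFrame | None = field(default=None)

    def columns_of_group(self, group: str) -> list[str]:
        sel = self.meta.loc[self.meta["group"] == group, "phenotype"]
        return [c for c in self.values.columns if c in set(sel)]

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def filter_samples(counts: CountTable, min_reads: int = 10000) -> CountTable:
    """Keep samples with total reads >= ``min_reads`` (order preserved)."""
    totals = counts.counts.sum(axis=1)
    kept = counts.counts.loc[totals >= min_reads]
    if kept.empty:
        raise DataError(f"no sample reaches {min_reads} reads")
    return CountTable(kept, counts.taxonomy)


def filter_asvs(
    counts: CountTable,
    min_samples: int = 3,
    min_total_frac: float = 0.00005,
) -> CountTable:
    """Discard features deficient on BOTH rules: present in fewer than
    ``min_samples`` samples AND totalling less than ``min_total_frac`` of all
    counts.  A feature failing only one rule is kept (the discard rule is a
    conjunction).
    """
    table = counts.counts
    prevalence = (table > 0).sum(axis=0)
    totals = table.sum(axis=0)
    grand = totals.sum()
    discard = (prevalence < min_samples) & (totals < min_total_frac * grand)
    return CountTable(table.loc[:, ~discard], counts.taxonomy)


def rarefy(counts: CountTable, depth: int = 10000, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads."""
    rng = np.random.default_rng(seed)
    mat = counts.counts.to_numpy(dtype=np.int64)
    out = np.empty_like(mat)
    for i, sample in enumerate(counts.counts.index):
        total = int(mat[i].sum())
        if total < depth:
            raise DataError(f"sample {sample} has {total} < {depth} reads")
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    rarefied = pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)
    return CountTable(rarefied, counts.taxonomy)


# --------------------------------------------------------------------------
# Diversity and transforms
# --------------------------------------------------------------------------

def shannon(abundances: np.ndarray) -> float:
    """Shannon index H = -sum p_i ln p_i over nonzero entries (natural log)."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise DataError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise DataError("cannot compute Shannon diversity of an all-zero vector")
    return float(entropy(x / total))


def aggregate_and_prevalence_filter(
    counts: CountTable, min_prevalence: float = 0.60
) -> CountTable:
    """Sum ASVs to genus level, then keep genera present (count > 0) in
    strictly more than ``min_prevalence`` of the samples.
    """
    unmapped = [f for f in counts.counts.columns if f not in counts.taxonomy.index]
    if unmapped:
        raise DataError(f"features missing from the taxonomy map: {unmapped[:5]}")
    tax = counts.taxonomy.loc[counts.counts.columns]
    genus_counts = counts.counts.T.groupby(tax["genus"], sort=False).sum().T
    genus_kingdom = tax.drop_duplicates("genus").set_index("genus")["kingdom"]
    prevalence = (genus_counts > 0).mean(axis=0)
    kept = genus_counts.loc[:, prevalence > min_prevalence]
    taxonomy = pd.DataFrame(
        {"genus": kept.columns, "kingdom": genus_kingdom.loc[kept.columns].to_numpy()},
        index=pd.Index(kept.columns, name="feature_id"),
    )
    return CountTable(kept, taxonomy)


def clr_transform(
    genus_counts: CountTable, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Centred log-ratio per sample, within each kingdom block.

    x_i = ln(c_i + pseudocount) - mean_j ln(c_j + pseudocount), the mean
    running over the genera of the same kingdom, so each kingdom block of a
    sample sums to zero.
    """
    blocks = []
    for kingdom in KINGDOMS:
        feats = genus_counts.features_of_kingdom(kingdom)
        if not feats:
            continue
        logs = np.log(genus_counts.counts[feats].to_numpy(dtype=float) + pseudocount)
        clr = logs - logs.mean(axis=1, keepdims=True)
        blocks.append(
            pd.DataFrame(
                clr,
                index=genus_counts.counts.index,
                columns=[ABUNDANCE_PREFIX[kingdom] + f for f in feats],
            )
        )
    if not blocks:
        raise DataError("no kingdom block present in the genus table")
    return pd.concat(blocks, axis=1)


# --------------------------------------------------------------------------
# Full phenotype pipeline
# --------------------------------------------------------------------------

def build_phenotypes(
    counts: CountTable,
    covariates: pd.DataFrame | None = None,
    min_reads: int = 10000,
    min_samples: int = 3,
    min_total_frac: float = 0.00005,
    rarefaction_depth: int = 10000,
    min_prevalence: float = 0.60,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> PhenotypeTable:
    """Run the fixed pipeline and return diversity + clr phenotypes.

    Diversity is computed per kingdom on the rarefied ASV table; clr genus
    abundances come from the unrarefied filtered table.  Covariate rows are
    aligned to the retained samples.
    """
    filtered = filter_asvs(
        filter_samples(counts, min_reads), min_samples, min_total_frac
    )
    rarefied = rarefy(filtered, rarefaction_depth, seed)

    div_cols = {}
    meta_rows = []
    for kingdom in KINGDOMS:
        feats = rarefied.features_of_kingdom(kingdom)
        if not feats:
            continue
        name = DIVERSITY_NAMES[kingdom]
        div_cols[name] = rarefied.counts[feats].apply(
            lambda row: shannon(row.to_numpy()), axis=1
        )
        meta_rows.append({"phenotype": name, "group": kingdom, "kind": "diversity"})

    genus = aggregate_and_prevalence_filter(filtered, min_prevalence)
    clr = clr_transform(genus, pseudocount)
    for col in clr.columns:
        group = "bacteria" if col.startswith("B_") else "protist"
        meta_rows.append({"phenotype": col, "group": group, "kind": "abundance"})

    values = pd.concat([pd.DataFrame(div_cols), clr], axis=1)
    if covariates is not None:
        covariates = covariates.loc[values.index]
    return PhenotypeTable(values, pd.DataFrame(meta_rows), covariates)
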