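"""Genotype panel container and its file formats.

A :class:`GenotypePanel` holds an individuals x SNPs allele-dosage matrix
(0/1/2, ``NaN`` for missing) together with the SNP map (id, chromosome, bp).
Panels round-trip through VCF (read via :mod:`cyvcf2`) and through a plain
dosage TSV (samples as rows, SNPs as columns, empty cells for missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["GenotypePanel", "read_vcf", "read_dosage_tsv"]


@dataclass
class GenotypePanel:
    """Allele-dosage matrix with map positions and missingness mask.

    Parameters
    ----------
    dosages:
        ``(n_individuals, n_snps)`` float array with values in {0, 1, 2}
        and ``NaN`` for missing genotypes.
    snp_map:
        Frame with columns ``snp_id``, ``chrom``, ``bp`` (and optionally
        ``freq``, the generating allele frequency), sorted by (chrom, bp).
    samples:
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D individuals x SNPs matrix")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise DataError(
                f"snp_map has {len(self.snp_map)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        if not self.samples:
            self.samples = [f"S{i + 1:04d}" for i in range(self.dosages.shape[0])]
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        x = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
        return x

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.dosages[:, mask],
            self.snp_map.loc[np.asarray(mask)].reset_index(drop=True),
            list(self.samples),
        )

    # ------------------------------------------------------------------ io

    def to_vcf(self, path: str) -> None:
        """Write a minimal diploid VCF (GT field only, unphased)."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.snp_map["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, row in self.snp_map.iterrows():
                gts = [
                    "./." if np.isnan(d) else gt_codes[d] for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row['chrom']}\t{row['bp']}\t{row['snp_id']}\tA\tG\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )

    def to_dosage_tsv(self, path: str) -> None:
        df = pd.DataFrame(
            self.dosages, index=self.samples, columns=self.snp_map["snp_id"]
        )
        df.to_csv(path, sep="\t", index_label="sample")


def read_vcf(path: str) -> GenotypePanel:
    """Load a diploid VCF into a dosage panel (alt-allele count per genotype)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, bps = [], [], [], []
    for variant in vcf:
        gt = np.asarray(variant.gt_types, dtype=float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        bps.append(variant.POS)
    if not rows:
        raise DataError(f"no variants found in {path}")
    snp_map = pd.DataFrame({"snp_id": ids, "chrom": chroms, "bp": bps})
    return GenotypePanel(np.vstack(rows).T, snp_map, samples)


def read_dosage_tsv(path: str, snp_map: pd.DataFrame | None = None) -> GenotypePanel:
    """Load a samples x SNPs dosage TSV; map defaults to one dummy contig."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "snp_id": df.columns,
                "chrom": "1",
                "bp": np.arange(1, df.shape[1] + 1) * 1000,
            }
        )
    return GenotypePanel(df.to_numpy(dtype=float), snp_map, list(df.index.astype(str)))
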