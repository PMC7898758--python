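"""Synthetic genotypes, microbiomes, annotations and sequences with ground truth.

Every downstream stage of the pipeline can be exercised against a planted,
recoverable signal:

* ``gen_genotypes`` draws a SNP panel under Hardy-Weinberg sampling with a
  block-copy linkage-disequilibrium scheme: within a block of consecutive
  SNPs each haplotype allele copies the block's seed haplotype with
  probability ``ld_rho`` and is drawn fresh otherwise, so the marginal
  frequency of every SNP stays inside ``maf_range`` while within-block
  correlation is non-trivial.
* ``gen_gene_annotation`` tiles gene intervals over the simulated
  chromosomes so that configurable shares of SNPs fall inside a gene, within
  5 kb of one, or farther away, and labels genes protein-coding / TF / miRNA.
* ``gen_microbiome`` builds a latent clr-scale abundance per taxon as
  sex + batch + polygenic term (covariance proportional to the realized GRM,
  scaled to the target heritability) + planted sparse SNP effects +
  residual, pushes each kingdom block through a softmax, splits genera into
  ASVs, and draws multinomial counts at a per-sample sequencing depth.  A
  correlated body-weight trait shares one causal SNP with a designated
  taxon.
* ``gen_sequences`` emits 1-kb promoters and 0.3-2-kb 3'-UTRs from a
  zero-order base composition with PFM consensus instances and 7mer-m8 seed
  sites planted at recorded positions.

All stages draw from RNG streams derived from the master seed by fixed
offsets, so each generator is individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .panel import GenotypePanel
from .phenotypes import CountTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "gen_genotypes",
    "gen_gene_annotation",
    "gen_microbiome",
    "gen_sequences",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
]

# fixed offsets deriving one RNG stream per generator from the master seed
_STREAM = {"genotypes": 11, "annotation": 23, "microbiome": 37, "sequences": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[stage],))
    )


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the reference design: 390 individuals genotyped at
    42,562 retained SNPs over 18 autosomes, 31 bacterial and 6 protist
    genera, sexes balanced across 7 batches, amplicon depths compatible with
    a 10,000-read rarefaction.  ``h2`` is the narrow-sense heritability of
    the latent polygenic background of each taxon; ``effect_size_sd`` is the
    spread of planted allele-substitution effects in clr units per allele.
    """

    n_individuals: int = 390
    n_snps: int = 42562
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    ld_block_size: int = 10
    n_bacteria: int = 31
    n_protists: int = 6
    n_causal_per_taxon: int = 3
    effect_size_sd: float = 0.4
    h2: float = 0.25
    depth_range: tuple[int, int] = (12000, 60000)
    batch_count: int = 7
    seed: int = 0
    # secondary structure knobs (not study-reported; see docs/methods.md)
    ld_rho: float = 0.8
    n_chromosomes: int = 18
    snp_spacing_bp: int = 2000
    n_regulator_snps: int = 2
    regulator_breadth: int = 8
    asvs_per_genus: tuple[int, int] = (1, 4)
    residual_sd: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.h2 < 1.0:
            raise ConfigError("h2 must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ConfigError("ld_rho must lie in [0, 1]")
        for name in (
            "n_individuals", "n_snps", "ld_block_size", "n_bacteria",
            "batch_count", "n_chromosomes", "snp_spacing_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("n_protists", "n_causal_per_taxon", "n_regulator_snps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be a non-negative count")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ConfigError("depth_range must be an increasing pair of positive counts")

    @property
    def n_taxa(self) -> int:
        return self.n_bacteria + self.n_protists


@dataclass
class TruthSet:
    """Planted ground truth recorded by the generators.

    ``causal_map`` holds (snp_id, taxon, effect in clr units per allele);
    ``regulator_snps`` are the planted pleiotropic SNPs; sequence placements
    record where motif instances and seed sites were inserted.
    """

    causal_map: list[tuple[str, str, float]] = field(default_factory=list)
    regulator_snps: list[str] = field(default_factory=list)
    motif_placements: list[tuple[str, int, str]] = field(default_factory=list)
    seed_site_placements: list[tuple[str, int]] = field(default_factory=list)
    body_weight_snp: str | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            causal_map=[tuple(x) for x in raw["causal_map"]],
            regulator_snps=list(raw["regulator_snps"]),
            motif_placements=[tuple(x) for x in raw["motif_placements"]],
            seed_site_placements=[tuple(x) for x in raw["seed_site_placements"]],
            body_weight_snp=raw.get("body_weight_snp"),
        )


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

def gen_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a dosage panel with block-copy LD and HWE marginals.

    The ``freq`` column of the returned map stores each SNP's generating
    allele frequency (the block-seed/fresh mixture), which realized sample
    frequencies track to binomial accuracy.
    """
    rng = _rng(cfg.seed, "genotypes")
    n, m = cfg.n_individuals, cfg.n_snps
    lo, hi = cfg.maf_range

    chrom_sizes = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    chrom_sizes[: m % cfg.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), chrom_sizes)
    bp = np.empty(m, dtype=np.int64)
    start = 0
    for size in chrom_sizes:
        gaps = rng.integers(cfg.snp_spacing_bp // 2, cfg.snp_spacing_bp * 3 // 2 + 1,
                            size=size)
        bp[start : start + size] = np.cumsum(gaps) + 1000
        start += size

    dosages = np.empty((n, m), dtype=float)
    freqs = np.empty(m, dtype=float)
    pos = 0
    while pos < m:
        # block must not straddle a chromosome boundary
        end = min(pos + cfg.ld_block_size, m)
        end = pos + int(np.searchsorted(chroms[pos:end], chroms[pos], side="right"))
        block = slice(pos, end)
        width = end - pos
        p_seed = rng.uniform(lo, hi)
        seed_hap = rng.random((n, 2)) < p_seed
        p_fresh = rng.uniform(lo, hi, size=width)
        copy = rng.random((n, 2, width)) < cfg.ld_rho
        fresh = rng.random((n, 2, width)) < p_fresh
        hap = np.where(copy, seed_hap[:, :, None], fresh)
        hap[:, :, 0] = seed_hap  # first SNP of the block is the seed itself
        dosages[:, block] = hap.sum(axis=1)
        freqs[block] = cfg.ld_rho * p_seed + (1 - cfg.ld_rho) * p_fresh
        freqs[pos] = p_seed
        pos = end

    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        dosages[mask] = np.nan

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"SNP{j + 1:06d}" for j in range(m)],
            "chrom": chroms.astype(str),
            "bp": bp,
            "freq": freqs,
        }
    )
    return GenotypePanel(dosages, snp_map)


# --------------------------------------------------------------------------
# Gene annotation
# --------------------------------------------------------------------------

def gen_gene_annotation(
    panel: GenotypePanel,
    tf_fraction: float = 0.05,
    mirna_fraction: float = 0.02,
    seed: int = 0,
    inside_frac: float = 0.6,
    near_frac: float = 0.2,
    window: int = 5000,
    gene_length_range: tuple[int, int] = (1000, 5000),
) -> pd.DataFrame:
    """One gene per SNP, placed inside / within ``window`` bp / far away.

    Class counts are exact: ``round(inside_frac * n)`` SNPs get a covering
    gene, ``round(near_frac * n)`` a gene 1..window bp away, the rest a gene
    beyond ``window``.  Gene-type labels (TF / miRNA / protein_coding) are
    likewise allocated with exact counts and then shuffled.  Returns a frame
    with columns gene_id, chrom, start, end, strand, gene_type, placement.
    """
    if tf_fraction < 0 or mirna_fraction < 0 or tf_fraction + mirna_fraction >= 1:
        raise ConfigError("tf_fraction + mirna_fraction must lie in [0, 1)")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM["annotation"],))
    )
    m = panel.n_snps
    n_inside = int(round(inside_frac * m))
    n_near = int(round(near_frac * m))
    if n_inside + n_near > m:
        raise ConfigError("inside_frac + near_frac must not exceed 1")
    placement = np.array(
        ["inside"] * n_inside + ["near"] * n_near + ["far"] * (m - n_inside - n_near)
    )
    rng.shuffle(placement)

    n_tf = int(round(tf_fraction * m))
    n_mir = int(round(mirna_fraction * m))
    gene_type = np.array(
        ["TF"] * n_tf + ["miRNA"] * n_mir + ["protein_coding"] * (m - n_tf - n_mir)
    )
    rng.shuffle(gene_type)

    lo_len, hi_len = gene_length_range
    lengths = rng.integers(lo_len, hi_len + 1, size=m)
    strands = np.where(rng.random(m) < 0.5, "+", "-")
    starts = np.empty(m, dtype=np.int64)
    for j in range(m):
        bp_j = int(panel.snp_map.at[j, "bp"])
        length = int(lengths[j])
        if placement[j] == "inside":
            starts[j] = bp_j - int(rng.integers(0, length))
        elif placement[j] == "near":
            dist = int(rng.integers(1, window + 1))
            if rng.random() < 0.5:
                starts[j] = bp_j + dist          # gene downstream of the SNP
            else:
                starts[j] = bp_j - dist - length + 1
        else:
            dist = window + int(rng.integers(2000, 20000))
            starts[j] = bp_j + dist
    starts = np.maximum(starts, 1)
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{j + 1:06d}" for j in range(m)],
            "chrom": panel.snp_map["chrom"].to_numpy(),
            "start": starts,
            "end": starts + lengths - 1,
            "strand": strands,
            "gene_type": gene_type,
            "placement": placement,
        }
    )


def write_gff3(annotation: pd.DataFrame, path: str) -> None:
    """Emit the annotation frame as GFF3 (gene features with biotype)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.iterrows():
            attrs = f"ID={g['gene_id']};biotype={g['gene_type']}"
            fh.write(
                f"{g['chrom']}\tawmnet_sim\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )


def read_gff3(path: str) -> pd.DataFrame:
    """Parse gene features from GFF3 into the annotation frame layout."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "gene_type": feat.attributes.get("biotype", ["protein_coding"])[0],
            }
        )
    if not rows:
        raise DataError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Microbiome counts + covariates
# --------------------------------------------------------------------------

def gen_microbiome(
    panel: GenotypePanel,
    cfg: SimConfig,
    truth: TruthSet | None = None,
    planted_effects: list[tuple[int, int, float]] | None = None,
) -> tuple[CountTable, pd.DataFrame, TruthSet]:
    """Simulate ASV counts and covariates from the latent mixed model.

    ``planted_effects`` overrides the random causal draw with explicit
    (snp_index, taxon_index, effect) triples; taxa are indexed bacteria
    first.  Returns (count table, covariates, truth).
    """
    if panel.n_individuals != cfg.n_individuals:
        raise DataError("panel and config disagree on the number of individuals")
    truth = truth or TruthSet()
    rng = _rng(cfg.seed, "microbiome")
    n, k = cfg.n_individuals, cfg.n_taxa
    genera = [f"BactGenus{i + 1:02d}" for i in range(cfg.n_bacteria)] + [
        f"ProtGenus{i + 1:02d}" for i in range(cfg.n_protists)
    ]
    kingdom = ["bacteria"] * cfg.n_bacteria + ["protist"] * cfg.n_protists

    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(0, cfg.batch_count, size=n)
    sex_eff = rng.normal(0.0, 0.15, size=k)
    batch_eff = rng.normal(0.0, 0.2, size=(cfg.batch_count, k))
    baseline = rng.normal(0.0, 1.2, size=k)

    x = panel.imputed_dosages()
    latent = (
        baseline[None, :]
        + sex[:, None] * sex_eff[None, :]
        + batch_eff[batch, :]
    )

    # polygenic background scaled to the target h2 on the latent scale
    sigma_e2 = cfg.residual_sd ** 2
    if cfg.h2 > 0:
        from .gwas import compute_grm, grm_eigendecomposition

        grm = compute_grm(panel)
        sigma_u2 = cfg.h2 / (1.0 - cfg.h2) * sigma_e2
        # Yang-style diagonal can leave the GRM slightly indefinite; draw the
        # polygenic term through the eigendecomposition with eigenvalues
        # clipped at zero
        d, u = grm_eigendecomposition(grm)
        root = u * np.sqrt(d)[None, :]
        latent = latent + np.sqrt(sigma_u2) * (root @ rng.standard_normal((n, k)))
    latent = latent + rng.normal(0.0, cfg.residual_sd, size=(n, k))

    # planted sparse causal SNPs
    if planted_effects is None:
        planted_effects = []
        for taxon in range(k):
            snps = rng.choice(panel.n_snps, size=cfg.n_causal_per_taxon, replace=False)
            effects = rng.normal(0.0, cfg.effect_size_sd, size=cfg.n_causal_per_taxon)
            planted_effects += [(int(s), taxon, float(e)) for s, e in zip(snps, effects)]
        # pleiotropic "regulator" SNPs hitting many bacterial taxa at once
        for _ in range(cfg.n_regulator_snps):
            snp = int(rng.choice(panel.n_snps))
            taxa = rng.choice(cfg.n_bacteria, size=min(cfg.regulator_breadth,
                                                       cfg.n_bacteria), replace=False)
            truth.regulator_snps.append(panel.snp_map.at[snp, "snp_id"])
            for taxon in taxa:
                eff = float(rng.normal(0.0, cfg.effect_size_sd) + np.sign(rng.random() - 0.5)
                            * cfg.effect_size_sd)
                planted_effects.append((snp, int(taxon), eff))
    for snp, taxon, eff in planted_effects:
        latent[:, taxon] += eff * x[:, snp]
        truth.causal_map.append((panel.snp_map.at[snp, "snp_id"], genera[taxon],
                                 float(eff)))

    # body weight sharing one causal SNP with the first bacterial taxon
    if planted_effects:
        shared_snp = planted_effects[0][0]
    else:
        shared_snp = int(rng.choice(panel.n_snps))
    truth.body_weight_snp = panel.snp_map.at[shared_snp, "snp_id"]
    body_weight = (
        20.0 + 1.5 * sex + 1.0 * x[:, shared_snp] + rng.normal(0.0, 2.0, size=n)
    )

    # softmax per kingdom, split genera into ASVs, multinomial sampling
    asv_counts: dict[str, np.ndarray] = {}
    taxonomy_rows = []
    offsets = {"bacteria": slice(0, cfg.n_bacteria),
               "protist": slice(cfg.n_bacteria, k)}
    for kd, sl in offsets.items():
        size = sl.stop - sl.start
        if size == 0:
            continue
        z = latent[:, sl]
        z = z - z.max(axis=1, keepdims=True)
        props = np.exp(z)
        props /= props.sum(axis=1, keepdims=True)
        n_asv = rng.integers(cfg.asvs_per_genus[0], cfg.asvs_per_genus[1] + 1,
                             size=size)
        weights = [rng.dirichlet(np.full(c, 2.0)) for c in n_asv]
        depth = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=n)
        asv_props = np.concatenate(
            [props[:, [t]] * weights[t][None, :] for t in range(size)], axis=1
        )
        draws = np.vstack(
            [rng.multinomial(depth[i], asv_props[i]) for i in range(n)]
        )
        col = 0
        for t in range(size):
            genus = genera[sl.start + t]
            for a in range(n_asv[t]):
                asv_id = f"ASV_{genus}_{a + 1}"
                asv_counts[asv_id] = draws[:, col]
                taxonomy_rows.append({"feature_id": asv_id, "genus": genus,
                                      "kingdom": kd})
                col += 1

    samples = [f"S{i + 1:04d}" for i in range(n)]
    counts = CountTable(
        pd.DataFrame(asv_counts, index=samples),
        pd.DataFrame(taxonomy_rows).set_index("feature_id"),
    )
    covariates = pd.DataFrame(
        {"sex": sex, "batch": batch, "body_weight": body_weight}, index=samples
    )
    return counts, covariates, truth


# --------------------------------------------------------------------------
# Sequences
# --------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def gen_sequences(
    annotation: pd.DataFrame,
    pfms: list,
    mirna_seed_site: str,
    truth: TruthSet | None = None,
    seed: int = 0,
    promoter_length: int = 1000,
    utr_length_range: tuple[int, int] = (300, 2000),
    gc: float = 0.42,
    plant_fraction: float = 0.3,
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Promoter and 3'-UTR sequences with planted motif and seed instances.

    For a ``plant_fraction`` share of genes, the consensus of a cycled PFM is
    written into the promoter at a recorded offset (strand recorded too), and
    the 7-mer ``mirna_seed_site`` into the UTR.  Returns (promoters, utrs,
    truth).
    """
    site = mirna_seed_site.upper().replace("U", "T")
    if len(site) != 7 or any(b not in "ACGT" for b in site):
        raise ConfigError("mirna_seed_site must be a 7-letter DNA string")
    truth = truth or TruthSet()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM["sequences"],))
    )
    promoters: dict[str, str] = {}
    utrs: dict[str, str] = {}
    gene_ids = list(annotation["gene_id"])
    n_plant = int(round(plant_fraction * len(gene_ids)))
    planted = set(rng.choice(len(gene_ids), size=n_plant, replace=False).tolist())

    consensi = []
    for pfm in pfms:
        counts = np.asarray(pfm.counts if hasattr(pfm, "counts") else pfm, dtype=float)
        consensi.append("".join("ACGT"[b] for b in counts.argmax(axis=0)))

    for idx, gene in enumerate(gene_ids):
        prom = _random_seq(rng, promoter_length, gc)
        utr_len = int(rng.integers(utr_length_range[0], utr_length_range[1] + 1))
        utr = _random_seq(rng, utr_len, gc)
        if idx in planted:
            if consensi:
                word = consensi[idx % len(consensi)]
                if len(word) > promoter_length:
                    raise DataError(
                        f"planted motif longer than the promoter for {gene}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                insert = word if strand == "+" else _revcomp(word)
                offset = int(rng.integers(0, promoter_length - len(word) + 1))
                prom = prom[:offset] + insert + prom[offset + len(word):]
                truth.motif_placements.append((gene, offset, strand))
            if len(site) > utr_len:
                raise DataError(f"planted seed site longer than the UTR for {gene}")
            offset = int(rng.integers(0, utr_len - len(site) + 1))
            utr = utr[:offset] + site + utr[offset + len(site):]
            truth.seed_site_placements.append((gene, offset))
        promoters[gene] = prom
        utrs[gene] = utr
    return promoters, utrs, truth


# --------------------------------------------------------------------------
# FASTA helpers
# --------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in
               sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
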