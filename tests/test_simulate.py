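import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from awmnet import gwas
from awmnet.awm import map_snp_to_gene
from awmnet.errors import ConfigError
from awmnet.regseq import Pfm
from awmnet.simulate import (
    SimConfig,
    TruthSet,
    gen_gene_annotation,
    gen_genotypes,
    gen_microbiome,
    gen_sequences,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"maf_range": (0.0, 0.5)}, "maf_range"),
            ({"maf_range": (0.1, 0.6)}, "maf_range"),
            ({"h2": 1.0}, "h2"),
            ({"n_snps": 0}, "n_snps"),
            ({"depth_range": (0, 100)}, "depth_range"),
            ({"missing_rate": 1.5}, "missing_rate"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)


class TestGenotypes:
    def test_no_missing_when_rate_zero(self):
        cfg = SimConfig(n_individuals=50, n_snps=100, missing_rate=0.0, seed=1)
        assert not np.isnan(gen_genotypes(cfg).dosages).any()

    def test_seed_determinism(self):
        cfg = SimConfig(n_individuals=40, n_snps=120, seed=5)
        a, b = gen_genotypes(cfg), gen_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snp_map, b.snp_map)

    def test_realized_maf_tracks_generating_frequency(self):
        cfg = SimConfig(n_individuals=400, n_snps=1000, missing_rate=0.0,
                        maf_range=(0.05, 0.5), seed=2)
        panel = gen_genotypes(cfg)
        assert (panel.maf() >= 0.01).all()
        realized = panel.allele_frequency()
        drawn = panel.snp_map["freq"].to_numpy()
        se = np.sqrt(drawn * (1 - drawn) / (2 * cfg.n_individuals))
        within = np.abs(realized - drawn) <= 5 * se
        assert within.mean() > 0.995

    def test_ld_blocks_are_correlated_and_independent_across(self):
        cfg = SimConfig(n_individuals=500, n_snps=40, ld_block_size=10,
                        missing_rate=0.0, ld_rho=0.9, n_chromosomes=1, seed=3)
        d = gen_genotypes(cfg).dosages
        within = np.corrcoef(d[:, 1], d[:, 2])[0, 1]
        across = np.corrcoef(d[:, 5], d[:, 15])[0, 1]
        assert abs(within) > 0.4
        assert abs(across) < 0.2

    def test_map_sorted_by_chrom_and_bp(self, tiny_panel):
        m = tiny_panel.snp_map
        for _, grp in m.groupby("chrom"):
            assert grp["bp"].is_monotonic_increasing


class TestAnnotation:
    def test_tf_fraction_zero_means_no_tf(self, tiny_panel):
        ann = gen_gene_annotation(tiny_panel, tf_fraction=0.0,
                                  mirna_fraction=0.0, seed=0)
        assert (ann["gene_type"] == "protein_coding").all()

    def test_exact_placement_counts_with_thirds(self):
        cfg = SimConfig(n_individuals=20, n_snps=99, snp_spacing_bp=60000,
                        seed=4)
        panel = gen_genotypes(cfg)
        ann = gen_gene_annotation(panel, seed=4, inside_frac=1 / 3,
                                  near_frac=1 / 3)
        counts = ann["placement"].value_counts()
        assert counts["inside"] == counts["near"] == counts["far"] == 33

    def test_placement_classes_agree_with_mapper(self):
        # wide SNP spacing so each SNP sees only its own gene
        cfg = SimConfig(n_individuals=20, n_snps=60, snp_spacing_bp=80000,
                        seed=5)
        panel = gen_genotypes(cfg)
        ann = gen_gene_annotation(panel, seed=5, inside_frac=0.5, near_frac=0.3)
        assigned = map_snp_to_gene(panel.snp_map, ann, window=5000)
        merged = assigned.merge(
            panel.snp_map.assign(placement=ann["placement"].to_numpy()),
            on="snp_id",
        )
        inside = merged.loc[merged["placement"] == "inside", "distance"]
        near = merged.loc[merged["placement"] == "near", "distance"]
        assert (inside == 0).all()
        assert ((near >= 1) & (near <= 5000)).all()
        far_ids = set(ann.loc[ann["placement"] == "far", "gene_id"])
        assert far_ids.isdisjoint(set(merged["gene_id"]))

    def test_gff3_roundtrip(self, tiny_panel, tmp_path):
        ann = gen_gene_annotation(tiny_panel, seed=1)
        path = tmp_path / "genes.gff3"
        write_gff3(ann, str(path))
        back = read_gff3(str(path))
        assert len(back) == len(ann)
        merged = back.merge(ann, on="gene_id", suffixes=("_r", ""))
        assert (merged["start_r"] == merged["start"]).all()
        assert (merged["gene_type_r"] == merged["gene_type"]).all()


class TestMicrobiome:
    def test_kingdom_depths_within_range_and_determinism(self):
        cfg = SimConfig(n_individuals=30, n_snps=60, n_bacteria=6,
                        n_protists=3, depth_range=(5000, 8000), seed=6)
        panel = gen_genotypes(cfg)
        counts, cov, truth = gen_microbiome(panel, cfg)
        tax = counts.taxonomy
        for kingdom in ("bacteria", "protist"):
            feats = [f for f in counts.counts.columns
                     if tax.loc[f, "kingdom"] == kingdom]
            totals = counts.counts[feats].sum(axis=1)
            assert totals.between(5000, 8000).all()
        again = gen_microbiome(panel, cfg)[0]
        pd.testing.assert_frame_equal(counts.counts, again.counts)

    def test_truth_records_existing_ids(self):
        cfg = SimConfig(n_individuals=30, n_snps=60, n_bacteria=6,
                        n_protists=3, seed=7)
        panel = gen_genotypes(cfg)
        counts, cov, truth = gen_microbiome(panel, cfg)
        snp_ids = set(panel.snp_map["snp_id"])
        genera = set(counts.taxonomy["genus"])
        for snp, taxon, eff in truth.causal_map:
            assert snp in snp_ids and taxon in genera
        assert set(truth.regulator_snps) <= snp_ids
        assert truth.body_weight_snp in snp_ids

    def test_covariates_shape_and_levels(self):
        cfg = SimConfig(n_individuals=40, n_snps=50, batch_count=7, seed=8)
        panel = gen_genotypes(cfg)
        _, cov, _ = gen_microbiome(panel, cfg)
        assert set(cov["sex"].unique()) <= {0, 1}
        assert cov["batch"].between(0, 6).all()
        assert cov["body_weight"].std() > 0

    def test_truthset_json_roundtrip(self, tmp_path):
        t = TruthSet(causal_map=[("SNP1", "G1", 0.5)], regulator_snps=["SNP2"],
                     motif_placements=[("g", 3, "+")],
                     seed_site_placements=[("g", 9)], body_weight_snp="SNP1")
        p = tmp_path / "truth.json"
        t.to_json(str(p))
        assert TruthSet.from_json(str(p)) == t


class TestSequences:
    def _ann(self, n):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "chrom": "1",
             "start": 1000, "end": 2000, "strand": "+",
             "gene_type": "protein_coding"}
        )

    def test_empty_annotation_gives_empty_fastas(self):
        proms, utrs, truth = gen_sequences(self._ann(0), [], "ACGTACG", seed=1)
        assert proms == {} and utrs == {}

    def test_planted_site_longer_than_sequence_raises(self):
        pfm = Pfm("long", np.ones((4, 1200)))
        from awmnet.errors import DataError

        with pytest.raises(DataError):
            gen_sequences(self._ann(4), [pfm], "ACGTACG", seed=2,
                          promoter_length=1000, plant_fraction=1.0)

    def test_chance_seed_hits_within_poisson_bounds(self):
        # GC-balanced background, no planting: expected chance 7-mer hits per
        # 300-bp gene ~ 294 * (1/4)^7 ~ 0.0179 per strand
        from awmnet.regseq import SeedSpec, find_seed_sites

        proms, utrs, _ = gen_sequences(
            self._ann(1000), [], "ACGTACG", seed=9, gc=0.5,
            utr_length_range=(300, 300), plant_fraction=0.0,
        )
        spec = SeedSpec("AACGUACGUACGUACGUACGU")   # site CGTACGT
        total = int(find_seed_sites(utrs, spec)["n_sites"].sum())
        mean = 1000 * (300 - 6) * 0.25**7
        assert poisson.ppf(0.005, mean) <= total <= poisson.ppf(0.995, mean)

    def test_fasta_roundtrip(self, tmp_path):
        proms, utrs, _ = gen_sequences(self._ann(5), [], "ACGTACG", seed=3,
                                       plant_fraction=0.0)
        path = tmp_path / "p.fa"
        write_fasta(proms, str(path))
        assert read_fasta(str(path)) == proms


class TestStatisticalInvariants:
    def test_grm_mean_diagonal_near_one_at_scale(self):
        cfg = SimConfig(n_individuals=300, n_snps=5000, missing_rate=0.0,
                        seed=10)
        g = gwas.compute_grm(gen_genotypes(cfg))
        assert abs(float(np.diag(g).mean()) - 1.0) < 0.05

    def test_heritability_recovery_on_latent_trait(self):
        # y = Xb + u + e with u drawn from the realized GRM at h2 = 0.4:
        # the REML estimate should recover the target on average
        target = 0.4
        estimates = []
        for rep in range(20):
            cfg = SimConfig(n_individuals=400, n_snps=1500, missing_rate=0.0,
                            seed=300 + rep)
            panel = gen_genotypes(cfg)
            grm = gwas.compute_grm(panel)
            d, u = gwas.grm_eigendecomposition(grm)
            rng = np.random.default_rng(rep)
            su2 = target / (1 - target)
            poly = (u * np.sqrt(d)) @ rng.standard_normal(400) * np.sqrt(su2)
            y = 0.3 * rng.integers(0, 2, 400) + poly + rng.standard_normal(400)
            cov = pd.DataFrame({"sex": rng.integers(0, 2, 400),
                                "batch": rng.integers(0, 7, 400)})
            fit = gwas.fit_null_model(y, cov, grm, eig=(d, u))
            estimates.append(fit.h2)
        assert abs(float(np.mean(estimates)) - target) < 0.15
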