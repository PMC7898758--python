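import numpy as np
import pandas as pd
import pytest

from awmnet import awm
from awmnet.errors import DataError

from conftest import make_resultset


def _annotation(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
    )


class TestSnpGeneMapping:
    def test_window_boundaries(self):
        ann = _annotation([("g1", "1", 100000, 102000, "+", "protein_coding")])
        snps = pd.DataFrame(
            {
                "snp_id": ["in", "edge_in", "edge_out", "far"],
                "chrom": "1",
                "bp": [101000, 100000 - 4999, 100000 - 5001, 300000],
            }
        )
        out = awm.map_snp_to_gene(snps, ann, window=5000)
        got = dict(zip(out["snp_id"], out["distance"]))
        assert got == {"in": 0, "edge_in": 4999}

    def test_nearest_gene_wins_and_ties_keep_both(self):
        ann = _annotation(
            [
                ("near", "1", 10000, 11000, "+", "protein_coding"),
                ("farther", "1", 13000, 14000, "+", "protein_coding"),
                ("tied_a", "2", 20000, 21000, "+", "protein_coding"),
                ("tied_b", "2", 23000, 24000, "+", "protein_coding"),
            ]
        )
        snps = pd.DataFrame(
            {
                "snp_id": ["s", "t"],
                "chrom": ["1", "2"],
                "bp": [11500, 22000],  # 500 vs 1500; exactly 1000 vs 1000
            }
        )
        out = awm.map_snp_to_gene(snps, ann, window=5000)
        assert list(out.loc[out["snp_id"] == "s", "gene_id"]) == ["near"]
        assert set(out.loc[out["snp_id"] == "t", "gene_id"]) == {"tied_a", "tied_b"}


def _selection_fixture():
    """Six anchored SNP-genes with hand-chosen pleiotropy structure.

    Diversity-associated anchors have pleiotropy {2, 4} so N_A = 3; among the
    rest one SNP clears 4 phenotypes (enters), one clears exactly 3 (does
    not).
    """
    phenos = ["AlphaBACT", "AlphaPROTO"] + [f"B_t{i}" for i in range(6)]
    idx = [f"s{i}" for i in range(6)]
    p = pd.DataFrame(1.0, index=idx, columns=phenos)
    p.loc["s0", ["AlphaBACT", "B_t0"]] = 0.01                     # rule A, pleio 2
    p.loc["s1", ["AlphaPROTO", "B_t0", "B_t1", "B_t2"]] = 0.01    # rule A, pleio 4
    p.loc["s2", ["B_t0", "B_t1", "B_t2", "B_t3"]] = 0.01          # pleio 4 > 3
    p.loc["s3", ["B_t0", "B_t1", "B_t2"]] = 0.01                  # pleio 3, out
    p.loc["s4", "B_t0"] = 0.01                                    # pleio 1, out
    # s5: nothing significant
    res = make_resultset(p)
    assignments = pd.DataFrame(
        {
            "snp_id": idx,
            "bp": res.snp_map["bp"],
            "gene_id": [f"g{i}" for i in range(6)],
            "distance": [0, 100, 0, 0, 2000, 0],
        }
    )
    return res, assignments


class TestRowSelection:
    def test_na_threshold_and_strict_inequality(self):
        res, assignments = _selection_fixture()
        mat = awm.select_rows(res, assignments)
        assert mat.n_a == 3.0
        by_cls = mat.rows.groupby("cls")["gene_id"].apply(set).to_dict()
        assert by_cls["diversity"] == {"g0", "g1"}
        assert by_cls["pleiotropic"] == {"g2"}
        assert "g3" not in set(mat.rows["gene_id"])

    def test_protist_diversity_alone_triggers_rule_a(self):
        res, assignments = _selection_fixture()
        mat = awm.select_rows(res, assignments)
        assert "g1" in set(mat.rows.loc[mat.rows["cls"] == "diversity",
                                        "gene_id"])

    def test_entries_are_standardized_effects(self):
        res, assignments = _selection_fixture()
        mat = awm.select_rows(res, assignments)
        np.testing.assert_allclose(
            mat.entries.loc["g0"].to_numpy(),
            res.zscores.loc["s0"].to_numpy(),
        )

    def test_no_rule_a_raises(self):
        res, assignments = _selection_fixture()
        res.pvalues[["AlphaBACT", "AlphaPROTO"]] = 0.5
        with pytest.raises(DataError):
            awm.select_rows(res, assignments)

    def test_planted_pleiotropic_regulators_fully_recovered(self):
        # regulators significant on 6 phenotypes, background on at most 2
        rng = np.random.default_rng(8)
        phenos = ["AlphaBACT", "AlphaPROTO"] + [f"B_t{i}" for i in range(8)]
        idx = [f"s{i}" for i in range(40)]
        p = pd.DataFrame(0.5, index=idx, columns=phenos)
        p.iloc[0, 0] = 0.01                       # one rule-A anchor, pleio 1
        planted = idx[1:6]
        for s in planted:
            cols = rng.choice(phenos[2:], size=6, replace=False)
            p.loc[s, cols] = 0.001
        for s in idx[6:]:
            cols = rng.choice(phenos[2:], size=rng.integers(0, 3), replace=False)
            p.loc[s, cols] = 0.01
        res = make_resultset(p)
        assignments = pd.DataFrame(
            {"snp_id": idx, "bp": res.snp_map["bp"],
             "gene_id": [f"g{i}" for i in range(40)], "distance": 0}
        )
        mat = awm.select_rows(res, assignments)
        selected = set(mat.rows.loc[mat.rows["cls"] == "pleiotropic", "gene_id"])
        want = {f"g{i}" for i in range(1, 6)}
        assert want <= selected          # sensitivity 1.0
        assert mat.n_a == 1.0


class TestAddRegulators:
    def test_zero_association_regulator_still_enters(self):
        res, assignments = _selection_fixture()
        anchors = awm.anchor_genes(assignments, res)
        mat = awm.select_rows(res, assignments)
        hits = pd.DataFrame({"gene_id": ["g5"]})
        out = awm.add_regulators(mat, hits, res, anchors)
        row = out.rows.set_index("gene_id").loc["g5"]
        assert row["cls"] == "regulator"
        assert row["pleiotropy"] == 0

    def test_existing_row_not_duplicated(self):
        res, assignments = _selection_fixture()
        anchors = awm.anchor_genes(assignments, res)
        mat = awm.select_rows(res, assignments)
        out = awm.add_regulators(mat, pd.DataFrame({"gene_id": ["g0"]}), res,
                                 anchors)
        assert len(out) == len(mat)
        assert out.rows.set_index("gene_id").loc["g0", "cls"] == "diversity"

    def test_empty_hits_is_identity(self):
        res, assignments = _selection_fixture()
        anchors = awm.anchor_genes(assignments, res)
        mat = awm.select_rows(res, assignments)
        out = awm.add_regulators(mat, pd.DataFrame({"gene_id": []}), res, anchors)
        assert len(out) == len(mat)


class TestPhenotypeClustering:
    def _matrix(self, entries):
        rows = pd.DataFrame(
            {"gene_id": entries.index, "snp_id": entries.index,
             "distance": 0, "cls": "diversity", "pleiotropy": 1}
        )
        return awm.AwmMatrix(entries=entries, rows=rows, n_a=1.0)

    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((30, 3))
        entries = pd.DataFrame(
            np.column_stack([base, base[:, 0], -base[:, 1]]),
            index=[f"g{i}" for i in range(30)],
            columns=["a", "b", "c", "a_dup", "b_neg"],
        )
        corr, linkage, order = awm.phenotype_correlation_cluster(
            self._matrix(entries)
        )
        assert corr.loc["a", "a_dup"] == pytest.approx(1.0)
        assert corr.loc["b", "b_neg"] == pytest.approx(-1.0)
        assert abs(order.index("a") - order.index("a_dup")) == 1

    def test_planted_blocks_recovered_at_two_cluster_cut(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(2)
        n = 200
        f1, f2 = rng.standard_normal((2, n))
        block1 = np.column_stack([f1 + 0.5 * rng.standard_normal(n)
                                  for _ in range(4)])
        block2 = np.column_stack([f2 + 0.5 * rng.standard_normal(n)
                                  for _ in range(4)])
        entries = pd.DataFrame(
            np.column_stack([block1, block2]),
            index=[f"g{i}" for i in range(n)],
            columns=[f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)],
        )
        _, linkage, _ = awm.phenotype_correlation_cluster(self._matrix(entries))
        labels = fcluster(linkage, t=2, criterion="maxclust")
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_constant_column_raises_with_name(self):
        entries = pd.DataFrame(
            {"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        with pytest.raises(DataError, match="flat"):
            awm.phenotype_correlation_cluster(self._matrix(entries))

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(3)
        entries = pd.DataFrame(rng.standard_normal((10, 4)),
                               index=[f"g{i}" for i in range(10)],
                               columns=list("abcd"))
        corr, linkage, order = awm.phenotype_correlation_cluster(
            self._matrix(entries)
        )
        nwk = awm.linkage_to_newick(linkage, list(corr.index))
        assert all(leaf in nwk for leaf in "abcd")
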