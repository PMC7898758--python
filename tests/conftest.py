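from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from awmnet.gwas import GwasResultSet, standardize_effects
from awmnet.phenotypes import CountTable
from awmnet.simulate import SimConfig, gen_genotypes


@pytest.fixture(scope="session")
def tiny_panel():
    """60 individuals x 200 SNPs, a little missingness, fixed seed."""
    cfg = SimConfig(n_individuals=60, n_snps=200, ld_block_size=5,
                    missing_rate=0.02, seed=7)
    return gen_genotypes(cfg)


@pytest.fixture()
def small_counts():
    """Hand-sized ASV table: 6 samples, 5 bacterial + 2 protist ASVs."""
    counts = pd.DataFrame(
        {
            "asv1": [120, 80, 60, 100, 90, 70],
            "asv2": [30, 40, 0, 20, 10, 25],
            "asv3": [0, 5, 10, 0, 15, 5],
            "asv4": [50, 60, 70, 40, 30, 55],
            "asv5": [1, 0, 0, 0, 0, 0],
            "asv6": [200, 150, 180, 160, 170, 140],
            "asv7": [20, 30, 10, 25, 15, 35],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    taxonomy = pd.DataFrame(
        {
            "genus": ["GenA", "GenA", "GenB", "GenB", "GenC", "GenP", "GenP"],
            "kingdom": ["bacteria"] * 5 + ["protist"] * 2,
        },
        index=pd.Index([f"asv{i}" for i in range(1, 8)], name="feature_id"),
    )
    return CountTable(counts, taxonomy)


def make_resultset(
    pvalues: pd.DataFrame,
    effects: pd.DataFrame | None = None,
    snp_map: pd.DataFrame | None = None,
) -> GwasResultSet:
    """Assemble a GwasResultSet from explicit matrices (tests only)."""
    if effects is None:
        rng = np.random.default_rng(0)
        effects = pd.DataFrame(
            rng.standard_normal(pvalues.shape),
            index=pvalues.index, columns=pvalues.columns,
        )
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "snp_id": pvalues.index,
                "chrom": "1",
                "bp": np.arange(1, len(pvalues) + 1) * 10000,
            }
        )
    res = GwasResultSet(
        effects=effects,
        se=effects * 0 + 1.0,
        pvalues=pvalues,
        snp_map=snp_map,
        varcomps=pd.DataFrame(
            {"phenotype": pvalues.columns, "sigma_u2": 0.1, "sigma_e2": 0.9,
             "h2": 0.1}
        ),
    )
    return standardize_effects(res)
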