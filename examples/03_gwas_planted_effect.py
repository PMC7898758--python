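"""Recover a planted allele-substitution effect with the mixed model.

Plants a 1.0 clr-unit-per-allele effect of one SNP on one bacterial genus,
pushes it through count generation and the phenotype pipeline, and scans all
SNPs with the GRM-controlled mixed model y = sex + batch + u + s*a + e.
"""

import numpy as np

from awmnet import gwas
from awmnet.phenotypes import build_phenotypes
from awmnet.simulate import SimConfig, gen_genotypes, gen_microbiome

cfg = SimConfig(n_individuals=390, n_snps=600, h2=0.3, n_causal_per_taxon=0,
                n_regulator_snps=0, seed=7)
panel = gen_genotypes(cfg)
snp = int(np.argmin(np.abs(panel.maf() - 0.3)))   # a SNP at MAF ~ 0.3
counts, covariates, truth = gen_microbiome(panel, cfg,
                                           planted_effects=[(snp, 2, 1.0)])
phen = build_phenotypes(counts, covariates, seed=7)

filtered = gwas.filter_snps(panel)
res = gwas.run_gwas(filtered, phen.values[["B_BactGenus03"]],
                    covariates[["sex", "batch"]])

sid = panel.snp_map.at[snp, "snp_id"]
eff = res.effects.loc[sid, "B_BactGenus03"]
se = res.se.loc[sid, "B_BactGenus03"]
p = res.pvalues.loc[sid, "B_BactGenus03"]
h2 = res.varcomps.loc[0, "h2"]

print(f"planted effect 1.0 at {sid} (MAF {panel.maf()[snp]:.2f})")
print(f"estimate: {eff:.3f} +/- {se:.3f}   p = {p:.2e}")
print(f"REML heritability of the phenotype: {h2:.2f}")
print("The estimate sits slightly below 1.0: the clr transform re-centres")
print("each sample, attenuating a single-taxon effect by ~(1 - 1/K).")
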