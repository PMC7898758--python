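"""Published summary statistics bundled as worked-example inputs.

The constants below are summary-level results of a genome-wide association
study of gut microbial communities in a commercial pig population: 390
genotyped animals, 42,562 SNPs after filtering, and 39 microbial phenotypes
(Shannon alpha diversity for bacteria and for protists, plus the clr
abundance of 31 bacterial and 6 protist genera).  They are printed numbers,
not raw data, and serve two purposes: worked examples for the arithmetic
operations (FDR formula, regulator-table correlation analytics, seed-site
enrichment) and regression anchors for the acceptance checks.

``significant_snp_counts`` gives, per phenotype, the number of SNPs
significant at nominal P < 0.05, 0.01 and 0.001.  ``regulator_table`` gives
the 47 key regulators with their RIF1/RIF2 scores, standardized association
with the two alpha diversities, top-associated phenotype, pleiotropy (number
of phenotypes with P < 0.05) and network connections (first neighbors in the
PCIT co-association network).
"""

from __future__ import annotations

import io

import pandas as pd

#: Total number of SNPs tested per GWAS in the reference study.
N_SNPS_TESTED = 42562

#: Distinct-gene and total-site counts from the miRNA 7mer-m8 seed search
#: for the top microRNA regulator: foreground = seed sites in the 3'-UTRs of
#: the 588 co-associated candidate target genes; background = the same search
#: in the reverse-complemented UTRs.
MIRNA_SEED_COUNTS = {
    "foreground_sites": 155,
    "foreground_genes": 71,
    "background_sites": 115,
    "background_genes": 48,
    "candidate_target_genes": 588,
}

_SIG_SNP_TSV = """\
phenotype\tgroup\tkind\tn_p05\tn_p01\tn_p001
Anaerovibrio\tbacteria\tabundance\t3836\t355\t105
Blautia\tbacteria\tabundance\t3803\t232\t88
Bulleidia\tbacteria\tabundance\t4114\t196\t77
Butyricicoccus\tbacteria\tabundance\t3830\t255\t92
Campylobacter\tbacteria\tabundance\t4088\t271\t69
Catenibacterium\tbacteria\tabundance\t4407\t164\t25
Clostridium\tbacteria\tabundance\t4024\t211\t67
Collinsella\tbacteria\tabundance\t3969\t290\t73
Coprococcus\tbacteria\tabundance\t4152\t269\t68
Desulfovibrio\tbacteria\tabundance\t3797\t203\t70
Dorea\tbacteria\tabundance\t4170\t226\t63
Faecalibacterium\tbacteria\tabundance\t3644\t750\t387
Fibrobacter\tbacteria\tabundance\t4032\t225\t66
Gemmiger\tbacteria\tabundance\t4077\t238\t43
Lachnospira\tbacteria\tabundance\t4192\t248\t64
Lactobacillus\tbacteria\tabundance\t3966\t291\t103
Megasphaera\tbacteria\tabundance\t4027\t234\t69
Mitsuokella\tbacteria\tabundance\t4201\t211\t58
Oscillospira\tbacteria\tabundance\t4161\t198\t68
Parabacteroides\tbacteria\tabundance\t4206\t211\t45
Peptococcus\tbacteria\tabundance\t4254\t319\t95
Phascolarctobacterium\tbacteria\tabundance\t3921\t278\t129
Prevotella\tbacteria\tabundance\t3952\t267\t66
RFN20\tbacteria\tabundance\t3946\t299\t101
Roseburia\tbacteria\tabundance\t4025\t264\t59
Ruminococcus\tbacteria\tabundance\t4015\t265\t97
Sphaerochaeta\tbacteria\tabundance\t4143\t213\t68
Streptococcus\tbacteria\tabundance\t4060\t260\t73
Succinivibrio\tbacteria\tabundance\t4071\t314\t99
Sutterella\tbacteria\tabundance\t4016\t248\t81
Treponema\tbacteria\tabundance\t3966\t307\t102
AlphaBACT\tbacteria\tdiversity\t3960\t314\t89
Entamoeba\tprotist\tabundance\t3849\t335\t117
Hypotrichomonas\tprotist\tabundance\t3897\t230\t67
Trichomitus\tprotist\tabundance\t3944\t307\t126
Tetratrichomonas\tprotist\tabundance\t3998\t266\t64
Neobalantidium\tprotist\tabundance\t3828\t297\t139
Blastocystis\tprotist\tabundance\t3859\t320\t78
AlphaPROTO\tprotist\tdiversity\t4195\t259\t67
"""

_REGULATOR_TSV = """\
regulator\trif1\trif2\talpha_b\talpha_p\ttop_association\tpleiotropy\tconnections
PRDM15\t0.648\t2.806\t0.239\t0.277\tB_Treponema\t10\t942
HOXD12\t1.342\t2.536\t-0.667\t-0.624\tB_Sphaerochaeta\t1\t910
ZNF514\t0.045\t2.607\t-2.938\t0.310\tB_Sphaerochaeta\t5\t889
KIAA1549\t1.270\t2.715\t-1.701\t-1.465\tB_RFN20\t3\t812
KLF7\t-5.625\t0.204\t-0.603\t1.249\tB_Bulleidia\t2\t807
CREB3L2\t-2.411\t0.511\t-0.694\t0.818\tB_Sphaerochaeta\t0\t676
TFE3\t-0.127\t2.144\t1.045\t-0.216\tB_Phascolarctobacterium\t3\t627
TBX15\t2.506\t1.414\t-0.373\t-1.229\tB_Anaerovibrio\t2\t617
STAT1\t-1.464\t2.285\t-1.043\t0.370\tB_Catenibacterium\t5\t607
PURG\t1.542\t2.173\t-1.320\t0.338\tB_Sphaerochaeta\t2\t595
ssc-mir-371\t-2.848\t1.073\t1.181\t-0.690\tB_Roseburia\t3\t588
MTA3\t0.390\t2.097\t-0.952\t-0.107\tP_Hypotrichomonas\t2\t556
OSR2\t-2.512\t-0.194\t0.270\t0.005\tB_Lachnospira\t3\t473
DBX1\t-2.047\t-0.129\t-2.207\t-1.577\tB_Peptococcus\t4\t468
UNCX\t-3.085\t-0.194\t-0.051\t1.258\tB_Desulfovibrio\t1\t426
MYEF2\t-0.754\t-2.657\t1.215\t2.430\tB_Fibrobacter\t4\t391
GBX1\t-0.730\t-2.439\t-0.245\t-1.460\tB_Campylobacter\t2\t380
ZNF134\t-2.419\t0.128\t-0.572\t1.686\tB_Lactobacillus\t2\t370
ZNF606\t-2.419\t0.128\t-0.572\t1.686\tB_Lactobacillus\t2\t370
SOX9\t-2.524\t-0.404\t-0.498\t0.096\tB_Anaerovibrio\t0\t284
KMT2C\t-0.311\t-2.260\t-0.628\t-0.811\tB_Catenibacterium\t3\t281
RUNX2\t-3.631\t-1.878\t-0.206\t-1.776\tB_Collinsella\t3\t273
ELF2\t-1.740\t-2.300\t-0.739\t1.688\tB_Mitsuokella\t1\t245
ZNF322\t-2.079\t-0.792\t-0.233\t0.809\tB_Collinsella\t2\t229
IRF2\t-0.764\t-2.656\t-0.697\t-1.697\tB_Peptococcus\t0\t209
GTF2IRD1\t2.117\t0.660\t-1.421\t0.132\tB_Lachnospira\t0\t206
ZNF516\t2.099\t0.150\t2.010\t0.690\tB_Fibrobacter\t2\t195
NFE2L2\t-2.077\t-0.227\t0.705\t-0.051\tB_Coprococcus\t1\t183
NCOR1\t-1.999\t-0.455\t-1.007\t1.063\tB_Coprococcus\t2\t165
KLF14\t-2.287\t-2.255\t-0.327\t-1.073\tB_Sutterella\t1\t161
ZGLP1\t2.029\t-0.491\t0.577\t0.729\tB_Butyricicoccus\t3\t161
TCF4\t-2.497\t-1.382\t0.280\t-0.333\tB_Clostridium\t1\t150
TP73\t-2.788\t-0.275\t0.633\t-1.082\tB_Campylobacter\t1\t146
ZNF782\t-2.831\t-0.500\t0.382\t-1.811\tB_Desulfovibrio\t0\t132
SALL1\t-1.133\t-2.716\t-0.833\t-2.125\tP_AlphaPROTO\t2\t131
TOX3\t-2.335\t-2.043\t0.365\t1.641\tB_Lactobacillus\t1\t129
TRERF1\t-2.359\t-1.043\t-0.286\t-2.005\tP_Neobalantidium\t3\t128
MECP2\t-2.059\t-0.864\t0.536\t-0.591\tB_Dorea\t2\t118
SMAD4\t-2.460\t-2.206\t0.431\t1.586\tB_Catenibacterium\t0\t118
IKZF2\t-1.694\t-2.864\t-0.578\t-1.337\tP_AlphaPROTO\t0\t117
ssc-mir-9817\t-1.841\t-2.175\t2.358\t2.135\tB_RFN20\t0\t116
ZHX2\t-2.028\t-1.124\t0.266\t-1.654\tB_Desulfovibrio\t1\t109
ZNF282\t-1.657\t-2.258\t0.954\t1.573\tB_Ruminococcus\t0\t85
BAZ2B\t-2.287\t-0.786\t-1.879\t0.484\tB_Clostridium\t1\t76
ssc-mir-29a\t-2.067\t-2.748\t-0.568\t0.811\tB_Lachnospira\t2\t62
NFATC3\t-2.132\t-2.525\t0.270\t0.442\tB_Desulfovibrio\t1\t24
ZNF18\t-1.353\t-2.134\t-0.490\t-0.929\tP_Neobalantidium\t0\t18
"""


def significant_snp_counts() -> pd.DataFrame:
    """Per-phenotype significant-SNP counts at nominal P < 0.05 / 0.01 / 0.001.

    Returns a 39-row frame with columns ``phenotype``, ``group``, ``kind``,
    ``n_p05``, ``n_p01``, ``n_p001``.
    """
    return pd.read_csv(io.StringIO(_SIG_SNP_TSV), sep="\t")


def regulator_table() -> pd.DataFrame:
    """The 47 key regulators with RIF scores, pleiotropy and connectivity."""
    return pd.read_csv(io.StringIO(_REGULATOR_TSV), sep="\t")
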