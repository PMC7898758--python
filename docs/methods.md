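# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot establish.

## Phenotype construction

The pipeline order is fixed: sample read-depth filter (≥ 10,000 reads) →
ASV filter → two branches.  The diversity branch rarefies the filtered ASV
table to exactly 10,000 reads (multivariate hypergeometric, i.e. without
replacement) and computes one Shannon index per kingdom on the rarefied
counts; the abundance branch aggregates the *unrarefied* filtered ASVs to
genus, keeps genera present in strictly more than 60% of samples, and
applies the centred log-ratio transform per kingdom block.

Choices where the procedure was open:

* **ASV discard rule is a conjunction** — a feature is dropped only if it is
  both in fewer than 3 samples *and* under 0.005% of total counts.
* **Shannon uses the natural log.**  The base is a monotone rescaling and is
  applied consistently; `scipy.stats.entropy` provides the computation.
* **clr zero handling**: pseudocount 1 added to every genus count
  (configurable).  With pseudocount 0 the transform is exactly
  scale-invariant; with the pseudocount it is approximately so at realistic
  depths.
* **"Present" means count > 0** after the ASV filter, both for prevalence
  and for the Shannon support.

## Mixed-model GWAS

Per phenotype: y = sex + batch + u + s·a + e with u ~ N(0, σ²ᵤG),
e ~ N(0, σ²ₑI).  G follows Yang et al. (2011): standardized cross-products
off the diagonal and the bias-corrected form 1 + (x² − (1+2p)x + 2p²)/(2pq)
on it.  Missing dosages are mean-imputed per SNP, both for G and for
association.

REML works in the eigenbasis of G, where the covariance is diagonal in the
variance ratio λ = σ²ᵤ/σ²ₑ: the restricted likelihood is profiled over the
fixed effects and σ²ₑ and optimised over log₁₀λ on a 33-point grid in
[−8, 8] refined by bounded Brent search (xatol 1e-6).  A maximiser at the
grid edge is clamped (σ²ᵤ = 0 at the lower edge) and flagged.  Variance
components are estimated once per phenotype under the no-SNP null and held
fixed during the scan — the standard one-step approximation; the G = I
limit then reduces to ordinary least squares exactly, which the tests
assert at 1e-9.  Each SNP is tested by a Wald z with the covariance treated
as known; p-values are clipped into (0, 1].  The scan is vectorised: the
rotated dosage matrix UᵀX_g is computed once per panel and reused across
phenotypes.

The FDR summary uses the explicit formula FDR = P(1 − A/T)/((A/T)(1 − P))
and is reported as a percentage.  Standardized effects divide each
phenotype's effect column by its sd (denominator n − 1).

## AWM selection

SNPs anchor to the nearest gene within 5 kb (distance 0 inside the span; an
exact tie keeps the SNP eligible for both genes).  One SNP per gene: the
smallest key-phenotype p-value (minimum over the two alpha diversities),
ties broken by higher pleiotropy, then smaller bp.  Rule A admits anchors
with p < 0.05 on either alpha diversity; N_A is the mean pleiotropy count
of those anchors, kept as a real number; rule B admits remaining anchors
with pleiotropy strictly above N_A.  Pleiotropy counts nominal p < 0.05
over all phenotype columns, including the key phenotypes.  RIF-significant
regulators are appended afterwards even with zero associations; class
labels follow the precedence diversity > pleiotropic > regulator.
Phenotype clustering uses average linkage on 1 − r.

## RIF

The two regulatory impact factors are computed in standardized-SNP-effect
space.  With bacterial columns as group 1 and protist columns as group 2
(each alpha diversity belongs to its kingdom's group): e₁ⱼ/e₂ⱼ are the mean
|z| of target j within each group (the analogue of differential
expression), r₁ᵢⱼ/r₂ᵢⱼ the within-group Pearson correlations of regulator
and target row vectors (the analogue of co-expression), PIFⱼ = (e₁+e₂)/2
and dCoᵢⱼ = r₁ − r₂.  Then RIF1ᵢ = meanⱼ PIFⱼ·dCo², RIF2ᵢ = meanⱼ
[(e₁r₁)² − (e₂r₂)²].  RIF1 is non-negative and symmetric under group
exchange; RIF2 is antisymmetric.  Both are z-standardized across
regulators (sd denominator n − 1); significance defaults to |z| ≥ 1.96 on
either metric — the threshold is configurable because the reference count
of significant regulators does not pin it down.  A regulator row constant
within a group contributes correlation 0 (warned).  All intermediates are
exposed on the returned object so alternative formulations can be swapped.

## PCIT

For every trio (x, y, z) the three first-order partials
r_ab·c = (r_ab − r_ac·r_bc)/√((1−r_ac²)(1−r_bc²)) are computed; the trio
tolerance ε is the mean of |partial/direct| over the ratios whose direct
correlation is nonzero (if none is defined the trio cannot eliminate).
Edge (x, y) dies if some z gives |r_xy| ≤ ε|r_xz| and |r_xy| ≤ ε|r_yz|
(non-strict).  Unit off-diagonal correlations are handled by clamping r² at
1 − 1e-12 inside the square roots.  The implementation chunks the third
index and is exact: tests require identity with a naive all-trios reference
on every instance (200 random matrices up to 60 nodes), and invariance to
chunk size and node permutation.  Zero correlations never form edges; edge
sign is the sign of r.

A note on a boundary case: a trio whose partial r_xy·z is exactly zero does
*not* automatically eliminate the (x, y) edge — elimination additionally
requires the tolerance inequality, which fails when the direct correlations
are strong (e.g. r_xz = r_yz = 0.8, r_xy = 0.64 keeps its edge, while
r_xz = r_yz = 0.3, r_xy = 0.09 loses it).

## Sequence follow-up

PFMs (JASPAR text, parsed with `Bio.motifs`) become log₂-odds PWMs against
a zero-order background, with a pseudocount added to counts per cell
(default 0.5); zero cells at pseudocount 0 produce −∞ log-odds and such
matrices are rejected at scan time.  Window-score p-values are exact under
the background: per-column scores are integerized at scale 1000 (error
< 10⁻³ in log₂-odds units) and their distributions convolved across
columns; the survival function of the resulting lattice distribution gives
P(score ≥ s).  Both strands are scanned by default; a hit on the minus
strand is reported at its offset within the reverse complement.  Windows
containing non-ACGT characters are skipped.  The background is estimated
from the scanned sequence set unless supplied.

The 7mer-m8 site is the DNA reverse complement of mature-miRNA positions
2–8; matches are exact and overlapping occurrences are all counted, while
genes count once in enrichment summaries.  The background search applies
the identical procedure to each reverse-complemented UTR; fold enrichment
is the ratio of distinct genes with ≥ 1 site.  A self-reverse-complementary
site makes both searches identical (fold exactly 1); such sites exist only
at even lengths, so the property is exercised with a 6-mer palindrome.

## Synthetic data

The generator's defaults mirror the reference design: 390 individuals,
42,562 SNPs on 18 autosomes, 31 bacterial + 6 protist genera, two sexes,
seven batches, per-kingdom sequencing depths of 12,000–60,000 reads
(compatible with the 10,000-read rarefaction), MAF drawn in (0.05, 0.5].

* **LD**: block-copy haplotypes — within a block of 10 consecutive SNPs
  each haplotype allele copies the block's seed haplotype with probability
  ρ = 0.8, otherwise it is drawn fresh at its own frequency.  Marginal
  frequencies stay in the configured range (the mixture of two in-range
  frequencies); within-block correlation is ~ρ² between non-seed SNPs,
  blocks are independent.  This is deliberately the simplest structure that
  makes 5-kb gene anchoring and the GRM non-trivial; it is not a
  coalescent model.
* **Latent abundance model**: per taxon, clr-scale latent = baseline
  (sd 1.2) + sex effect (sd 0.15) + batch effect (sd 0.2) + polygenic term
  drawn from N(0, σ²ᵤ·G_realized) + planted SNP effects + residual
  (sd 0.5), with σ²ᵤ set so the polygenic share of the non-fixed variance
  is h². The default h² = 0.25 is a design parameter of the generator —
  the reference study reports no per-taxon heritabilities — chosen as a
  realistic mid-range value for microbial traits.  Effect sizes of planted
  causal SNPs are N(0, 0.4²) clr units per allele; a small number of
  "regulator" SNPs additionally hit eight bacterial taxa at once to give
  the AWM/RIF stages a recoverable pleiotropic signal.
* **Softmax link**: each kingdom block's latent vector maps through a
  softmax to proportions, genera split into 1–4 ASVs by Dirichlet weights,
  and counts are multinomial at the drawn depth.  clr(softmax(x)) equals
  x − mean(x) exactly, so a planted single-taxon effect reappears in the
  clr phenotype attenuated by (1 − 1/K); recovery tests budget for this.
* **Body weight** is Gaussian (20 ± 2 kg scale, sex effect 1.5) and shares
  its causal SNP with the first planted abundance effect, supporting
  pleiotropy analyses between a host trait and a taxon.
* **Sequences** are i.i.d. zero-order (default GC 0.42); motif consensus
  strings and seed sites are written at recorded offsets (random strand for
  motifs) in a configurable share of genes.
* **Streams**: each generator draws from its own RNG stream derived from
  the master seed by a fixed spawn key, so stages are individually
  reproducible.

What passing tests on this generator do **not** show: robustness to real
amplicon artefacts (sequencing error, chimeras, compositional zeros beyond
multinomial sampling), population structure beyond the GRM, realistic LD
decay, or genuine regulatory biology in the sequences.  They do show the
algorithms are calibrated (type-I error, KS-uniform null p-values), recover
planted signals at the stated power, and agree exactly with independent
brute-force references where the computation is combinatorial.

## Problem sizes

The default end-to-end pipeline run simulates 200 individuals × 4,000 SNPs
× 20 taxa; calibration and recovery studies use 390–400 individuals with
600–2,000 SNPs and 20–50 replicates.  These sizes were chosen so the whole
verification cycle stays interactive while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances; all of them are
configurable upward.

## Known limitations

* The per-SNP test fixes the variance components at their null REML values
  (one-step approximation); p-values at extremely strong signals are
  slightly anticonservative relative to per-SNP refitting.
* The exact PWM p-value rounds scores to the 1e-3 lattice; ties at the
  threshold can differ from an infinite-precision scan by one lattice step.
* The published FDR table's P < 0.01 and P < 0.001 columns are internally
  inconsistent with the FDR formula by a near-constant factor of ten; only
  the P < 0.05 column is reproduced (see `awmnet.datasets`).
* RIF formulas in the literature are described verbally; the forms here
  adapt the cited metrics to SNP-effect space and are exposed for
  substitution.
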