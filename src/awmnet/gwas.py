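"""Single-SNP mixed-model association with a genomic relationship matrix.

For each phenotype y (a clr genus abundance or a Shannon diversity) the model
is

    y = sex + batch + u + s_l * a_l + e,      u ~ N(0, sigma_u^2 G),
                                              e ~ N(0, sigma_e^2 I)

where G is the Yang et al. (2011)-style genomic relationship matrix built
from the filtered SNPs, s_l is the 0/1/2 allele dosage at SNP l and a_l its
allele-substitution effect.  Variance components are estimated once per
phenotype by REML under the no-SNP null, using the eigendecomposition of G so
that the restricted likelihood reduces to a one-dimensional optimisation over
the variance ratio lambda = sigma_u^2 / sigma_e^2.  Each SNP is then scored
by generalized least squares with the covariance fixed at the null estimate,
giving a Wald two-sided p-value per SNP.

The module also implements the study-specific FDR summary

    FDR = P (1 - A/T) / ((A/T) (1 - P))

with P the nominal threshold, A the number of significant SNPs at P and T
the number tested, and the across-SNP standardization z = a_hat / sd(a_hat)
used by the downstream association weight matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, NumericalError
from .panel import GenotypePanel

__all__ = [
    "filter_snps",
    "compute_grm",
    "grm_eigendecomposition",
    "fit_null_model",
    "NullModelFit",
    "snp_scan",
    "run_gwas",
    "GwasResultSet",
    "fdr",
    "fdr_summary",
    "standardize_effects",
    "covariate_design",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# SNP filtering and GRM
# --------------------------------------------------------------------------

def filter_snps(
    panel: GenotypePanel,
    min_maf: float = 0.05,
    max_missing: float = 0.10,
    mapped: np.ndarray | None = None,
) -> GenotypePanel:
    """Drop SNPs with MAF < ``min_maf``, missing rate > ``max_missing``, or
    (if ``mapped`` is given) no genome-map assignment.

    Both boundaries follow the strict readings: a SNP at exactly the MAF
    threshold or exactly the missingness threshold is kept.
    """
    keep = (panel.maf() >= min_maf) & (panel.missing_rate() <= max_missing)
    if mapped is not None:
        keep &= np.asarray(mapped, dtype=bool)
    if not keep.any():
        raise DataError("SNP filtering removed every SNP")
    return panel.subset_snps(keep)


def compute_grm(panel: GenotypePanel) -> np.ndarray:
    """Genomic relationship matrix with the Yang et al. (2011) diagonal.

    Off-diagonal: G_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k q_k).
    Diagonal:     G_ii = 1 + (1/m) sum_k (x_ik^2 - (1 + 2 p_k) x_ik + 2 p_k^2)
                                          / (2 p_k q_k).

    Missing dosages are mean-imputed per SNP before centring.
    """
    p = panel.allele_frequency()
    if np.any((p <= 0) | (p >= 1)):
        raise NumericalError(
            "monomorphic SNP reached compute_grm; filter_snps must run first"
        )
    x = panel.imputed_dosages()
    m = panel.n_snps
    denom = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(denom)
    g = (w @ w.T) / m
    diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom).sum(axis=1) / m
    np.fill_diagonal(g, diag)
    return g


def grm_eigendecomposition(grm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (clipped at 0) and eigenvectors of a symmetric GRM."""
    d, u = np.linalg.eigh(grm)
    return np.clip(d, 0.0, None), u


# --------------------------------------------------------------------------
# Covariate design
# --------------------------------------------------------------------------

def covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + reference-level dummy coding for sex (2 levels) and batch.

    Any column of ``covariates`` named ``sex`` or ``batch`` is dummy-coded
    dropping the first level; other columns are passed through numerically.
    """
    n = len(covariates)
    cols = [np.ones(n)]
    for name in covariates.columns:
        if name in ("sex", "batch"):
            values = covariates[name].astype("category")
            for level in values.cat.categories[1:]:
                cols.append((values == level).to_numpy(dtype=float))
        else:
            cols.append(covariates[name].to_numpy(dtype=float))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("covariate design matrix is rank deficient")
    return x


# --------------------------------------------------------------------------
# REML null model
# --------------------------------------------------------------------------

@dataclass
class NullModelFit:
    """REML variance components and the spectral cache reused by the scan."""

    sigma_u2: float
    sigma_e2: float
    ratio: float                      # lambda = sigma_u2 / sigma_e2
    loglik: float
    eigvals: np.ndarray               # d, eigenvalues of G
    eigvecs: np.ndarray               # U, columns are eigenvectors
    x_rot: np.ndarray                 # U^T X
    y_rot: np.ndarray                 # U^T y
    at_boundary: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0


def _reml_neg_loglik(log_lam: float, y_rot, x_rot, d) -> float:
    lam = 10.0 ** log_lam
    v = lam * d + 1.0
    n, p = x_rot.shape
    xtvx = x_rot.T @ (x_rot / v[:, None])
    xtvy = x_rot.T @ (y_rot / v)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise NumericalError(f"singular design in REML at lambda={lam}") from exc
    resid = y_rot - x_rot @ beta
    rss = float(resid @ (resid / v))
    if rss <= 0:
        return np.inf
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    return 0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.log(v).sum()
        + logdet_xtvx
        + (n - p)
    )


_LOG_LAM_LO, _LOG_LAM_HI = -8.0, 8.0


def fit_null_model(
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    grm: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullModelFit:
    """REML fit of the polygenic model without a SNP term.

    The restricted likelihood is profiled over beta and sigma_e^2 and
    optimised over log10(lambda) on a coarse grid refined by bounded Brent
    search.  A ratio estimate at the grid boundary is clamped there (the
    corresponding variance component is effectively 0 or the residual is)
    and flagged with a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise DataError("phenotype contains missing values; drop those samples first")
    x = covariates if isinstance(covariates, np.ndarray) else covariate_design(covariates)
    if eig is None:
        eig = grm_eigendecomposition(grm)
    d, u = eig
    y_rot = u.T @ y
    x_rot = u.T @ x

    grid = np.linspace(_LOG_LAM_LO, _LOG_LAM_HI, 33)
    vals = np.array([_reml_neg_loglik(g, y_rot, x_rot, d) for g in grid])
    if not np.isfinite(vals).any():
        raise NumericalError(
            f"REML likelihood not finite anywhere in "
            f"[{_LOG_LAM_LO}, {_LOG_LAM_HI}] (final bracket: full grid)"
        )
    k = int(np.nanargmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(y_rot, x_rot, d),
        method="bounded",
        options={"xatol": 1e-6},
    )
    log_lam = float(res.x)
    at_boundary = False
    if k == 0 and log_lam <= _LOG_LAM_LO + 1e-3:
        log_lam, at_boundary = _LOG_LAM_LO, True
        logger.warning("REML variance ratio clamped at the lower boundary")
    elif k == len(grid) - 1 and log_lam >= _LOG_LAM_HI - 1e-3:
        log_lam, at_boundary = _LOG_LAM_HI, True
        logger.warning("REML variance ratio clamped at the upper boundary")
    lam = 10.0 ** log_lam

    v = lam * d + 1.0
    n, p = x_rot.shape
    xtvx = x_rot.T @ (x_rot / v[:, None])
    beta = np.linalg.solve(xtvx, x_rot.T @ (y_rot / v))
    resid = y_rot - x_rot @ beta
    sigma_e2 = float(resid @ (resid / v)) / (n - p)
    sigma_u2 = lam * sigma_e2
    if at_boundary and log_lam == _LOG_LAM_LO:
        sigma_u2 = 0.0
        lam = 0.0
    return NullModelFit(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        ratio=lam,
        loglik=-float(_reml_neg_loglik(log_lam, y_rot, x_rot, d)),
        eigvals=d,
        eigvecs=u,
        x_rot=x_rot,
        y_rot=y_rot,
        at_boundary=at_boundary,
    )


# --------------------------------------------------------------------------
# Per-SNP scan
# --------------------------------------------------------------------------

def snp_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    null_fit: NullModelFit,
    dosages_rot: np.ndarray | None = None,
) -> pd.DataFrame:
    """GLS allele-substitution effects with covariance fixed from the null.

    Working in the eigenbasis of G, observations are whitened by
    1/sqrt(sigma_u^2 d_i + sigma_e2), covariates are projected out, and each
    (mean-imputed) SNP is tested by a Wald z = a_hat / SE with the variance
    treated as known.  SNPs constant after imputation get NaN results rather
    than raising.

    ``dosages_rot`` may carry a precomputed ``U^T X_g`` (shared across
    phenotypes for one panel) to avoid repeating the rotation.
    """
    y = np.asarray(phenotype, dtype=float)
    u = null_fit.eigvecs
    d = null_fit.eigvals
    w = 1.0 / np.sqrt(null_fit.sigma_u2 * d + null_fit.sigma_e2)

    if dosages_rot is None:
        dosages_rot = u.T @ panel.imputed_dosages()
    g_w = dosages_rot * w[:, None]
    x = covariates if isinstance(covariates, np.ndarray) else covariate_design(covariates)
    x_w = (u.T @ x) * w[:, None]
    y_w = (u.T @ y) * w

    q, _ = np.linalg.qr(x_w)
    y_perp = y_w - q @ (q.T @ y_w)
    g_perp = g_w - q @ (q.T @ g_w)

    gtg = np.einsum("ij,ij->j", g_perp, g_perp)
    constant = gtg <= 1e-12
    gtg_safe = np.where(constant, 1.0, gtg)
    effect = (g_perp.T @ y_perp) / gtg_safe
    se = 1.0 / np.sqrt(gtg_safe)
    z = effect / se
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    pvalues = np.clip(pvalues, np.finfo(float).tiny, 1.0)
    effect[constant] = np.nan
    se[constant] = np.nan
    pvalues[constant] = np.nan
    if constant.any():
        logger.warning("%d SNPs constant after imputation; flagged missing",
                       int(constant.sum()))
    return pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"].to_numpy(),
            "chrom": panel.snp_map["chrom"].to_numpy(),
            "bp": panel.snp_map["bp"].to_numpy(),
            "effect": effect,
            "se": se,
            "p": pvalues,
        }
    )


# --------------------------------------------------------------------------
# Result container, FDR, standardization
# --------------------------------------------------------------------------

@dataclass
class GwasResultSet:
    """Per-SNP, per-phenotype effects, SEs, p-values and variance components."""

    effects: pd.DataFrame            # snps x phenotypes
    se: pd.DataFrame
    pvalues: pd.DataFrame
    snp_map: pd.DataFrame
    varcomps: pd.DataFrame           # phenotype, sigma_u2, sigma_e2, h2
    zscores: pd.DataFrame | None = None
    phenotype_meta: pd.DataFrame | None = field(default=None)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.effects.columns)


def run_gwas(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    grm: np.ndarray | None = None,
    phenotype_meta: pd.DataFrame | None = None,
) -> GwasResultSet:
    """Mixed-model scan of every phenotype column against every panel SNP."""
    if grm is None:
        grm = compute_grm(panel)
    eig = grm_eigendecomposition(grm)
    x = covariate_design(covariates)
    rot = eig[1].T @ panel.imputed_dosages()
    eff, ses, ps, vcs = {}, {}, {}, []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        fit = fit_null_model(y, x, grm, eig=eig)
        res = snp_scan(panel, y, x, fit, dosages_rot=rot)
        eff[name] = res["effect"].to_numpy()
        ses[name] = res["se"].to_numpy()
        ps[name] = res["p"].to_numpy()
        vcs.append((name, fit.sigma_u2, fit.sigma_e2, fit.h2))
    index = pd.Index(panel.snp_map["snp_id"], name="snp_id")
    result = GwasResultSet(
        effects=pd.DataFrame(eff, index=index),
        se=pd.DataFrame(ses, index=index),
        pvalues=pd.DataFrame(ps, index=index),
        snp_map=panel.snp_map.copy(),
        varcomps=pd.DataFrame(
            vcs, columns=["phenotype", "sigma_u2", "sigma_e2", "h2"]
        ),
        phenotype_meta=phenotype_meta,
    )
    return standardize_effects(result)


def fdr(p: float, a: int, t: int) -> float:
    """Study FDR at nominal threshold ``p``: P(1 - A/T) / ((A/T)(1 - P)).

    ``a`` is the number of SNPs significant at ``p`` out of ``t`` tested.
    Returned as a fraction (may exceed 1); multiply by 100 for percent.
    """
    if not 0.0 < p < 1.0:
        raise DataError(f"threshold p={p} must lie in (0, 1)")
    if t <= 0:
        raise DataError(f"total SNP count t={t} must be positive")
    if not 0 <= a <= t:
        raise DataError(f"significant count a={a} must lie in [0, {t}]")
    if a == 0:
        raise DataError("FDR undefined when no SNP is significant (A = 0)")
    frac = a / t
    return p * (1.0 - frac) / (frac * (1.0 - p))


def fdr_summary(
    results: GwasResultSet, thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)
) -> pd.DataFrame:
    """Per-phenotype significant counts and FDR% at each nominal threshold."""
    t = len(results.snp_map)
    rows = []
    for name in results.phenotypes:
        p = results.pvalues[name].dropna()
        row: dict[str, object] = {"phenotype": name}
        for thr in thresholds:
            a = int((p < thr).sum())
            row[f"N_p{thr}"] = a
            row[f"FDR%_p{thr}"] = 100.0 * fdr(thr, a, t) if a > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def standardize_effects(results: GwasResultSet, ddof: int = 1) -> GwasResultSet:
    """z_l = a_hat_l / sd(all a_hat) per phenotype column (sd denominator n-1)."""
    z = {}
    for name in results.phenotypes:
        col = results.effects[name]
        sd = col.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise NumericalError(f"zero effect-sd for phenotype {name}")
        z[name] = col / sd
    results.zscores = pd.DataFrame(z, index=results.effects.index)
    return results
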