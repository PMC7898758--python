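"""Regulatory impact factor (RIF) scoring on a bacteria-vs-protist contrast.

A candidate regulator is any TF- or miRNA-annotated SNP-gene; its potential
targets are the diversity-associated plus pleiotropic AWM rows.  Working in
standardized-SNP-effect space, with the phenotype columns split into a
bacterial group (1) and a protist group (2):

* e1_j, e2_j  — mean |z| of target j over the group-1 / group-2 columns
                (how strongly the target is associated within each group);
* r1_ij, r2_ij — Pearson correlation of regulator i's and target j's row
                vectors restricted to each group's columns (co-association);
* PIF_j = (e1_j + e2_j) / 2 and dCo_ij = r1_ij - r2_ij.

    RIF1_i = (1/n_t) sum_j PIF_j * dCo_ij^2
    RIF2_i = (1/n_t) sum_j [ (e1_j r1_ij)^2 - (e2_j r2_ij)^2 ]

RIF1 rewards regulators whose co-association with strongly associated
targets differs most between the two kingdoms; RIF2 rewards regulators whose
ability to predict target association is most altered between them (and is
antisymmetric under swapping the groups).  Both are z-standardized across
regulators; significance defaults to |z| >= 1.96 on either metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["RifScores", "rif_scores", "select_significant",
           "regulator_correlations"]

logger = logging.getLogger(__name__)


@dataclass
class RifScores:
    """Raw and z-standardized RIF metrics plus all intermediates."""

    scores: pd.DataFrame       # index regulator gene_id: rif1, rif2, rif1_z, rif2_z
    e1: pd.Series              # per target
    e2: pd.Series
    r1: pd.DataFrame           # regulators x targets
    r2: pd.DataFrame
    pif: pd.Series

    def __len__(self) -> int:
        return len(self.scores)


def _row_correlations(a: np.ndarray, b: np.ndarray, label: str) -> np.ndarray:
    """Pearson correlation of every row of ``a`` against every row of ``b``.

    Rows constant across the group get correlation 0 with a warning.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    zero_a = an == 0
    zero_b = bn == 0
    if zero_a.any() or zero_b.any():
        logger.warning(
            "%d constant row(s) within the %s group; correlations set to 0",
            int(zero_a.sum() + zero_b.sum()), label,
        )
    an = np.where(zero_a, 1.0, an)
    bn = np.where(zero_b, 1.0, bn)
    r = (ac / an[:, None]) @ (bc / bn[:, None]).T
    r[zero_a, :] = 0.0
    r[:, zero_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def rif_scores(
    targets: pd.DataFrame,
    regulators: pd.DataFrame,
    group1_cols: list[str],
    group2_cols: list[str],
) -> RifScores:
    """Score each regulator row against the target rows.

    ``targets`` and ``regulators`` are genes x phenotypes frames of
    standardized effects (regulators need not be a subset of targets).
    ``group1_cols`` / ``group2_cols`` are the bacterial / protist phenotype
    columns; each group needs at least 3 columns for the within-group
    correlations to be meaningful.
    """
    if len(group1_cols) < 3 or len(group2_cols) < 3:
        raise DataError("each contrast group needs at least 3 phenotype columns")
    if targets.empty or regulators.empty:
        raise DataError("targets and regulators must be non-empty")

    t1 = targets[group1_cols].to_numpy(dtype=float)
    t2 = targets[group2_cols].to_numpy(dtype=float)
    g1 = regulators[group1_cols].to_numpy(dtype=float)
    g2 = regulators[group2_cols].to_numpy(dtype=float)

    e1 = np.abs(t1).mean(axis=1)
    e2 = np.abs(t2).mean(axis=1)
    pif = 0.5 * (e1 + e2)

    r1 = _row_correlations(g1, t1, "group-1")
    r2 = _row_correlations(g2, t2, "group-2")
    dco = r1 - r2

    rif1 = (pif[None, :] * dco**2).mean(axis=1)
    rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    scores = pd.DataFrame(
        {
            "rif1": rif1,
            "rif2": rif2,
            "rif1_z": _z(rif1),
            "rif2_z": _z(rif2),
        },
        index=pd.Index(regulators.index, name="gene_id"),
    )
    return RifScores(
        scores=scores,
        e1=pd.Series(e1, index=targets.index),
        e2=pd.Series(e2, index=targets.index),
        r1=pd.DataFrame(r1, index=regulators.index, columns=targets.index),
        r2=pd.DataFrame(r2, index=regulators.index, columns=targets.index),
        pif=pd.Series(pif, index=targets.index),
    )


def select_significant(rif: RifScores, z_cut: float = 1.96) -> pd.DataFrame:
    """Regulators with |RIF1 z| >= z_cut OR |RIF2 z| >= z_cut."""
    s = rif.scores
    mask = (s["rif1_z"].abs() >= z_cut) | (s["rif2_z"].abs() >= z_cut)
    out = s.loc[mask].reset_index()
    return out


def regulator_correlations(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson (r, p) among the regulator-table analytics columns.

    Expects columns ``rif1``, ``rif2``, ``pleiotropy``, ``connections`` and
    reports the four pairings used to summarize a regulator table:
    pleiotropy-connections, rif1-rif2, rif2-pleiotropy, rif2-connections.
    """
    pairs = {
        "pleiotropy_connections": ("pleiotropy", "connections"),
        "rif1_rif2": ("rif1", "rif2"),
        "rif2_pleiotropy": ("rif2", "pleiotropy"),
        "rif2_connections": ("rif2", "connections"),
    }
    out = {}
    for name, (a, b) in pairs.items():
        r, p = stats.pearsonr(table[a], table[b])
        out[name] = (float(r), float(p))
    return out
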