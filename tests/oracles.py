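"""Independent brute-force reference implementations used only by tests.

These deliberately mirror nothing of the package's vectorised code paths:
plain Python loops over the mathematical definitions.
"""

from __future__ import annotations

import numpy as np


def naive_pcit_edges(r: np.ndarray) -> set[tuple[int, int]]:
    """All-trios PCIT by the book: O(n^3) python loops, no vectorisation."""
    n = r.shape[0]
    clamp = 1.0 - 1e-12

    def partial(ab: float, ac: float, bc: float) -> float:
        return (ab - ac * bc) / np.sqrt(
            (1 - min(ac * ac, clamp)) * (1 - min(bc * bc, clamp))
        )

    elim = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy, rxz, ryz = r[x, y], r[x, z], r[y, z]
                pxy = partial(rxy, rxz, ryz)
                pxz = partial(rxz, rxy, ryz)
                pyz = partial(ryz, rxy, rxz)
                ratios = []
                if abs(rxy) > 0:
                    ratios.append(abs(pxy / rxy))
                if abs(rxz) > 0:
                    ratios.append(abs(pxz / rxz))
                if abs(ryz) > 0:
                    ratios.append(abs(pyz / ryz))
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(rxy) <= eps * abs(rxz) and abs(rxy) <= eps * abs(ryz):
                    elim[x, y] = elim[y, x] = True
                    break
    return {
        (x, y)
        for x in range(n)
        for y in range(x + 1, n)
        if r[x, y] != 0 and not elim[x, y]
    }


def sliding_window_count(seq: str, word: str) -> int:
    """Overlapping substring occurrences by exhaustive window comparison."""
    w = len(word)
    return sum(1 for i in range(len(seq) - w + 1) if seq[i : i + w] == word)


def ols_slope_after_covariates(y: np.ndarray, g: np.ndarray,
                               x: np.ndarray) -> np.ndarray:
    """Per-column OLS slope of y on g after projecting out covariates x."""
    q, _ = np.linalg.qr(x)
    yp = y - q @ (q.T @ y)
    gp = g - q @ (q.T @ g)
    return (gp * yp[:, None]).sum(axis=0) / (gp * gp).sum(axis=0)


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))
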