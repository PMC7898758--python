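"""PCIT co-association network inference and network analytics.

PCIT (partial correlation and information theory) keeps a correlation
between two loci only if no third locus explains it.  For every trio
(x, y, z) the three first-order partials are computed, e.g.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

and the trio's data-driven tolerance is the average ratio of partial to
direct correlation over the ratios that are defined (nonzero direct):

    eps_xyz = mean(|r_xy.z / r_xy|, |r_xz.y / r_xz|, |r_yz.x / r_yz|).

The edge (x, y) is eliminated if some z satisfies both
|r_xy| <= eps_xyz |r_xz| and |r_xy| <= eps_xyz |r_yz|.  No hard threshold is
placed on the correlation strength.  The survivors form a signed weighted
graph whose nodes are AWM gene rows and whose weights are the direct
correlations of standardized-effect row vectors.

The z-loop implementation is vectorised and chunked for memory but is
exact — it must agree with a naive all-trios reference on every instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "row_correlations",
    "pcit",
    "CoAssociationNetwork",
    "network_stats",
    "extract_regulator_subnetwork",
    "write_edge_list",
    "write_sif",
    "write_graphml",
]

_CLAMP = 1.0 - 1e-12


def row_correlations(entries: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of gene rows (across columns)."""
    if entries.shape[1] < 3:
        raise DataError("row correlations need at least 3 phenotype columns")
    mat = entries.to_numpy(dtype=float)
    sds = mat.std(axis=1)
    if (sds == 0).any():
        bad = entries.index[sds == 0][0]
        raise DataError(f"gene row {bad} is constant across phenotypes")
    corr = np.corrcoef(mat)
    return pd.DataFrame(corr, index=entries.index, columns=entries.index)


@dataclass
class CoAssociationNetwork:
    """Signed weighted graph over AWM rows retained by PCIT."""

    graph: nx.Graph
    nodes: list[str]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sign_counts(self) -> tuple[int, int]:
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["weight"] > 0)
        return pos, self.n_edges - pos

    def degree(self) -> pd.Series:
        return pd.Series(
            {n: d for n, d in self.graph.degree()}, name="connections"
        ).reindex(self.nodes, fill_value=0)


def pcit(corr: pd.DataFrame | np.ndarray, chunk: int = 32) -> CoAssociationNetwork:
    """Run PCIT on a symmetric unit-diagonal correlation matrix.

    With fewer than 3 nodes every nonzero correlation survives (no trio
    exists).  ``chunk`` bounds how many third-node slices are processed per
    vectorised pass; results are independent of it.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.index)
        r = corr.to_numpy(dtype=float)
    else:
        r = np.asarray(corr, dtype=float)
        names = [f"N{i}" for i in range(r.shape[0])]
    n = r.shape[0]
    if r.shape != (n, n) or not np.allclose(r, r.T, atol=1e-10):
        raise DataError("PCIT needs a symmetric correlation matrix")
    if not np.allclose(np.diag(r), 1.0, atol=1e-8):
        raise DataError("PCIT needs a unit-diagonal correlation matrix")

    eliminated = np.zeros((n, n), dtype=bool)
    if n >= 3:
        eye = np.eye(n, dtype=bool)
        a = np.abs(r)
        # cap the chunk so each working buffer stays modest, and allocate
        # the buffers once — the loop then runs entirely in place
        width = max(1, min(max(chunk, 1), max(1, int(8_000_000 // (n * n)))))
        shape = (n, n, width)
        bp1, bp2, bp3 = (np.empty(shape) for _ in range(3))
        bt1, bt2, beps, bcnt = (np.empty(shape) for _ in range(4))
        bc1, bc2 = (np.empty(shape, dtype=bool) for _ in range(2))

        for z0 in range(0, n, width):
            hi = min(z0 + width, n)
            w = hi - z0
            p1, p2, p3 = bp1[..., :w], bp2[..., :w], bp3[..., :w]
            t1, t2 = bt1[..., :w], bt2[..., :w]
            eps, cnt = beps[..., :w], bcnt[..., :w]
            cond, scratch = bc1[..., :w], bc2[..., :w]

            r_xy = r[:, :, None]                 # (x, y, 1)
            r_xz = r[:, z0:hi][:, None, :]       # (x, 1, z)
            r_yz = r[:, z0:hi][None, :, :]       # (1, y, z)
            a_xy = a[:, :, None]
            a_xz = a[:, z0:hi][:, None, :]
            a_yz = a[:, z0:hi][None, :, :]

            def partial(out, r_ab, r_ac, r_bc):
                np.multiply(r_ac, r_bc, out=t1)
                np.subtract(r_ab, t1, out=out)
                np.multiply(r_ac, r_ac, out=t1)
                np.minimum(t1, _CLAMP, out=t1)
                np.subtract(1.0, t1, out=t1)
                np.multiply(r_bc, r_bc, out=t2)
                np.minimum(t2, _CLAMP, out=t2)
                np.subtract(1.0, t2, out=t2)
                np.multiply(t1, t2, out=t1)
                np.sqrt(t1, out=t1)
                np.divide(out, t1, out=out)

            partial(p1, r_xy, r_xz, r_yz)
            partial(p2, r_xz, r_xy, r_yz)
            partial(p3, r_yz, r_xy, r_xz)

            # eps = mean of |partial/direct| over the defined ratios
            eps[...] = 0.0
            cnt[...] = 0.0
            for p, direct in ((p1, a_xy), (p2, a_xz), (p3, a_yz)):
                np.greater(direct, 0.0, out=scratch)
                np.abs(p, out=p)
                np.divide(p, direct, out=p, where=scratch)
                np.add(eps, p, out=eps, where=scratch)
                np.add(cnt, 1.0, out=cnt, where=scratch)
            np.greater(cnt, 0.0, out=scratch)
            np.divide(eps, cnt, out=eps, where=scratch)

            # eliminate (x, y) when |r_xy| <= eps|r_xz| and <= eps|r_yz|
            np.multiply(eps, a_xz, out=t1)
            np.multiply(eps, a_yz, out=t2)
            np.less_equal(a_xy, t1, out=cond)
            np.logical_and(cond, scratch, out=cond)   # trio must be defined
            np.less_equal(a_xy, t2, out=scratch)
            np.logical_and(cond, scratch, out=cond)
            # exclude degenerate trios: z == x, z == y, x == y
            for k, z in enumerate(range(z0, hi)):
                cond[z, :, k] = False
                cond[:, z, k] = False
            cond[eye, :] = False
            eliminated |= cond.any(axis=2)

    keep = (~eliminated) & (~eliminated.T)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        w = r[i, j]
        if w != 0 and keep[i, j]:
            graph.add_edge(names[i], names[j], weight=float(w),
                           sign=1 if w > 0 else -1)
    return CoAssociationNetwork(graph=graph, nodes=names)


def network_stats(
    net: CoAssociationNetwork,
    awm_entries: pd.DataFrame,
    rows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-node degree and strongest-association phenotype.

    ``awm_entries`` is the genes x phenotypes z matrix the network was built
    from; the strongest association of a node is the column of maximal |z|.
    If ``rows`` (AWM metadata with ``pleiotropy``) is given it is joined in.
    """
    degree = net.degree()
    strongest = awm_entries.abs().idxmax(axis=1).reindex(net.nodes)
    out = pd.DataFrame(
        {"gene_id": net.nodes,
         "connections": degree.to_numpy(),
         "top_association": strongest.to_numpy()}
    )
    if rows is not None:
        out = out.merge(
            rows[["gene_id", "cls", "pleiotropy"]], on="gene_id", how="left"
        )
    return out


def extract_regulator_subnetwork(
    net: CoAssociationNetwork,
    regulators: list[str],
    min_abs_r: float = 0.7,
) -> nx.Graph:
    """Regulators plus first neighbors connected by |r| > ``min_abs_r``.

    Node attributes of the parent graph are preserved; unknown regulator ids
    raise.
    """
    unknown = [g for g in regulators if g not in net.graph]
    if unknown:
        raise DataError(f"unknown regulator node(s): {unknown[:5]}")
    keep = set(regulators)
    for reg in regulators:
        for nb in net.graph[reg]:
            if abs(net.graph[reg][nb]["weight"]) > min_abs_r:
                keep.add(nb)
    return net.graph.subgraph(keep).copy()


# --------------------------------------------------------------------------
# exports
# --------------------------------------------------------------------------

def write_edge_list(net: CoAssociationNetwork, path: str) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "r": d["weight"], "sign": d["sign"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(net: CoAssociationNetwork, path: str) -> None:
    with open(path, "w") as fh:
        for a, b, d in net.graph.edges(data=True):
            rel = "pos" if d["weight"] > 0 else "neg"
            fh.write(f"{a}\t{rel}\t{b}\n")


def write_graphml(net: CoAssociationNetwork, path: str) -> None:
    nx.write_graphml(net.graph, path)
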