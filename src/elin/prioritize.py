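"""PageRank prioritization of nodes in the full heterogeneous network.

The walk runs on the symmetrized, by default unweighted adjacency of the whole
multilayer graph with uniform teleportation: a node is important when many
important genes/bioprocesses/diseases attach to it, which favours high-degree
hubs while keeping low-degree nodes that sit next to important neighbours.
Isolated nodes (e.g. denoised non-human genes that enrichment never
re-connected) receive teleport-only mass and therefore rank at the floor
(1 - damping)/N rather than at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import Layer, MultilayerGraph

__all__ = ["PageRankParams", "RankResult", "pagerank", "rank_table", "top_genes"]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""


@dataclass(frozen=True)
class PageRankParams:
    """damping: probability of following an edge instead of teleporting;
    tol: L1 convergence threshold between iterates; max_iter: iteration cap."""

    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    use_weights: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")


@dataclass(frozen=True)
class RankResult:
    node_id: str
    label: str
    layer: Layer
    score: float
    overall_rank: int
    layer_rank: int


def pagerank(
    graph: MultilayerGraph, params: PageRankParams = PageRankParams()
) -> dict[str, float]:
    """Power iteration on the symmetrized adjacency; returns node_id -> score.

    Parallel edges between a pair (differing provenance) count once in the
    unweighted walk; with ``use_weights`` the transition probability is
    proportional to summed edge weight.
    """
    nodes = sorted(graph.g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank needs a non-empty graph")
    index = {v: i for i, v in enumerate(nodes)}

    rows, cols, vals = [], [], []
    seen: dict[tuple[int, int], float] = {}
    for u, v, d in graph.g.edges(data=True):
        i, j = index[u], index[v]
        key = (min(i, j), max(i, j))
        if params.use_weights:
            seen[key] = seen.get(key, 0.0) + float(d["weight"])
        else:
            seen[key] = 1.0
    for (i, j), w in seen.items():
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    degree = np.asarray(adj.sum(axis=1)).ravel()
    dangling = degree == 0
    inv_deg = np.divide(1.0, degree, out=np.zeros_like(degree), where=~dangling)
    # column-stochastic transition: M[i, j] = adj[j, i] / degree[j]
    transition = adj.multiply(inv_deg[:, None]).T.tocsr()

    d = params.damping
    x = np.full(n, 1.0 / n)
    for _ in range(params.max_iter):
        new = d * (transition @ x + x[dangling].sum() / n) + (1 - d) / n
        residual = float(np.abs(new - x).sum())
        x = new
        if residual < params.tol:
            return dict(zip(nodes, x.tolist()))
    raise ConvergenceError(
        f"pagerank did not converge in {params.max_iter} iterations (residual {residual:.3e})"
    )


def rank_table(scores: dict[str, float], graph: MultilayerGraph) -> list[RankResult]:
    """All nodes sorted by score descending, node id ascending on ties, with
    overall and within-layer rank positions."""
    nodes = graph.g.nodes
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    layer_counter: dict[str, int] = {}
    out = []
    for overall, (nid, score) in enumerate(ordered, start=1):
        layer = nodes[nid]["layer"]
        layer_counter[layer] = layer_counter.get(layer, 0) + 1
        out.append(
            RankResult(
                node_id=nid,
                label=nodes[nid]["label"],
                layer=Layer(layer),
                score=score,
                overall_rank=overall,
                layer_rank=layer_counter[layer],
            )
        )
    return out


def top_genes(
    scores: dict[str, float], graph: MultilayerGraph, k: int = 50
) -> list[tuple[str, float]]:
    """Top-k gene/protein nodes by score (ties broken by node id ascending);
    fewer than k when the gene layer is smaller."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = [r for r in rank_table(scores, graph) if r.layer is Layer.GENE_PROTEIN]
    return [(r.node_id, r.score) for r in genes[:k]]
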