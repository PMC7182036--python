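"""Infer cross-layer edges from shared-gene overlap.

Two nodes in different layers (e.g. a bioprocess and a disease) are linked
when the gene sets annotated to them overlap more than chance would allow:
for profiles of sizes ``|A|`` and ``|B|`` drawn from a background universe of
``N`` genes, the overlap ``k`` is scored with the hypergeometric upper tail
``P(X >= k)``; p-values are Benjamini-Hochberg adjusted across all candidate
pairs of the layer pair, and pairs with ``q <= alpha`` become undirected
INFERRED edges weighted by the Jaccard similarity of the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import Layer, MultilayerGraph, Provenance

__all__ = [
    "InferredEdge",
    "gene_profile",
    "overlap_pvalue",
    "benjamini_hochberg",
    "infer_edges",
]


@dataclass(frozen=True)
class InferredEdge:
    """A candidate cross-layer edge that passed the overlap test."""

    a_id: str
    b_id: str
    shared_genes: frozenset[str]
    jaccard: float
    p_value: float
    q_value: float

    @property
    def k(self) -> int:
        return len(self.shared_genes)


def gene_profile(graph: MultilayerGraph, node_id: str) -> frozenset[str]:
    """Gene symbols attached to a node.

    For ordinary nodes: the uppercase labels of all gene/protein neighbours,
    whatever the connecting edge's provenance.  For immune-endpoint nodes,
    which have no direct gene edges, the union of the profiles of the
    bioprocess terms mapped onto them.
    """
    if node_id not in graph.g:
        raise KeyError(f"unknown node {node_id!r}")
    nodes = graph.g.nodes
    if nodes[node_id]["layer"] == Layer.IMMUNE_ENDPOINT.value:
        terms = {
            nbr
            for _, nbr, key in graph.g.edges(node_id, keys=True)
            if key == Provenance.ENDPOINT_MAPPING.value
        }
        out: set[str] = set()
        for t in terms:
            out |= gene_profile(graph, t)
        return frozenset(out)
    return frozenset(
        nodes[nbr]["label"].upper()
        for nbr in graph.g.neighbors(node_id)
        if nodes[nbr]["layer"] == Layer.GENE_PROTEIN.value
    )


def overlap_pvalue(k: int, size_a: int, size_b: int, background_n: int) -> float:
    """Hypergeometric upper-tail probability P(X >= k) for an overlap of k
    between gene sets of sizes ``size_a`` and ``size_b`` drawn from a
    background of ``background_n`` genes."""
    return float(hypergeom.sf(k - 1, background_n, size_a, size_b))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def infer_edges(
    graph: MultilayerGraph,
    layer_a: Layer,
    layer_b: Layer,
    background_n: int,
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> list[InferredEdge]:
    """Test every (layer_a, layer_b) node pair sharing >= min_overlap genes.

    Significant pairs (BH q <= alpha, adjusted across all tested pairs of
    this layer pair) are added to the graph in place as undirected INFERRED
    edges with weight = Jaccard, and returned sorted by (q, p, a_id, b_id).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    profiles_a = {n: gene_profile(graph, n) for n in graph.nodes_in_layer(layer_a)}
    profiles_b = {n: gene_profile(graph, n) for n in graph.nodes_in_layer(layer_b)}
    for n, prof in {**profiles_a, **profiles_b}.items():
        if len(prof) > background_n:
            raise ValueError(
                f"background_n={background_n} smaller than the gene profile of {n} ({len(prof)})"
            )

    tested: list[tuple[str, str, frozenset[str], float, float]] = []
    for a, pa in profiles_a.items():
        if not pa:
            continue
        for b, pb in profiles_b.items():
            shared = pa & pb
            if len(shared) < min_overlap:
                continue
            union = len(pa | pb)
            if union > background_n:
                raise ValueError(
                    f"background_n={background_n} smaller than the profile union of "
                    f"({a}, {b}) ({union})"
                )
            p = overlap_pvalue(len(shared), len(pa), len(pb), background_n)
            tested.append((a, b, shared, len(shared) / union, p))

    if not tested:
        return []
    q = benjamini_hochberg(np.array([t[4] for t in tested]))
    edges = [
        InferredEdge(a_id=a, b_id=b, shared_genes=shared, jaccard=jac, p_value=p, q_value=qv)
        for (a, b, shared, jac, p), qv in zip(tested, q)
        if qv <= alpha
    ]
    edges.sort(key=lambda e: (e.q_value, e.p_value, e.a_id, e.b_id))
    for e in edges:
        if not graph.g.has_edge(e.a_id, e.b_id, key=Provenance.INFERRED.value):
            graph.add_edge(e.a_id, e.b_id, Provenance.INFERRED, weight=max(e.jaccard, 1e-12))
    graph.log(
        "infer",
        layers=f"{layer_a.value}-{layer_b.value}",
        n_tested=len(tested),
        n_significant=len(edges),
    )
    return edges
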