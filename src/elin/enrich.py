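"""Attach gene->GO, gene->GO-slim, gene->disease and bioprocess->endpoint edges.

Enrichment is an annotation join, restricted to genes already present in the
period network: for every annotation row whose gene symbol matches a human
gene node, the term node is added (if absent) together with an undirected
enrichment edge of weight 1.  Endpoint-map rows connect bioprocess terms that
made it into the graph to the four fixed immune-health endpoints; terms absent
from the graph contribute nothing, so no endpoint hangs off a term without
gene support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import IMMUNE_ENDPOINTS, Layer, MultilayerGraph, Provenance
from .ingest import AnnotationTable

__all__ = ["EnrichmentSummary", "enrich_graph"]

log = logging.getLogger(__name__)

_SOURCE_LAYER = {
    "GO": Layer.GO_PROCESS,
    "GOSLIM": Layer.GOSLIM_PROCESS,
    "DISEASE": Layer.DISEASE,
}
_SOURCE_PROVENANCE = {
    "GO": Provenance.GO_ENRICHMENT,
    "GOSLIM": Provenance.GOSLIM_ENRICHMENT,
    "DISEASE": Provenance.DISEASE_ENRICHMENT,
}


@dataclass
class EnrichmentSummary:
    """Added-node and added-edge counts per annotation source."""

    added_nodes: dict[str, int] = field(default_factory=dict)
    added_edges: dict[str, int] = field(default_factory=dict)

    def record(self, source: str, nodes: int, edges: int) -> None:
        self.added_nodes[source] = nodes
        self.added_edges[source] = edges


def _gene_index(graph: MultilayerGraph) -> dict[str, str]:
    """Uppercase human gene symbol -> node id."""
    return {
        d["label"].upper(): n
        for n, d in graph.g.nodes(data=True)
        if d["layer"] == Layer.GENE_PROTEIN.value and d["is_human_gene"]
    }


def enrich_graph(
    graph: MultilayerGraph,
    annotations: list[AnnotationTable],
    min_score: float | None = None,
) -> tuple[MultilayerGraph, EnrichmentSummary]:
    """Join annotation tables onto the graph's gene layer.

    ENDPOINT_MAP tables are applied after all gene->term sources so that
    endpoint edges only attach to term nodes present in the enriched graph.
    ``min_score`` optionally filters DISEASE rows on a numeric ``score``
    column when one is present (off by default).
    """
    out = graph.copy()
    summary = EnrichmentSummary()
    for tab in annotations:
        if tab.source not in _SOURCE_LAYER and tab.source != "ENDPOINT_MAP":
            raise ValueError(f"unknown annotation source {tab.source!r}")

    genes = _gene_index(out)
    for tab in sorted(
        (t for t in annotations if t.source != "ENDPOINT_MAP"), key=lambda t: t.source
    ):
        layer = _SOURCE_LAYER[tab.source]
        prov = _SOURCE_PROVENANCE[tab.source]
        df = tab.df
        if tab.source == "DISEASE" and min_score is not None and "score" in df.columns:
            df = df[df["score"].astype(float) >= min_score]
        n_nodes = n_edges = 0
        # sort for row-order independence
        for row in df.sort_values(["gene", "term_id"]).itertuples(index=False):
            nid = genes.get(row.gene)
            if nid is None:
                continue
            if row.term_id not in out.g:
                out.add_entity(row.term_id, row.term_name, layer)
                n_nodes += 1
            if not out.g.has_edge(nid, row.term_id, key=prov.value):
                out.add_edge(nid, row.term_id, prov, weight=1.0)
                n_edges += 1
        summary.record(tab.source, n_nodes, n_edges)

    for tab in (t for t in annotations if t.source == "ENDPOINT_MAP"):
        n_nodes = n_edges = 0
        for row in tab.df.sort_values(["term_id", "endpoint"]).itertuples(index=False):
            if row.term_id not in out.g:
                continue
            if row.endpoint not in IMMUNE_ENDPOINTS:
                log.warning("ignoring unknown endpoint %r", row.endpoint)
                continue
            eid = f"ENDPOINT:{row.endpoint.upper().replace(' ', '_')}"
            if eid not in out.g:
                out.add_entity(eid, row.endpoint, Layer.IMMUNE_ENDPOINT)
                n_nodes += 1
            if not out.g.has_edge(row.term_id, eid, key=Provenance.ENDPOINT_MAPPING.value):
                out.add_edge(row.term_id, eid, Provenance.ENDPOINT_MAPPING, weight=1.0)
                n_edges += 1
        summary.record("ENDPOINT_MAP", n_nodes, n_edges)

    out.log(
        "enrich",
        added_nodes=dict(summary.added_nodes),
        added_edges=dict(summary.added_edges),
    )
    return out, summary
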