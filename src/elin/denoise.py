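"""Denoise literature gene-gene edges against a reference association table.

A literature edge between two gene/protein nodes is kept only when its
unordered symbol pair appears in the reference human association table (any
network type); kept edges are re-tagged REFERENCE_CONFIRMED.  Gene-gene edges
touching a non-human gene node can never be confirmed and are always removed.
Nodes are never removed: unsupported genes stay in the network as disconnected
nodes so later enrichment can re-connect them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import Layer, MultilayerGraph, Period, Provenance
from .ingest import ReferenceEdgeTable

__all__ = ["DenoiseReport", "denoise_graph", "confirmation_table", "pct_half_up"]

log = logging.getLogger(__name__)


def pct_half_up(numerator: int, denominator: int) -> int:
    """Integer percentage with half-up rounding; 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DenoiseReport:
    """Confirmation statistics for one period network."""

    period: Period
    n_genes: int
    n_literature_gene_edges: int
    n_confirmed: int

    @property
    def pct_confirmed(self) -> int:
        return pct_half_up(self.n_confirmed, self.n_literature_gene_edges)


def denoise_graph(
    graph: MultilayerGraph, ref: ReferenceEdgeTable
) -> tuple[MultilayerGraph, DenoiseReport]:
    """Filter gene-gene literature edges by reference membership.

    Returns a new graph (input untouched) with the same node set; confirmed
    gene-gene edges are re-tagged REFERENCE_CONFIRMED, unconfirmed ones are
    dropped.  Edges with at least one non-gene endpoint pass through unchanged.
    """
    if len(ref) == 0:
        log.warning("empty reference table: all gene-gene literature edges will be removed")
    out = graph.copy()
    gene_layer = Layer.GENE_PROTEIN.value
    nodes = out.g.nodes

    def is_gene(n: str) -> bool:
        return nodes[n]["layer"] == gene_layer

    candidates = [
        (u, v, d)
        for u, v, k, d in out.g.edges(keys=True, data=True)
        if k == Provenance.LITERATURE.value and is_gene(u) and is_gene(v)
    ]
    n_confirmed = 0
    for u, v, d in candidates:
        human = nodes[u]["is_human_gene"] and nodes[v]["is_human_gene"]
        confirmed = human and (nodes[u]["label"], nodes[v]["label"]) in ref
        out.g.remove_edge(u, v, key=Provenance.LITERATURE.value)
        if confirmed:
            n_confirmed += 1
            out.add_edge(
                u,
                v,
                Provenance.REFERENCE_CONFIRMED,
                weight=d["weight"],
                evidence_count=d["evidence_count"],
                directed=d["directed"],
            )
    report = DenoiseReport(
        period=out.period,
        n_genes=sum(1 for n in nodes if is_gene(n)),
        n_literature_gene_edges=len(candidates),
        n_confirmed=n_confirmed,
    )
    out.log(
        "denoise",
        n_gene_edges=report.n_literature_gene_edges,
        n_confirmed=report.n_confirmed,
        pct_confirmed=report.pct_confirmed,
    )
    return out, report


def confirmation_table(reports: list[DenoiseReport]) -> pd.DataFrame:
    """Render confirmation statistics as one row per period:
    (period, n_genes, n_edges, confirmed) with confirmed formatted
    ``"<n> (<pct>%)"``."""
    periods = [r.period for r in reports]
    if len(set(periods)) != len(periods):
        raise ValueError("duplicate period in denoise reports")
    rows = [
        {
            "period": r.period.name,
            "n_genes": r.n_genes,
            "n_edges": r.n_literature_gene_edges,
            "confirmed": f"{r.n_confirmed} ({r.pct_confirmed}%)",
        }
        for r in sorted(reports, key=lambda r: list(Period).index(r.period))
    ]
    return pd.DataFrame(rows, columns=["period", "n_genes", "n_edges", "confirmed"])
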