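"""Shared fixtures: small hand-built graphs, tables and a synthetic bundle."""

from __future__ import annotations

import pandas as pd
import pytest

from elin import (
    Layer,
    MultilayerGraph,
    Period,
    Provenance,
    ReferenceEdgeTable,
    SynthConfig,
    generate_bundle,
)
from elin.ingest import AnnotationTable


def make_graph(period=Period.NEWBORN) -> MultilayerGraph:
    return MultilayerGraph(period)


def add_gene(graph: MultilayerGraph, symbol: str, human: bool = True, hgnc: str | None = None) -> str:
    nid = f"HGNC:{hgnc or symbol}" if human else f"TEXT:{symbol.upper()}"
    graph.add_entity(nid, symbol, Layer.GENE_PROTEIN, is_human_gene=human)
    return nid


def ref_table(pairs: list[tuple[str, str]], network_type: str = "physical") -> ReferenceEdgeTable:
    df = pd.DataFrame(
        [
            {"gene_a": min(a, b).upper(), "gene_b": max(a, b).upper(), "network_type": network_type, "weight": 0.5}
            for a, b in pairs
        ],
        columns=["gene_a", "gene_b", "network_type", "weight"],
    )
    return ReferenceEdgeTable(df=df)


def annotation(source: str, rows: list[tuple]) -> AnnotationTable:
    if source == "ENDPOINT_MAP":
        df = pd.DataFrame(rows, columns=["term_id", "endpoint"])
    else:
        df = pd.DataFrame(rows, columns=["gene", "term_id", "term_name"])
    return AnnotationTable(source=source, df=df)


#: small generator config used across tests (fast; full default stays in the
#: acceptance suite)
SMALL_SYNTH = dict(
    n_genes=60, n_hubs=4, n_processes=16, n_diseases=10,
    statements_per_period=120, n_nonhuman=2, seed=7,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(SynthConfig(**SMALL_SYNTH), out)
    return out, truth
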