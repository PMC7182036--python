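"""Shared domain model: periods, layers, entities, edges and the multilayer graph.

The networks built here are heterogeneous multilayer graphs: nodes are typed
into eight layers (genes/proteins, protein families, chemicals, text-mined
bioprocesses, GO and GO-slim processes, diseases and four fixed immune-health
endpoints), and edges carry a provenance tag recording which pipeline stage
introduced them (literature assembly, reference confirmation, annotation
enrichment, endpoint mapping or gene-overlap inference).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Period",
    "Layer",
    "Provenance",
    "Entity",
    "MultilayerGraph",
    "IMMUNE_ENDPOINTS",
    "GROUNDING_PRECEDENCE",
    "canonical_id",
    "assign_layer",
    "InvalidEntityError",
]


class InvalidEntityError(ValueError):
    """Raised for an entity with neither a name nor any grounding."""


class Period(enum.Enum):
    """Early-life time periods, ordered from early gestation to infancy.

    The value is the human developmental window: the three gestational
    trimesters by gestational day/week, then birth, newborn (0-28 days) and
    infant (1-23 months).
    """

    EG = "GD0–GW12"
    MG = "GW13–28"
    LG = "GW29–40"
    BIRTH = ""
    NEWBORN = "0–28 days"
    INFANT = "1–23 months"

    @property
    def human_window(self) -> str:
        return self.value

    def __lt__(self, other: "Period") -> bool:
        order = list(Period)
        return order.index(self) < order.index(other)

    @classmethod
    def gestational(cls) -> tuple["Period", "Period", "Period"]:
        return (cls.EG, cls.MG, cls.LG)


class Layer(str, enum.Enum):
    """Node layers of the multilayer immune network."""

    GENE_PROTEIN = "GENE_PROTEIN"
    PROTEIN_FAMILY = "PROTEIN_FAMILY"
    CHEMICAL = "CHEMICAL"
    INDRA_BIOPROCESS = "INDRA_BIOPROCESS"
    GO_PROCESS = "GO_PROCESS"
    GOSLIM_PROCESS = "GOSLIM_PROCESS"
    DISEASE = "DISEASE"
    IMMUNE_ENDPOINT = "IMMUNE_ENDPOINT"


class Provenance(str, enum.Enum):
    """Which pipeline stage introduced an edge."""

    LITERATURE = "LITERATURE"
    REFERENCE_CONFIRMED = "REFERENCE_CONFIRMED"
    GO_ENRICHMENT = "GO_ENRICHMENT"
    GOSLIM_ENRICHMENT = "GOSLIM_ENRICHMENT"
    DISEASE_ENRICHMENT = "DISEASE_ENRICHMENT"
    ENDPOINT_MAPPING = "ENDPOINT_MAPPING"
    INFERRED = "INFERRED"


def _load_endpoints() -> tuple[str, ...]:
    text = resources.files("elin.data").joinpath("immune_endpoints.txt").read_text("utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


#: The four fixed immune-health endpoints forming the network's top layer.
IMMUNE_ENDPOINTS: tuple[str, ...] = _load_endpoints()

#: Namespace precedence used when an entity carries conflicting groundings.
GROUNDING_PRECEDENCE: tuple[str, ...] = ("HGNC", "FPLX", "CHEBI", "GO", "MESH", "DOID", "UMLS")

_DISEASE_NAMESPACES = frozenset({"MESH", "DOID", "UMLS"})

_NAMESPACE_LAYER: dict[str, Layer] = {
    "HGNC": Layer.GENE_PROTEIN,
    "FPLX": Layer.PROTEIN_FAMILY,
    "CHEBI": Layer.CHEMICAL,
    "GO": Layer.GO_PROCESS,
    "MESH": Layer.DISEASE,
    "DOID": Layer.DISEASE,
    "UMLS": Layer.DISEASE,
}


@dataclass(frozen=True)
class Entity:
    """A grounded biological node.

    Parameters
    ----------
    name:
        Display label as it appeared in text (e.g. a gene symbol).
    groundings:
        Mapping namespace -> identifier (HGNC, FPLX, CHEBI, GO, MESH/DOID/UMLS).
        ``TEXT`` entries are ignored for grounding purposes.
    kind_hint:
        Optional hint from the statement source for ungrounded entities:
        ``"bioprocess"`` routes to the text-mined bioprocess layer, anything
        else (or ``None``) is treated as a gene-like symbol.
    """

    name: str
    groundings: Mapping[str, str] = field(default_factory=dict)
    kind_hint: str | None = None

    def __post_init__(self) -> None:
        if not self.name and not self.groundings:
            raise InvalidEntityError("entity needs a name or at least one grounding")
        object.__setattr__(self, "groundings", dict(self.groundings))

    @property
    def is_human_gene(self) -> bool:
        return "HGNC" in self.groundings

    @property
    def layer(self) -> Layer:
        return assign_layer(self)

    @property
    def id(self) -> str:
        return canonical_id(self)


def canonical_id(entity: Entity) -> str:
    """Canonical node id ``NAMESPACE:identifier`` from the highest-precedence
    grounding, falling back to ``TEXT:<UPPERCASED NAME>`` for ungrounded
    entities so that case variants of the same surface form merge.
    """
    if not entity.name and not entity.groundings:
        raise InvalidEntityError("entity needs a name or at least one grounding")
    for ns in GROUNDING_PRECEDENCE:
        if ns in entity.groundings:
            ident = entity.groundings[ns]
            # GO/DOID identifiers conventionally already carry their prefix
            if ident.upper().startswith(ns + ":"):
                return ident.upper()
            return f"{ns}:{ident}"
    return f"TEXT:{entity.name.upper()}"


def assign_layer(entity: Entity) -> Layer:
    """Layer of an entity, a pure function of its groundings (and, for
    ungrounded entities, of the endpoint list and the source hint).

    Grounded: HGNC -> gene/protein, FPLX -> protein family, CHEBI -> chemical,
    GO -> GO process, MESH/DOID/UMLS -> disease.  Ungrounded: one of the four
    endpoint names -> immune endpoint; a source-flagged bioprocess -> text-mined
    bioprocess; otherwise a gene-like symbol kept as a non-human gene node.
    """
    for ns in GROUNDING_PRECEDENCE:
        if ns in entity.groundings:
            return _NAMESPACE_LAYER[ns]
    if entity.name.strip().lower() in {e.lower() for e in IMMUNE_ENDPOINTS}:
        return Layer.IMMUNE_ENDPOINT
    if entity.kind_hint == "bioprocess":
        return Layer.INDRA_BIOPROCESS
    return Layer.GENE_PROTEIN


class MultilayerGraph:
    """A period-specific multilayer network.

    Thin wrapper over :class:`networkx.MultiGraph` where parallel edges are
    keyed by provenance (at most one edge per unordered node pair and
    provenance).  Node attributes: ``label``, ``layer``, ``is_human_gene``.
    Edge attributes: ``provenance``, ``weight``, ``evidence_count``,
    ``directed``.
    """

    def __init__(self, period: Period):
        self.period = period
        self.g = nx.MultiGraph(period=period.name)
        self.build_log: list[dict] = []

    # -- construction -------------------------------------------------------

    def add_entity(
        self,
        node_id: str,
        label: str,
        layer: Layer,
        is_human_gene: bool = False,
    ) -> None:
        if node_id in self.g:
            # keep first label seen; layer/flag must agree
            existing = self.g.nodes[node_id]
            if existing["layer"] != layer.value:
                raise ValueError(
                    f"node {node_id} already present in layer {existing['layer']}, "
                    f"refusing {layer.value}"
                )
            return
        self.g.add_node(node_id, label=label, layer=layer.value, is_human_gene=bool(is_human_gene))

    def add_edge(
        self,
        u: str,
        v: str,
        provenance: Provenance,
        weight: float = 1.0,
        evidence_count: int = 0,
        directed: bool = False,
    ) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u}")
        if u not in self.g or v not in self.g:
            raise KeyError(f"edge endpoints must exist as nodes: {u}, {v}")
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        if provenance is Provenance.LITERATURE and evidence_count < 1:
            raise ValueError("literature edges need evidence_count >= 1")
        if self.g.has_edge(u, v, key=provenance.value):
            raise ValueError(f"duplicate edge ({u}, {v}) with provenance {provenance.value}")
        self.g.add_edge(
            u,
            v,
            key=provenance.value,
            provenance=provenance.value,
            weight=float(weight),
            evidence_count=int(evidence_count),
            directed=bool(directed),
        )

    def log(self, stage: str, **counts) -> None:
        self.build_log.append({"stage": stage, **counts})

    # -- queries ------------------------------------------------------------

    def nodes_in_layer(self, layer: Layer) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["layer"] == layer.value)

    def layer_counts(self) -> dict[str, int]:
        """Node counts per layer, in the fixed layer order (report shape)."""
        counts = {layer.value: 0 for layer in Layer}
        for _, d in self.g.nodes(data=True):
            counts[d["layer"]] += 1
        return counts

    def label(self, node_id: str) -> str:
        return self.g.nodes[node_id]["label"]

    def edge_records(self) -> list[tuple]:
        """Sorted (u, v, provenance, directed, weight, evidence_count) tuples
        with u <= v; the canonical edge-set representation used for equality
        and serialization."""
        out = []
        for u, v, k, d in self.g.edges(keys=True, data=True):
            a, b = sorted((u, v))
            out.append((a, b, k, bool(d["directed"]), float(d["weight"]), int(d["evidence_count"])))
        return sorted(out)

    def copy(self) -> "MultilayerGraph":
        dup = MultilayerGraph(self.period)
        dup.g = self.g.copy()
        dup.build_log = [dict(r) for r in self.build_log]
        return dup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerGraph):
            return NotImplemented
        return (
            self.period == other.period
            and dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and self.edge_records() == other.edge_records()
        )

    # -- serialization ------------------------------------------------------

    def to_graphml(self, path: str | Path) -> None:
        g = self.g.copy()
        g.graph["period"] = self.period.name
        g.graph["build_log"] = json.dumps(self.build_log)
        nx.write_graphml(g, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "MultilayerGraph":
        g = nx.read_graphml(str(path), force_multigraph=True)
        obj = cls(Period[g.graph["period"]])
        obj.build_log = json.loads(g.graph.get("build_log", "[]"))
        for n, d in g.nodes(data=True):
            obj.add_entity(n, d["label"], Layer(d["layer"]), bool(d["is_human_gene"]))
        for u, v, k, d in g.edges(keys=True, data=True):
            obj.add_edge(
                u,
                v,
                Provenance(d["provenance"]),
                weight=float(d["weight"]),
                evidence_count=int(d["evidence_count"]),
                directed=bool(d["directed"]),
            )
        return obj

    def to_tsv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        nodes = pd.DataFrame(
            [
                {
                    "id": n,
                    "label": d["label"],
                    "layer": d["layer"],
                    "is_human_gene": d["is_human_gene"],
                }
                for n, d in sorted(self.g.nodes(data=True))
            ]
        )
        edges = pd.DataFrame(
            self.edge_records(),
            columns=["source", "target", "provenance", "directed", "weight", "evidence_count"],
        )
        with open(nodes_path, "w", encoding="utf-8") as fh:
            fh.write(f"# period={self.period.name}\n")
            nodes.to_csv(fh, sep="\t", index=False)
        with open(edges_path, "w", encoding="utf-8") as fh:
            fh.write(f"# period={self.period.name}\n")
            edges.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, nodes_path: str | Path, edges_path: str | Path) -> "MultilayerGraph":
        with open(nodes_path, encoding="utf-8") as fh:
            header = fh.readline().strip()
        period = Period[header.split("=", 1)[1]] if header.startswith("# period=") else Period.EG
        nodes = pd.read_csv(nodes_path, sep="\t", comment="#", dtype={"id": str, "label": str})
        edges = pd.read_csv(edges_path, sep="\t", comment="#", dtype={"source": str, "target": str})
        obj = cls(period)
        for row in nodes.itertuples(index=False):
            obj.add_entity(row.id, row.label, Layer(row.layer), bool(row.is_human_gene))
        for row in edges.itertuples(index=False):
            obj.add_edge(
                row.source,
                row.target,
                Provenance(row.provenance),
                weight=float(row.weight),
                evidence_count=int(row.evidence_count),
                directed=bool(row.directed),
            )
        return obj
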