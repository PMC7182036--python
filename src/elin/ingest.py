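"""Parse causal-statement files and tabular resources; assemble period networks.

Statement files are JSON arrays of text-mined causal relationships, one record
per relationship::

    {"type": "Activation",
     "subj": {"name": "IL6", "db_refs": {"HGNC": "6018"}},
     "obj":  {"name": "STAT3", "db_refs": {"HGNC": "11364"}},
     "evidence_count": 2, "pmids": ["12345"], "period": "NEWBORN"}

An entity dict may carry ``"kind": "bioprocess"`` to route an ungrounded name
to the text-mined bioprocess layer.  The record shape is also shipped as
``elin/data/statement_schema.json`` for reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    Entity,
    InvalidEntityError,
    Layer,
    MultilayerGraph,
    Period,
    Provenance,
    canonical_id,
)

__all__ = [
    "Statement",
    "StatementParseResult",
    "ReferenceEdgeTable",
    "AnnotationTable",
    "STATEMENT_TYPES",
    "DIRECTIONAL_TYPES",
    "parse_statements",
    "assemble_network",
    "read_reference_edges",
    "read_annotations",
    "MalformedInputError",
    "SchemaError",
]

log = logging.getLogger(__name__)

#: Closed causal-statement vocabulary.
STATEMENT_TYPES = frozenset(
    {"Activation", "Inhibition", "IncreaseAmount", "DecreaseAmount", "Complex", "Association"}
)
#: Types asserting a subject->object direction.
DIRECTIONAL_TYPES = frozenset({"Activation", "Inhibition", "IncreaseAmount", "DecreaseAmount"})

ANNOTATION_SOURCES = ("GO", "GOSLIM", "DISEASE", "ENDPOINT_MAP")


class MalformedInputError(ValueError):
    """More than half of the records in a statement file are invalid."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


@dataclass(frozen=True)
class Statement:
    """One causal literature relationship between two grounded entities."""

    subj: Entity
    obj: Entity
    stmt_type: str
    evidence_count: int
    pmids: tuple[str, ...]
    period: Period


@dataclass
class StatementParseResult:
    statements: list[Statement]
    n_invalid: int = 0
    n_self: int = 0

    def __iter__(self):
        return iter(self.statements)

    def __len__(self):
        return len(self.statements)


def _parse_entity(raw: dict) -> Entity:
    refs = {ns: str(v) for ns, v in raw.get("db_refs", {}).items() if ns != "TEXT"}
    return Entity(name=str(raw.get("name", "")), groundings=refs, kind_hint=raw.get("kind"))


def parse_statements(path: str | Path) -> StatementParseResult:
    """Read a statement file, keeping valid records in order.

    Invalid records (unknown type, malformed entities, missing fields) and
    self-statements (subject and object canonicalize to the same node) are
    counted and logged, not fatal — unless more than half of the records are
    invalid, which raises :class:`MalformedInputError`.
    """
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise MalformedInputError(f"{path}: expected a JSON array of statement records")

    out: list[Statement] = []
    n_invalid = n_self = 0
    for rec in records:
        try:
            stmt_type = rec["type"]
            if stmt_type not in STATEMENT_TYPES:
                raise ValueError(f"unknown statement type {stmt_type!r}")
            subj = _parse_entity(rec["subj"])
            obj = _parse_entity(rec["obj"])
            evidence = int(rec.get("evidence_count", 1))
            if evidence < 1:
                raise ValueError("evidence_count must be >= 1")
            period = Period[rec["period"]]
            pmids = tuple(str(p) for p in rec.get("pmids", []))
        except (KeyError, TypeError, ValueError, InvalidEntityError) as exc:
            n_invalid += 1
            log.warning("skipping invalid statement record: %s", exc)
            continue
        if canonical_id(subj) == canonical_id(obj):
            n_self += 1
            log.warning("dropping self-statement on %s", canonical_id(subj))
            continue
        out.append(
            Statement(
                subj=subj,
                obj=obj,
                stmt_type=stmt_type,
                evidence_count=evidence,
                pmids=pmids,
                period=period,
            )
        )
    if records and n_invalid > len(records) / 2:
        raise MalformedInputError(
            f"{path}: {n_invalid}/{len(records)} records invalid — input looks malformed"
        )
    return StatementParseResult(statements=out, n_invalid=n_invalid, n_self=n_self)


def _register(graph: MultilayerGraph, entity: Entity) -> str:
    nid = canonical_id(entity)
    graph.add_entity(nid, entity.name, entity.layer, entity.is_human_gene)
    return nid


def assemble_network(statements: list[Statement] | StatementParseResult, period: Period) -> MultilayerGraph:
    """De-duplicate statements into a period literature network.

    Statements collapsing onto the same unordered node pair merge into a
    single LITERATURE edge whose evidence_count is the sum over merged
    statements.  The edge stays directed only when every merged statement
    type is directional and all agree on the subject->object direction;
    conflicting or associative statements yield an undirected edge.
    """
    stmts = list(statements)
    if any(s.period is not period for s in stmts):
        raise ValueError("all statements must be tagged with the assembly period")
    graph = MultilayerGraph(period)
    if not stmts:
        log.warning("assembling %s from an empty statement list", period.name)
        graph.log("assemble", n_statements=0, n_edges=0, n_nodes=0)
        return graph

    merged: dict[tuple[str, str], dict] = {}
    for s in stmts:
        u = _register(graph, s.subj)
        v = _register(graph, s.obj)
        key = (min(u, v), max(u, v))
        entry = merged.setdefault(
            key, {"evidence": 0, "directions": set(), "all_directional": True}
        )
        entry["evidence"] += s.evidence_count
        if s.stmt_type in DIRECTIONAL_TYPES:
            entry["directions"].add((u, v))
        else:
            entry["all_directional"] = False

    for (u, v), entry in merged.items():
        directed = entry["all_directional"] and len(entry["directions"]) == 1
        graph.add_edge(
            u,
            v,
            Provenance.LITERATURE,
            weight=1.0,
            evidence_count=entry["evidence"],
            directed=directed,
        )
    graph.log(
        "assemble",
        n_statements=len(stmts),
        n_edges=graph.g.number_of_edges(),
        n_nodes=graph.g.number_of_nodes(),
    )
    return graph


@dataclass
class ReferenceEdgeTable:
    """Reference human gene-gene association edges (symbol pairs)."""

    df: pd.DataFrame = field(repr=False)

    @property
    def pairs(self) -> frozenset[frozenset[str]]:
        return frozenset(
            frozenset((a, b)) for a, b in zip(self.df["gene_a"], self.df["gene_b"])
        )

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a.upper(), b.upper())) in self.pairs

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class AnnotationTable:
    """Gene->term annotations from one source (GO, GOSLIM, DISEASE) or the
    bioprocess-term -> immune-endpoint map (ENDPOINT_MAP, where the ``gene``
    column holds the term id and ``term_id`` the endpoint name)."""

    source: str
    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_reference_edges(path: str | Path) -> ReferenceEdgeTable:
    """Load a reference association table (gene_a, gene_b, network_type, weight).

    Symbols are uppercased; duplicate unordered pairs within a network_type are
    collapsed with a logged count.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "network_type", "weight"])
    if df.empty:
        log.warning("%s: empty reference table", path)
        df["weight"] = df["weight"].astype(float)
        return ReferenceEdgeTable(df=df)
    df["gene_a"] = df["gene_a"].str.upper()
    df["gene_b"] = df["gene_b"].str.upper()
    df["weight"] = df["weight"].astype(float)
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    df = df.assign(gene_a=lo, gene_b=hi)
    before = len(df)
    df = df.drop_duplicates(subset=["gene_a", "gene_b", "network_type"]).reset_index(drop=True)
    if len(df) < before:
        log.info("%s: collapsed %d duplicate reference rows", path, before - len(df))
    return ReferenceEdgeTable(df=df)


def read_annotations(path: str | Path, source: str) -> AnnotationTable:
    """Load a gene->term annotation table for the given source.

    For GO/GOSLIM/DISEASE the columns are (gene, term_id, term_name); for
    ENDPOINT_MAP they are (term_id, endpoint).  Gene symbols are uppercased
    and duplicate (gene, term_id) rows collapsed.
    """
    if source not in ANNOTATION_SOURCES:
        raise ValueError(f"unknown annotation source {source!r}; expected one of {ANNOTATION_SOURCES}")
    if source == "ENDPOINT_MAP":
        df = _read_tsv(path, ["term_id", "endpoint"])
        before = len(df)
        df = df.drop_duplicates(subset=["term_id", "endpoint"]).reset_index(drop=True)
    else:
        df = _read_tsv(path, ["gene", "term_id", "term_name"])
        if not df.empty:
            df["gene"] = df["gene"].str.upper()
        before = len(df)
        df = df.drop_duplicates(subset=["gene", "term_id"]).reset_index(drop=True)
    if len(df) < before:
        log.info("%s: collapsed %d duplicate annotation rows", path, before - len(df))
    if df.empty:
        log.warning("%s: empty annotation table (%s)", path, source)
    return AnnotationTable(source=source, df=df)
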