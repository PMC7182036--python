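"""End-to-end orchestration: build -> denoise -> enrich -> infer -> rank per
period, then cross-period comparison, with per-stage artifacts on disk and a
machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd
import yaml

from .compare import combine_gestation, venn_partition
from .core import Layer, MultilayerGraph, Period
from .denoise import confirmation_table, denoise_graph
from .enrich import enrich_graph
from .infer import infer_edges
from .ingest import (
    AnnotationTable,
    assemble_network,
    parse_statements,
    read_annotations,
    read_reference_edges,
)
from .prioritize import PageRankParams, pagerank, rank_table, top_genes

__all__ = ["PipelineConfig", "run_all", "auto_background", "LAYER_ALIASES", "expand_pairs"]

log = logging.getLogger(__name__)

#: Aliases accepted in inference pair specs like ``bioprocess-disease``.
LAYER_ALIASES: dict[str, tuple[Layer, ...]] = {
    "gene": (Layer.GENE_PROTEIN,),
    "bioprocess": (Layer.INDRA_BIOPROCESS, Layer.GO_PROCESS, Layer.GOSLIM_PROCESS),
    "disease": (Layer.DISEASE,),
    "endpoint": (Layer.IMMUNE_ENDPOINT,),
}

DEFAULT_PAIRS = "bioprocess-disease,disease-endpoint"

_ANNOTATION_FILES = (("go", "GO"), ("goslim", "GOSLIM"), ("disease", "DISEASE"), ("endpoints", "ENDPOINT_MAP"))


class ConfigError(ValueError):
    """Pipeline configuration failed validation."""


@dataclass
class PipelineConfig:
    statements: dict[str, str]
    reference: str
    go: str
    goslim: str
    disease: str
    endpoints: str
    out_dir: str = "elin_out"
    pagerank: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    top_k: int = 50
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        try:
            cfg = cls(
                statements={str(k): str(v) for k, v in inputs["statements"].items()},
                reference=inputs["reference"],
                go=inputs["go"],
                goslim=inputs["goslim"],
                disease=inputs["disease"],
                endpoints=inputs["endpoints"],
                out_dir=raw.get("out_dir", "elin_out"),
                pagerank=raw.get("pagerank", {}),
                inference=raw.get("inference", {}),
                top_k=int(raw.get("top_k", 50)),
                log_level=raw.get("log_level", "INFO"),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in self.statements:
            if p not in Period.__members__:
                raise ConfigError(f"unknown period {p!r} in statements config")
        paths = [self.reference, self.go, self.goslim, self.disease, self.endpoints]
        paths += list(self.statements.values())
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input path(s) do not exist: {', '.join(missing)}")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        PageRankParams(**self.pagerank)  # validates damping etc.
        alpha = float(self.inference.get("alpha", 0.05))
        if not 0 < alpha < 1:
            raise ConfigError("inference alpha must lie in (0, 1)")


def expand_pairs(spec: str) -> list[tuple[Layer, Layer]]:
    """Expand a pair spec like ``bioprocess-disease,disease-endpoint`` into
    concrete layer pairs."""
    pairs = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            a_alias, b_alias = token.split("-")
            a_layers, b_layers = LAYER_ALIASES[a_alias], LAYER_ALIASES[b_alias]
        except (ValueError, KeyError):
            raise ConfigError(
                f"bad pair spec {token!r}; expected <alias>-<alias> with aliases "
                f"{sorted(LAYER_ALIASES)}"
            ) from None
        pairs.extend((a, b) for a in a_layers for b in b_layers)
    return pairs


def auto_background(graph: MultilayerGraph, annotations: list[AnnotationTable]) -> int:
    """Background gene-universe size for the overlap test: distinct gene
    symbols across the annotation tables and the graph's gene layer."""
    genes: set[str] = set()
    for tab in annotations:
        if tab.source != "ENDPOINT_MAP" and len(tab.df):
            genes.update(tab.df["gene"].str.upper())
    nodes = graph.g.nodes
    genes.update(
        nodes[n]["label"].upper()
        for n in graph.nodes_in_layer(Layer.GENE_PROTEIN)
    )
    return len(genes)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_top(path: Path, ranked, graph: MultilayerGraph, k: int) -> pd.DataFrame:
    genes = [r for r in ranked if r.layer is Layer.GENE_PROTEIN][:k]
    df = pd.DataFrame(
        [
            {
                "rank": i,
                "node_id": r.node_id,
                "label": r.label,
                "score": f"{r.score:.12g}",
                "layer": r.layer.value,
            }
            for i, r in enumerate(genes, start=1)
        ],
        columns=["rank", "node_id", "label", "score", "layer"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def run_all(config: PipelineConfig, pairs: str = DEFAULT_PAIRS) -> dict:
    """Run the full workflow for every configured period, then compare.

    Returns a manifest dict (also written as ``manifest.json``); artifacts are
    written under ``config.out_dir``.  Any stage failure raises with the
    period and stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref = read_reference_edges(config.reference)
    annotations = [
        read_annotations(getattr(config, attr), source)
        for attr, source in _ANNOTATION_FILES
    ]
    pr_params = PageRankParams(**config.pagerank)
    alpha = float(config.inference.get("alpha", 0.05))
    min_overlap = int(config.inference.get("min_overlap", 2))
    background = config.inference.get("background", "auto")
    layer_pairs = expand_pairs(pairs)

    reports = []
    top_lists: dict[str, list[str]] = {}
    period_artifacts: dict[str, dict] = {}
    for period_name in sorted(config.statements, key=lambda p: list(Period).index(Period[p])):
        period = Period[period_name]
        stage = "build"
        try:
            parsed = parse_statements(config.statements[period_name])
            graph = assemble_network(parsed.statements, period)
            graph.to_graphml(out / f"{period_name}_literature.graphml")

            stage = "denoise"
            graph, report = denoise_graph(graph, ref)
            reports.append(report)
            graph.to_graphml(out / f"{period_name}_denoised.graphml")

            stage = "enrich"
            graph, summary = enrich_graph(graph, annotations)

            stage = "infer"
            bg = auto_background(graph, annotations) if background == "auto" else int(background)
            inferred = []
            for la, lb in layer_pairs:
                inferred.extend(
                    infer_edges(graph, la, lb, background_n=bg, alpha=alpha, min_overlap=min_overlap)
                )
            pd.DataFrame(
                [
                    {
                        "a_id": e.a_id,
                        "b_id": e.b_id,
                        "k": e.k,
                        "jaccard": f"{e.jaccard:.6g}",
                        "p": f"{e.p_value:.6g}",
                        "q": f"{e.q_value:.6g}",
                    }
                    for e in inferred
                ],
                columns=["a_id", "b_id", "k", "jaccard", "p", "q"],
            ).to_csv(out / f"{period_name}_inferred.tsv", sep="\t", index=False)
            graph.to_graphml(out / f"{period_name}_final.graphml")
            graph.to_tsv(out / f"{period_name}_nodes.tsv", out / f"{period_name}_edges.tsv")

            stage = "rank"
            scores = pagerank(graph, pr_params)
            ranked = rank_table(scores, graph)
            top_df = _write_top(out / f"{period_name}_top{config.top_k}.tsv", ranked, graph, config.top_k)
            top_lists[period_name] = top_df["label"].tolist()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for period {period_name}: {exc}") from exc
        period_artifacts[period_name] = {
            "n_nodes": graph.g.number_of_nodes(),
            "n_edges": graph.g.number_of_edges(),
            "n_inferred": len(inferred),
            "background_n": bg,
        }

    confirmation_table(reports).to_csv(out / "denoise_report.tsv", sep="\t", index=False)

    gestation_names = [p.name for p in Period.gestational() if p.name in top_lists]
    venn_row = None
    if set(top_lists) == {p.name for p in Period}:
        gestation = combine_gestation(
            top_lists["EG"], top_lists["MG"], top_lists["LG"]
        )
        part = venn_partition(
            gestation,
            top_lists["BIRTH"],
            top_lists["NEWBORN"],
            top_lists["INFANT"],
            per_period_lists=[top_lists[p.name] for p in Period],
        )
        part.to_frame().to_csv(out / "venn.tsv", sep="\t", index=False)
        venn_row = {
            "n_gestation_union": len(gestation),
            "n_core_all_periods": len(part.core_all_periods),
            "core_all_periods": sorted(part.core_all_periods),
        }

    manifest = {
        "package": {"elin": _safe_version("elin"), "networkx": _safe_version("networkx")},
        "parameters": {
            "pagerank": {
                "damping": pr_params.damping,
                "tol": pr_params.tol,
                "max_iter": pr_params.max_iter,
                "use_weights": pr_params.use_weights,
            },
            "inference": {
                "alpha": alpha,
                "min_overlap": min_overlap,
                "background": background,
                "pairs": pairs,
            },
            "top_k": config.top_k,
            "seed": config.seed,
        },
        "inputs": {
            "reference": _sha256(config.reference),
            "annotations": {
                source: _sha256(getattr(config, attr)) for attr, source in _ANNOTATION_FILES
            },
            "statements": {p: _sha256(path) for p, path in sorted(config.statements.items())},
        },
        "periods": period_artifacts,
        "gestation_periods": gestation_names,
        "comparison": venn_row,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _safe_version(name: str) -> str:
    try:
        return pkg_version(name)
    except Exception:
        return "unknown"
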