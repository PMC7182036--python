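"""Synthetic input bundles with planted ground truth.

Emulates the five inputs the pipeline consumes — per-period causal-statement
files, a reference gene-gene association table, GO and GO-slim annotation
tables, a gene-disease table and a bioprocess-term -> immune-endpoint map —
so every stage and the end-to-end pipeline are testable without downloads.

Planted structure:

* ``n_hubs`` hub genes appear in statements, annotations and disease rows
  with ``hub_degree_multiplier`` times the baseline probability, so they are
  the ground-truth high-centrality markers PageRank should recover.
* ``noise_edge_fraction`` of gene-gene statement pairs are uniformly random
  and never enter the reference table; ``reference_coverage`` of all distinct
  gene-gene statement pairs (sampled from the non-noise pairs) are copied
  into the reference table, so denoising confirms roughly that fraction.
* ``n_nonhuman`` contaminant entities (bacterial/viral gene names) appear in
  statements without any grounding and receive no annotations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import IMMUNE_ENDPOINTS, Period

__all__ = ["SynthConfig", "GroundTruth", "generate_bundle"]

#: Non-human gene names observed in text-mined immune literature.
CONTAMINANT_POOL = ("lacZ", "env", "rpoD", "dop", "cscK", "lectin", "AtJ1", "lanA1", "ptc")

_STATEMENT_TYPES = ("Activation", "Inhibition", "IncreaseAmount", "DecreaseAmount", "Complex", "Association")
_NETWORK_TYPES = ("co-expression", "physical", "pathway", "co-localization")

# statement mix: share of each record kind per period
_MIX = {"gene_gene": 0.70, "gene_bioprocess": 0.12, "gene_chemical": 0.08, "gene_family": 0.05, "contaminant": 0.05}


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 300
    n_hubs: int = 10
    n_processes: int = 60
    n_diseases: int = 40
    n_periods: int = 6
    statements_per_period: int = 500
    hub_degree_multiplier: float = 8.0
    reference_coverage: float = 0.3
    noise_edge_fraction: float = 0.3
    n_nonhuman: int = 5
    seed: int = 42

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_hubs": self.n_hubs,
            "n_processes": self.n_processes,
            "n_diseases": self.n_diseases,
            "n_periods": self.n_periods,
            "statements_per_period": self.statements_per_period,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")
        for name, v in (
            ("reference_coverage", self.reference_coverage),
            ("noise_edge_fraction", self.noise_edge_fraction),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        if self.hub_degree_multiplier < 1:
            raise ValueError("hub_degree_multiplier must be >= 1")
        if self.n_hubs > self.n_genes:
            raise ValueError("n_hubs cannot exceed n_genes")
        if self.n_nonhuman < 0:
            raise ValueError("n_nonhuman must be >= 0")
        if self.n_periods > len(Period):
            raise ValueError(f"n_periods cannot exceed {len(Period)}")
        if self.reference_coverage > 1 - self.noise_edge_fraction:
            raise ValueError(
                "reference_coverage cannot exceed 1 - noise_edge_fraction "
                "(noise pairs are never placed in the reference table)"
            )


@dataclass
class GroundTruth:
    hub_gene_ids: list[str]
    periods: list[str]
    true_pairs: dict[str, list[list[str]]]
    noise_pairs: dict[str, list[list[str]]]
    reference_pairs: list[list[str]]
    process_profiles: dict[str, list[str]]
    disease_profiles: dict[str, list[str]]
    bookkeeping: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _symbols(config: SynthConfig) -> list[str]:
    width = max(3, len(str(config.n_genes)))
    return [f"ELG{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _weighted_gene(rng: np.random.Generator, symbols: list[str], weights: np.ndarray) -> str:
    return symbols[rng.choice(len(symbols), p=weights)]


def _entity(name: str, hgnc: str | None = None, **extra) -> dict:
    ent: dict = {"name": name, "db_refs": {}}
    if hgnc is not None:
        ent["db_refs"]["HGNC"] = hgnc
    ent.update(extra)
    return ent


def generate_bundle(config: SynthConfig, out_dir: str | Path) -> GroundTruth:
    """Write a complete synthetic input bundle into ``out_dir``.

    Deterministic given ``config.seed``: the same config yields byte-identical
    files.  Returns the :class:`GroundTruth` (also written as
    ``ground_truth.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    symbols = _symbols(config)
    hgnc_ids = {s: str(50000 + i) for i, s in enumerate(symbols, start=1)}
    hubs = sorted(rng.choice(symbols, size=config.n_hubs, replace=False).tolist())
    hub_set = set(hubs)
    weights = np.array(
        [config.hub_degree_multiplier if s in hub_set else 1.0 for s in symbols]
    )
    weights = weights / weights.sum()

    contaminants = [
        CONTAMINANT_POOL[i % len(CONTAMINANT_POOL)]
        + ("" if i < len(CONTAMINANT_POOL) else str(i // len(CONTAMINANT_POOL)))
        for i in range(config.n_nonhuman)
    ]

    n_go = max(1, (3 * config.n_processes) // 4)
    n_goslim = max(1, config.n_processes - n_go)
    go_terms = [(f"GO:{i:07d}", f"go process {i}") for i in range(1, n_go + 1)]
    goslim_terms = [(f"GOSLIM:{i:07d}", f"go-slim process {i}") for i in range(1, n_goslim + 1)]
    diseases = [(f"UMLS:C{i:07d}", f"disease {i}") for i in range(1, config.n_diseases + 1)]
    bioprocess_names = [f"bioprocess {i}" for i in range(1, 21)]
    chemicals = [(f"chem{i}", f"{20000 + i}") for i in range(1, 31)]
    families = [(f"FAM{i}", f"family{i}") for i in range(1, 16)]

    periods = [p.name for p in list(Period)[: config.n_periods]]
    true_pairs: dict[str, set[tuple[str, str]]] = {p: set() for p in periods}
    noise_pairs: dict[str, set[tuple[str, str]]] = {p: set() for p in periods}

    n_each = {
        kind: max(1, int(round(frac * config.statements_per_period)))
        for kind, frac in _MIX.items()
    }
    if config.n_nonhuman == 0:
        n_each["contaminant"] = 0

    def draw_pair(uniform: bool) -> tuple[str, str]:
        while True:
            if uniform:
                a, b = rng.choice(len(symbols), size=2, replace=False)
                pair = symbols[a], symbols[b]
            else:
                pair = (
                    _weighted_gene(rng, symbols, weights),
                    _weighted_gene(rng, symbols, weights),
                )
            if pair[0] != pair[1]:
                return min(pair), max(pair)

    def record(subj: dict, obj: dict, period: str) -> dict:
        return {
            "type": str(rng.choice(_STATEMENT_TYPES)),
            "subj": subj,
            "obj": obj,
            "evidence_count": int(1 + rng.poisson(0.5)),
            "pmids": [str(int(rng.integers(10_000_000, 40_000_000)))],
            "period": period,
        }

    for period in periods:
        statements: list[dict] = []
        n_gg = n_each["gene_gene"]
        n_noise = int(round(config.noise_edge_fraction * n_gg))
        for i in range(n_gg):
            noisy = i < n_noise
            a, b = draw_pair(uniform=noisy)
            (noise_pairs if noisy else true_pairs)[period].add((a, b))
            statements.append(
                record(_entity(a, hgnc_ids[a]), _entity(b, hgnc_ids[b]), period)
            )
        for _ in range(n_each["gene_bioprocess"]):
            g = _weighted_gene(rng, symbols, weights)
            bp = bioprocess_names[rng.integers(len(bioprocess_names))]
            statements.append(
                record(_entity(g, hgnc_ids[g]), {"name": bp, "db_refs": {}, "kind": "bioprocess"}, period)
            )
        for _ in range(n_each["gene_chemical"]):
            g = _weighted_gene(rng, symbols, weights)
            cname, chebi = chemicals[rng.integers(len(chemicals))]
            statements.append(
                record(_entity(g, hgnc_ids[g]), {"name": cname, "db_refs": {"CHEBI": chebi}}, period)
            )
        for _ in range(n_each["gene_family"]):
            g = _weighted_gene(rng, symbols, weights)
            fname, fplx = families[rng.integers(len(families))]
            statements.append(
                record(_entity(g, hgnc_ids[g]), {"name": fname, "db_refs": {"FPLX": fplx}}, period)
            )
        for i in range(n_each["contaminant"]):
            c = contaminants[i % len(contaminants)]
            g = _weighted_gene(rng, symbols, weights)
            statements.append(record({"name": c, "db_refs": {}}, _entity(g, hgnc_ids[g]), period))
        order = rng.permutation(len(statements))
        statements = [statements[i] for i in order]
        with open(out / f"statements_{period}.json", "w", encoding="utf-8") as fh:
            json.dump(statements, fh, indent=1, sort_keys=True)

    # within a period, true beats noise when the same pair is drawn both ways
    for period in periods:
        noise_pairs[period] -= true_pairs[period]
    all_true = set().union(*true_pairs.values())
    global_noise = set().union(*noise_pairs.values())

    # reference table: per period, reference_coverage of that period's
    # distinct gene-gene pairs, sampled from its true pairs only; pairs that
    # are noise in *any* period never enter the reference
    ref_pairs: set[tuple[str, str]] = set()
    for period in periods:
        distinct = true_pairs[period] | noise_pairs[period]
        n_take = int(math.floor(config.reference_coverage * len(distinct)))
        candidates = sorted(true_pairs[period] - global_noise)
        n_take = min(n_take, len(candidates))
        idx = rng.choice(len(candidates), size=n_take, replace=False)
        ref_pairs.update(candidates[i] for i in idx)
    # background pairs never seen in statements pad the table to a realistic size
    all_seen = all_true | global_noise
    n_background = 2 * len(ref_pairs)
    while n_background > 0:
        pair = draw_pair(uniform=True)
        if pair not in all_seen and pair not in ref_pairs:
            ref_pairs.add(pair)
            n_background -= 1
    ref_rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "network_type": _NETWORK_TYPES[int(rng.integers(len(_NETWORK_TYPES)))],
            "weight": round(float(rng.uniform(0.05, 1.0)), 4),
        }
        for a, b in sorted(ref_pairs)
    ]
    pd.DataFrame(ref_rows, columns=["gene_a", "gene_b", "network_type", "weight"]).to_csv(
        out / "reference.tsv", sep="\t", index=False
    )

    # annotation tables: per (gene, term) Bernoulli, hub probability multiplied
    def annotate(terms: list[tuple[str, str]], mean_per_gene: float) -> list[dict]:
        p0 = min(1.0, mean_per_gene / len(terms))
        rows = []
        for s in symbols:
            p = min(1.0, p0 * (config.hub_degree_multiplier if s in hub_set else 1.0))
            mask = rng.random(len(terms)) < p
            rows.extend(
                {"gene": s, "term_id": tid, "term_name": tname}
                for (tid, tname), hit in zip(terms, mask)
                if hit
            )
        return rows

    go_rows = annotate(go_terms, mean_per_gene=2.0)
    goslim_rows = annotate(goslim_terms, mean_per_gene=1.0)
    dis_rows = annotate(diseases, mean_per_gene=1.5)
    for rows, name in ((go_rows, "go.tsv"), (goslim_rows, "goslim.tsv"), (dis_rows, "disease.tsv")):
        pd.DataFrame(rows, columns=["gene", "term_id", "term_name"]).to_csv(
            out / name, sep="\t", index=False
        )

    # endpoint map over process-layer node ids (GO, GO-slim and text bioprocesses)
    process_ids = (
        [tid for tid, _ in go_terms]
        + [tid for tid, _ in goslim_terms]
        + [f"TEXT:{n.upper()}" for n in bioprocess_names]
    )
    ep_rows = []
    for tid in process_ids:
        if rng.random() < 0.3:
            n_ep = int(rng.integers(1, 3))
            chosen = rng.choice(len(IMMUNE_ENDPOINTS), size=n_ep, replace=False)
            ep_rows.extend({"term_id": tid, "endpoint": IMMUNE_ENDPOINTS[i]} for i in sorted(chosen))
    pd.DataFrame(ep_rows, columns=["term_id", "endpoint"]).to_csv(
        out / "endpoints.tsv", sep="\t", index=False
    )

    def profiles(rows: list[dict]) -> dict[str, list[str]]:
        prof: dict[str, list[str]] = {}
        for r in rows:
            prof.setdefault(r["term_id"], []).append(r["gene"])
        return {k: sorted(v) for k, v in sorted(prof.items())}

    bookkeeping = {
        "n_statement_records": {p: sum(n_each.values()) for p in periods},
        "n_distinct_gene_pairs": {
            p: len(true_pairs[p] | noise_pairs[p]) for p in periods
        },
        "n_confirmable_gene_pairs": {
            p: len((true_pairs[p] | noise_pairs[p]) & ref_pairs) for p in periods
        },
        "n_reference_rows": len(ref_rows),
        "n_annotation_rows": {
            "GO": len(go_rows),
            "GOSLIM": len(goslim_rows),
            "DISEASE": len(dis_rows),
            "ENDPOINT_MAP": len(ep_rows),
        },
    }
    truth = GroundTruth(
        hub_gene_ids=hubs,
        periods=periods,
        true_pairs={p: [list(t) for t in sorted(true_pairs[p])] for p in periods},
        noise_pairs={p: [list(t) for t in sorted(noise_pairs[p])] for p in periods},
        reference_pairs=[list(t) for t in sorted(ref_pairs)],
        process_profiles=profiles(go_rows + goslim_rows),
        disease_profiles=profiles(dis_rows),
        bookkeeping=bookkeeping,
    )
    truth.to_json(out / "ground_truth.json")
    return truth
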