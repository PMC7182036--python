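"""Statement parsing, network assembly and table readers."""

import json
import random

import pytest

from elin import Entity, Period, Provenance, assemble_network, parse_statements
from elin.ingest import (
    MalformedInputError,
    SchemaError,
    Statement,
    read_annotations,
    read_reference_edges,
)


def write_statements(path, records):
    path.write_text(json.dumps(records), encoding="utf-8")
    return path


def rec(subj, obj, stype="Activation", evidence=1, period="NEWBORN", **kw):
    def ent(x):
        if isinstance(x, dict):
            return x
        return {"name": x, "db_refs": {"HGNC": str(abs(hash(x)) % 10_000)}}

    return {"type": stype, "subj": ent(subj), "obj": ent(obj),
            "evidence_count": evidence, "pmids": ["1"], "period": period, **kw}


def stmt(a, b, stype="Activation", evidence=1, period=Period.NEWBORN):
    return Statement(
        subj=Entity(a, {"HGNC": a}),
        obj=Entity(b, {"HGNC": b}),
        stmt_type=stype,
        evidence_count=evidence,
        pmids=("1",),
        period=period,
    )


class TestParseStatements:
    def test_unknown_type_counted_not_fatal(self, tmp_path):
        records = [rec("A", "B"), rec("C", "D"), rec("E", "F"),
                   rec("G", "H", stype="Phosphorylation")]
        result = parse_statements(write_statements(tmp_path / "s.json", records))
        assert len(result) == 3
        assert result.n_invalid == 1

    def test_empty_file_gives_empty_list(self, tmp_path):
        result = parse_statements(write_statements(tmp_path / "s.json", []))
        assert list(result) == []

    def test_self_statement_dropped_and_counted(self, tmp_path):
        tnf = {"name": "TNF", "db_refs": {"HGNC": "11892"}}
        tnfa = {"name": "TNF-alpha", "db_refs": {"HGNC": "11892"}}
        result = parse_statements(write_statements(tmp_path / "s.json", [rec(tnf, tnfa)]))
        assert len(result) == 0
        assert result.n_self == 1

    def test_majority_invalid_is_malformed_input(self, tmp_path):
        records = [rec("A", "B")] + [rec("C", "D", stype="Nope")] * 3
        with pytest.raises(MalformedInputError):
            parse_statements(write_statements(tmp_path / "s.json", records))

    def test_order_preserved(self, tmp_path):
        records = [rec(f"G{i}", f"H{i}") for i in range(5)]
        result = parse_statements(write_statements(tmp_path / "s.json", records))
        assert [s.subj.name for s in result] == [f"G{i}" for i in range(5)]


class TestAssembleNetwork:
    def test_reciprocal_statements_merge_with_summed_evidence(self):
        s1 = stmt("IL6", "STAT3", "Activation", evidence=2)
        s2 = Statement(
            subj=Entity("STAT3", {"HGNC": "STAT3"}),
            obj=Entity("IL6", {"HGNC": "IL6"}),
            stmt_type="Association",
            evidence_count=1,
            pmids=("2",),
            period=Period.NEWBORN,
        )
        g = assemble_network([s1, s2], Period.NEWBORN)
        assert g.g.number_of_edges() == 1
        (_, _, data), = g.g.edges(data=True)
        assert data["evidence_count"] == 3
        assert data["provenance"] == "LITERATURE"
        assert not data["directed"]  # association demotes direction

    def test_distinct_pair_count_matches_brute_force(self):
        pairs = [("A", "B"), ("B", "A"), ("A", "C"), ("C", "D"), ("D", "E")]
        stmts = [stmt(a, b) for a, b in pairs]
        brute = {frozenset((a, b)) for a, b in pairs}
        g = assemble_network(stmts, Period.NEWBORN)
        assert g.g.number_of_edges() == len(brute) == 4

    def test_consistent_direction_preserved(self):
        g = assemble_network([stmt("A", "B"), stmt("A", "B", "Inhibition")], Period.NEWBORN)
        (_, _, data), = g.g.edges(data=True)
        assert data["directed"]

    def test_conflicting_directions_become_undirected(self):
        g = assemble_network([stmt("A", "B"), stmt("B", "A")], Period.NEWBORN)
        (_, _, data), = g.g.edges(data=True)
        assert not data["directed"]

    def test_order_invariant(self):
        rng = random.Random(11)
        stmts = [stmt(f"G{rng.randint(0, 9)}", f"H{rng.randint(0, 9)}", evidence=rng.randint(1, 4))
                 for _ in range(40)]
        g1 = assemble_network(stmts, Period.NEWBORN)
        shuffled = stmts[:]
        rng.shuffle(shuffled)
        assert assemble_network(shuffled, Period.NEWBORN) == g1

    def test_evidence_mass_conserved(self):
        rng = random.Random(5)
        stmts = [stmt(f"G{rng.randint(0, 5)}", f"H{rng.randint(0, 5)}", evidence=rng.randint(1, 3))
                 for _ in range(25)]
        g = assemble_network(stmts, Period.NEWBORN)
        total = sum(d["evidence_count"] for _, _, d in g.g.edges(data=True))
        assert total == sum(s.evidence_count for s in stmts)

    def test_wrong_period_tag_rejected(self):
        with pytest.raises(ValueError):
            assemble_network([stmt("A", "B", period=Period.EG)], Period.NEWBORN)

    def test_empty_statement_list_gives_empty_graph(self):
        g = assemble_network([], Period.EG)
        assert g.g.number_of_nodes() == 0
        assert g.build_log[0]["n_statements"] == 0

    def test_paper_scale_newborn_fixture_assembles(self, tmp_path):
        # roughly the scale of the densest period corpus (~2,917 relationships)
        rng = random.Random(2)
        records = [rec(f"G{rng.randint(0, 400)}", f"G{rng.randint(401, 800)}",
                       evidence=rng.randint(1, 3)) for _ in range(2917)]
        result = parse_statements(write_statements(tmp_path / "big.json", records))
        g = assemble_network(result.statements, Period.NEWBORN)
        assert g.g.number_of_edges() > 2000


class TestTableReaders:
    def test_duplicate_reference_pairs_collapsed(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text(
            "gene_a\tgene_b\tnetwork_type\tweight\n"
            "IL6\tTNF\tphysical\t0.5\n"
            "TNF\tIL6\tphysical\t0.7\n"
            "IL6\tIL10\tphysical\t0.2\n"
            "CD4\tFOXP3\tpathway\t0.9\n"
        )
        table = read_reference_edges(p)
        assert len(table.pairs) == 3
        assert ("tnf", "il6") in table

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("gene_a\tgene_b\tweight\nA\tB\t0.5\n")
        with pytest.raises(SchemaError, match="network_type"):
            read_reference_edges(p)

    def test_empty_but_headered_reference_ok(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("gene_a\tgene_b\tnetwork_type\tweight\n")
        assert len(read_reference_edges(p)) == 0

    def test_annotation_symbols_uppercased_and_merged(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text(
            "gene\tterm_id\tterm_name\n"
            "il6\tGO:1\timmune response\n"
            "IL6\tGO:1\timmune response\n"
            "Tnf\tGO:2\tapoptosis\n"
        )
        table = read_annotations(p, "GO")
        assert len(table) == 2
        assert set(table.df["gene"]) == {"IL6", "TNF"}

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("# comment\ngene\tterm_id\tterm_name\nIL6\tGO:1\tx\n")
        assert len(read_annotations(p, "GO")) == 1

    def test_unknown_source_rejected(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("gene\tterm_id\tterm_name\n")
        with pytest.raises(ValueError):
            read_annotations(p, "KEGG")
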