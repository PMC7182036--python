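"""Overlap-based cross-layer inference: hypergeometric tail, BH, gene profiles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elin import Layer, Provenance, benjamini_hochberg, gene_profile, infer_edges, overlap_pvalue

from conftest import add_gene, annotation, make_graph
from elin.enrich import enrich_graph


def enumerate_tail(k, size_a, size_b, n):
    """Oracle: P(|draw ∩ A| >= k) by enumerating all C(n, size_b) draws."""
    population = range(n)
    a = set(range(size_a))
    hits = sum(1 for draw in combinations(population, size_b) if len(a & set(draw)) >= k)
    return hits / comb(n, size_b)


class TestOverlapPvalue:
    def test_worked_example_one_third(self):
        # |A|=4, |B|=3, k=2, N=10: (C(4,2)C(6,1) + C(4,3))/C(10,3) = 40/120
        assert overlap_pvalue(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_enumeration_on_sampled_configs(self):
        # full sweep over background <= 12 lives in the acceptance suite
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            sa = int(rng.integers(0, n + 1))
            sb = int(rng.integers(0, n + 1))
            k = int(rng.integers(0, min(sa, sb) + 1))
            assert overlap_pvalue(k, sa, sb, n) == pytest.approx(
                enumerate_tail(k, sa, sb, n), abs=1e-12
            )

    def test_monotone_nonincreasing_in_k(self):
        ps = [overlap_pvalue(k, 8, 6, 20) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_k_zero_is_certain(self):
        assert overlap_pvalue(0, 5, 5, 10) == 1.0


class TestBenjaminiHochberg:
    @staticmethod
    def stepup_oracle(ps, alpha):
        """Textbook step-up scan: largest i with p_(i) <= i*alpha/m."""
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        m = len(ps)
        cutoff = -1
        for rank, i in enumerate(order, start=1):
            if ps[i] <= rank * alpha / m:
                cutoff = rank
        return {order[i] for i in range(cutoff)} if cutoff > 0 else set()

    def test_rejection_set_equals_stepup_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            ps = rng.uniform(size=rng.integers(1, 40)) ** rng.uniform(0.5, 3)
            for alpha in (0.01, 0.05, 0.2):
                q = benjamini_hochberg(ps)
                assert set(np.flatnonzero(q <= alpha)) == self.stepup_oracle(list(ps), alpha)

    def test_q_at_least_p_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(4)
        ps = rng.uniform(size=50)
        q = benjamini_hochberg(ps)
        assert np.all(q >= ps - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_empty_input(self):
        assert benjamini_hochberg(np.array([])).size == 0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_stepup_equivalence_for_arbitrary_pvalues(self, ps):
        q = benjamini_hochberg(np.array(ps))
        assert set(np.flatnonzero(q <= 0.05)) == self.stepup_oracle(ps, 0.05)


def profile_graph():
    """5 genes; disease D1 shares 2 genes with process P1, D2 is disjoint."""
    g = make_graph()
    for s in ["A", "B", "C", "D", "E"]:
        add_gene(g, s)
    g, _ = enrich_graph(
        g,
        [
            annotation("GO", [("A", "GO:P1", "p1"), ("B", "GO:P1", "p1"), ("C", "GO:P1", "p1")]),
            annotation(
                "DISEASE",
                [("A", "UMLS:D1", "d1"), ("B", "UMLS:D1", "d1"), ("D", "UMLS:D1", "d1"),
                 ("E", "UMLS:D2", "d2")],
            ),
            annotation("ENDPOINT_MAP", [("GO:P1", "autoimmunity")]),
        ],
    )
    return g


class TestGeneProfile:
    def test_neighbor_set(self):
        g = profile_graph()
        assert gene_profile(g, "UMLS:D1") == {"A", "B", "D"}
        assert gene_profile(g, "GO:P1") == {"A", "B", "C"}

    def test_endpoint_union_semantics(self):
        g = profile_graph()
        ep = g.nodes_in_layer(Layer.IMMUNE_ENDPOINT)[0]
        assert gene_profile(g, ep) == {"A", "B", "C"}

    def test_endpoint_union_over_two_terms(self):
        g = make_graph()
        for s in ["A", "B", "C"]:
            add_gene(g, s)
        g, _ = enrich_graph(
            g,
            [
                annotation("GO", [("A", "GO:1", "x"), ("B", "GO:1", "x"), ("B", "GO:2", "y"), ("C", "GO:2", "y")]),
                annotation("ENDPOINT_MAP", [("GO:1", "autoimmunity"), ("GO:2", "autoimmunity")]),
            ],
        )
        ep = g.nodes_in_layer(Layer.IMMUNE_ENDPOINT)[0]
        assert gene_profile(g, ep) == {"A", "B", "C"}

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            gene_profile(profile_graph(), "UMLS:NOPE")


class TestInferEdges:
    def test_overlapping_pair_found_disjoint_not_tested(self):
        g = profile_graph()
        edges = infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=5, alpha=0.9, min_overlap=2)
        assert [(e.a_id, e.b_id) for e in edges] == [("GO:P1", "UMLS:D1")]
        e = edges[0]
        assert e.shared_genes == {"A", "B"} and e.k == 2
        assert e.jaccard == pytest.approx(2 / 4)
        assert e.p_value == pytest.approx(overlap_pvalue(2, 3, 3, 5))
        assert e.q_value >= e.p_value
        assert g.g.has_edge("GO:P1", "UMLS:D1", key=Provenance.INFERRED.value)

    def test_min_overlap_gates_testing(self):
        g = profile_graph()
        edges = infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=5, alpha=1 - 1e-9, min_overlap=1)
        # D2 shares no genes with P1: never tested even at permissive alpha
        assert ("GO:P1", "UMLS:D2") not in {(e.a_id, e.b_id) for e in edges}

    def test_identical_profiles_have_jaccard_one(self):
        g = make_graph()
        for s in ["A", "B", "C"]:
            add_gene(g, s)
        rows = [(s, "GO:X", "x") for s in "ABC"]
        drows = [(s, "UMLS:Y", "y") for s in "ABC"]
        g, _ = enrich_graph(g, [annotation("GO", rows), annotation("DISEASE", drows)])
        (edge,) = infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=10, alpha=0.9)
        assert edge.jaccard == 1.0

    def test_background_smaller_than_profile_rejected(self):
        g = profile_graph()
        with pytest.raises(ValueError):
            infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=2)

    def test_alpha_and_min_overlap_validation(self):
        g = profile_graph()
        with pytest.raises(ValueError):
            infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=5, alpha=1.5)
        with pytest.raises(ValueError):
            infer_edges(g, Layer.GO_PROCESS, Layer.DISEASE, background_n=5, min_overlap=0)
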