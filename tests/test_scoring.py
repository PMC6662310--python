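"""Scoring semantics: upstream consistency, supported BFS, impact, triangulation."""

import math

import numpy as np
import pytest

from conftest import brute_force_impact, random_signed_graph
from tripath.graph_model import ExpressionTable, PathwayGraph, SignedEdge
from tripath.scoring import (
    GeneScoreRecord,
    ParameterError,
    ScoringParams,
    impact,
    score_pathway,
    supported_downstream_subgraph,
    triangulation,
    upstream_consistency,
)


class TestUpstreamConsistency:
    def test_mixed_evidence(self, fan_in_graph):
        # A activates g (A up, g up: supporting, weight 1); B inhibits g
        # (B up predicts g down, g is up: inconsistent, weight 3)
        graph, expr = fan_in_graph
        assert upstream_consistency(graph, expr, "g") == (1.0, 3.0, -0.5)

    def test_no_upstream_edges(self, chain_graph):
        graph, expr = chain_graph
        assert upstream_consistency(graph, expr, "g") == (0.0, 0.0, 0.0)

    def test_all_supporting_hits_plus_one(self, chain_graph):
        graph, expr = chain_graph
        assert upstream_consistency(graph, expr, "v1")[2] == 1.0

    def test_zero_expression_is_neutral(self):
        g = PathwayGraph("p", {"A", "g"}, [SignedEdge("A", "g", 1)])
        for expr in ({"A": 0.0, "g": 1.0}, {"A": 1.0, "g": 0.0}):
            assert upstream_consistency(g, ExpressionTable(expr), "g") == (0, 0, 0)

    def test_unknown_gene_errors(self, chain_graph):
        graph, expr = chain_graph
        with pytest.raises(KeyError):
            upstream_consistency(graph, expr, "nope")


class TestSupportedDownstream:
    def test_supported_chain(self, chain_graph):
        graph, expr = chain_graph
        assert supported_downstream_subgraph(graph, expr, "g") == {"v1": 1, "v2": 2}

    def test_sign_mismatch_blocks(self):
        g = PathwayGraph("p", {"g", "v1"}, [SignedEdge("g", "v1", 1)])
        expr = ExpressionTable({"g": 1.0, "v1": -2.0})
        assert supported_downstream_subgraph(g, expr, "g") == {}

    def test_inhibition_supported_when_signs_oppose(self):
        g = PathwayGraph("p", {"g", "v1"}, [SignedEdge("g", "v1", -1)])
        expr = ExpressionTable({"g": 1.0, "v1": -2.0})
        assert supported_downstream_subgraph(g, expr, "g") == {"v1": 1}

    def test_max_depth_caps_traversal(self, chain_graph):
        graph, expr = chain_graph
        assert supported_downstream_subgraph(graph, expr, "g", max_depth=1) == {"v1": 1}

    def test_cycle_terminates_and_excludes_source(self):
        g = PathwayGraph(
            "cyc", {"a", "b"}, [SignedEdge("a", "b", 1), SignedEdge("b", "a", 1)]
        )
        expr = ExpressionTable({"a": 1.0, "b": 1.0})
        assert supported_downstream_subgraph(g, expr, "a") == {"b": 1}


class TestImpact:
    def test_closed_form_chain(self, chain_graph):
        graph, expr = chain_graph
        expected = 2 * math.exp(-1) + 0.5 * math.exp(-2)
        assert impact(graph, expr, "g") == pytest.approx(expected, abs=1e-12)

    def test_empty_subgraph_is_zero(self, chain_graph):
        graph, expr = chain_graph
        assert impact(graph, expr, "v2") == 0.0

    def test_large_decay_kills_impact(self, chain_graph):
        graph, expr = chain_graph
        assert impact(graph, expr, "g", ScoringParams(decay_rate=50.0)) < 1e-20

    def test_invalid_decay_rejected(self):
        with pytest.raises(ParameterError):
            ScoringParams(decay_rate=0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_simple_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph, expr = random_signed_graph(rng, int(rng.integers(3, 10)))
        for gene in graph.nodes:
            assert impact(graph, expr, gene) == pytest.approx(
                brute_force_impact(graph, expr, gene), abs=1e-12
            )

    def test_matches_oracle_with_depth_cap(self):
        rng = np.random.default_rng(99)
        graph, expr = random_signed_graph(rng, 8)
        params = ScoringParams(max_depth=2)
        for gene in graph.nodes:
            assert impact(graph, expr, gene, params) == pytest.approx(
                brute_force_impact(graph, expr, gene, max_depth=2), abs=1e-12
            )


class TestTriangulation:
    def test_combination_arithmetic(self):
        imp = 2 * math.exp(-1) + 0.5 * math.exp(-2)
        params = ScoringParams(regulator_weighting=False)
        assert triangulation(-0.5, imp, 0, params) == pytest.approx(-0.5 * (1 + imp))

    def test_zero_consistency_annihilates(self):
        assert triangulation(0.0, 123.0, 99) == 0.0

    def test_regulator_weighting(self):
        assert triangulation(1.0, 0.0, 1) == pytest.approx(2.0)  # 1 + log2(2)

    def test_weighting_off_ignores_count(self):
        params = ScoringParams(regulator_weighting=False)
        assert triangulation(1.0, 0.0, 7, params) == 1.0


class TestScorePathway:
    def test_composes_per_gene_operations(self, chain_graph):
        graph, expr = chain_graph
        by_gene = {r.gene: r for r in score_pathway(graph, expr)}
        assert len(by_gene) == len(graph.nodes)
        for gene in graph.nodes:
            s, i, c = upstream_consistency(graph, expr, gene)
            r = by_gene[gene]
            assert (r.support, r.inconsistency, r.consistency) == (s, i, c)
            assert r.impact == pytest.approx(impact(graph, expr, gene), abs=1e-12)
            assert r.triangulation == pytest.approx(
                triangulation(c, r.impact, 0), abs=1e-12
            )

    def test_all_zero_expression_scores_zero(self, chain_graph):
        graph, _ = chain_graph
        expr = ExpressionTable({g: 0.0 for g in graph.nodes})
        for r in score_pathway(graph, expr):
            assert (r.support, r.inconsistency, r.consistency, r.impact, r.triangulation) == (
                0,
                0,
                0,
                0,
                0,
            )

    def test_edge_row_order_irrelevant(self):
        rng = np.random.default_rng(7)
        graph, expr = random_signed_graph(rng, 8)
        shuffled = list(graph.edges)
        rng.shuffle(shuffled)
        g2 = PathwayGraph(graph.pathway_id, set(graph.nodes), shuffled)
        a = {r.gene: r.triangulation for r in score_pathway(graph, expr)}
        b = {r.gene: r.triangulation for r in score_pathway(g2, expr)}
        assert a == b


class TestScoreInvariants:
    def test_consistency_bounds_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            graph, expr = random_signed_graph(rng, int(rng.integers(2, 8)), 0.4)
            for r in score_pathway(graph, expr):
                assert -1.0 <= r.consistency <= 1.0

    def test_sign_preservation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            graph, expr = random_signed_graph(rng, int(rng.integers(3, 9)), 0.4)
            for r in score_pathway(graph, expr):
                assert math.copysign(1, r.triangulation) == math.copysign(
                    1, r.consistency
                ) or (r.triangulation == 0 and r.consistency == 0)

    def test_impact_monotone_in_added_supported_edge(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            graph, expr = random_signed_graph(rng, 6, 0.3)
            before = {g: impact(graph, expr, g) for g in graph.nodes}
            # add one supported edge u->v not already present
            genes = sorted(graph.nodes)
            existing = {(e.source, e.target, e.sign) for e in graph.edges}
            added = None
            for u in genes:
                for v in genes:
                    eu, ev = expr.get(u), expr.get(v)
                    if u == v or eu == 0 or ev == 0:
                        continue
                    sign = 1 if (eu > 0) == (ev > 0) else -1
                    if (u, v, sign) not in existing:
                        added = SignedEdge(u, v, sign)
                        break
                if added:
                    break
            if added is None:
                continue
            g2 = PathwayGraph(graph.pathway_id, set(graph.nodes), list(graph.edges) + [added])
            for g in graph.nodes:
                assert impact(g2, expr, g) >= before[g] - 1e-12

    def test_triangulation_monotone_in_regulators(self):
        for c in (-0.8, 0.3, 1.0):
            values = [abs(triangulation(c, 0.5, k)) for k in range(6)]
            assert values == sorted(values)
            assert abs(triangulation(c, 0.5, 1)) >= abs(
                triangulation(c, 0.5, 1, ScoringParams(regulator_weighting=False))
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        graph, expr = random_signed_graph(rng, 7, 0.35)
        mapping = {g: f"X_{g}" for g in graph.nodes}
        g2 = PathwayGraph(
            "relabel",
            {mapping[g] for g in graph.nodes},
            [SignedEdge(mapping[e.source], mapping[e.target], e.sign) for e in graph.edges],
        )
        e2 = ExpressionTable({mapping[g]: expr.get(g) for g in graph.nodes})
        a = {r.gene: r for r in score_pathway(graph, expr)}
        b = {r.gene: r for r in score_pathway(g2, e2)}
        for g in graph.nodes:
            assert b[mapping[g]].triangulation == pytest.approx(a[g].triangulation, abs=1e-12)
            assert b[mapping[g]].consistency == a[g].consistency
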