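"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: impact is
checked against exhaustive simple-path enumeration, loop assignment against
union-find merging plus shortest-path search, and proximity against per-base
distance enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from tripath.graph_model import ExpressionTable, PathwayGraph, SignedEdge
from tripath.noncoding import GenomicInterval, Loop


# ---------------------------------------------------------------- graphs

def random_signed_graph(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.3):
    """Random signed directed graph (cycles allowed) + i.i.d. normal expression."""
    genes = [f"N{i}" for i in range(n_nodes)]
    seen = set()
    edges = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                sign = 1 if rng.random() < 0.5 else -1
                if (genes[i], genes[j], sign) not in seen:
                    seen.add((genes[i], genes[j], sign))
                    edges.append(SignedEdge(genes[i], genes[j], sign))
    graph = PathwayGraph("rand", set(genes), edges)
    expr = ExpressionTable({g: float(rng.normal()) for g in genes})
    return graph, expr


def regulated_random_graph(rng: np.random.Generator, n_nodes: int, n_parents: int = 3):
    """Random graph in which every gene has *n_parents* upstream regulators.

    Used for null calibration: with several regulators (and hence typically
    several targets) per gene, the null distribution of |T| is close to
    continuous, so empirical p-values are close to uniform.  At in-degree 1
    the statistic has large atoms (|consistency| = 1, impact = 0) and the
    permutation test is conservative there by construction.
    """
    genes = [f"N{i}" for i in range(n_nodes)]
    triples = set()
    for i in range(n_nodes):
        for j in rng.choice(n_nodes - 1, size=n_parents, replace=False):
            j = int(j) if j < i else int(j) + 1  # uniform parent != i
            triples.add((genes[j], genes[i], 1 if rng.random() < 0.5 else -1))
    edges = [SignedEdge(u, v, s) for u, v, s in sorted(triples)]
    return PathwayGraph("regulated", set(genes), edges)


# --------------------------------------------------------- impact oracle

def _supported(graph: PathwayGraph, expr: ExpressionTable):
    """Supported edge list under the sign rule, computed directly."""

    def sgn(x):
        return (x > 0) - (x < 0)

    out = []
    for e in graph.edges:
        su, sv = sgn(expr.get(e.source)), sgn(expr.get(e.target))
        if su != 0 and sv != 0 and su * e.sign == sv:
            out.append((e.source, e.target))
    return out


def brute_force_impact(
    graph: PathwayGraph,
    expr: ExpressionTable,
    gene: str,
    alpha: float = 1.0,
    max_depth: int | None = None,
) -> float:
    """Enumerate every simple supported path from *gene*; min depth per node."""
    adj: dict[str, list[str]] = {}
    for u, v in _supported(graph, expr):
        adj.setdefault(u, []).append(v)

    best: dict[str, int] = {}

    def dfs(node: str, depth: int, on_path: set[str]) -> None:
        for v in adj.get(node, []):
            if v in on_path:
                continue
            d = depth + 1
            if max_depth is not None and d > max_depth:
                continue
            if v not in best or d < best[v]:
                best[v] = d
            dfs(v, d, on_path | {v})

    dfs(gene, 0, {gene})
    return sum(abs(expr.get(v)) * math.exp(-alpha * d) for v, d in best.items())


# ------------------------------------------------- regulome oracles

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_force_loop_assignment(
    loops: list[Loop],
    genes: dict,
    regulators: list[GenomicInterval],
    promoter_window: int,
    hops: int,
) -> dict[str, set[GenomicInterval]]:
    """All-pairs anchor merging (union-find) + BFS over the component graph."""
    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.extend((lp.anchor_a, lp.anchor_b))
    uf = _UnionFind(len(anchors))
    for i, j in combinations(range(len(anchors)), 2):
        if _overlap(anchors[i], anchors[j]):
            uf.union(i, j)
    comp = [uf.find(i) for i in range(len(anchors))]

    comp_edges: dict[int, set[int]] = {}
    for k in range(len(loops)):
        a, b = comp[2 * k], comp[2 * k + 1]
        comp_edges.setdefault(a, set()).add(b)
        comp_edges.setdefault(b, set()).add(a)

    def comps_overlapping(iv: GenomicInterval) -> set[int]:
        return {comp[i] for i, a in enumerate(anchors) if _overlap(a, iv)}

    def within_hops(starts: set[int]) -> set[int]:
        # breadth-first so each component is seen at its minimum hop count
        from collections import deque

        reached = set(starts)
        frontier = deque((c, 0) for c in starts)
        while frontier:
            c, d = frontier.popleft()
            if d >= hops:
                continue
            for m in comp_edges.get(c, ()):
                if m not in reached:
                    reached.add(m)
                    frontier.append((m, d + 1))
        return reached

    result: dict[str, set[GenomicInterval]] = {}
    for gene, ann in genes.items():
        prom = GenomicInterval(ann.chrom, max(0, ann.tss - promoter_window), ann.tss + promoter_window + 1)
        near = within_hops(comps_overlapping(prom))
        assigned = {r for r in regulators if comps_overlapping(r) & near}
        if assigned:
            result[gene] = assigned
    return result


def brute_force_proximity(
    genes: dict, regulators: list[GenomicInterval], max_distance: int
) -> dict[str, set[GenomicInterval]]:
    """Per-base distance enumeration over every position of every region."""
    result: dict[str, set[GenomicInterval]] = {}
    for gene, ann in genes.items():
        for r in regulators:
            if r.chrom != ann.chrom:
                continue
            dist = min(abs(p - ann.tss) for p in range(r.start, r.end))
            if dist <= max_distance:
                result.setdefault(gene, set()).add(r)
    return result


def random_regulome(rng: np.random.Generator, n_loops: int, n_regions: int, n_genes: int):
    """Random loops/regions/genes on two small chromosomes for oracle checks."""
    from tripath.graph_model import GeneAnnotation

    def iv() -> GenomicInterval:
        chrom = "chrA" if rng.random() < 0.8 else "chrB"
        start = int(rng.integers(0, 5000))
        return GenomicInterval(chrom, start, start + int(rng.integers(50, 400)))

    loops = [Loop(iv(), iv()) for _ in range(n_loops)]
    regions = [iv() for _ in range(n_regions)]
    genes = {
        f"G{i}": GeneAnnotation(
            gene=f"G{i}",
            chrom="chrA" if rng.random() < 0.8 else "chrB",
            tss=int(rng.integers(0, 5400)),
            strand="+" if rng.random() < 0.5 else "-",
        )
        for i in range(n_genes)
    }
    return loops, regions, genes


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def chain_graph():
    """g(+1) -act-> v1(+2) -act-> v2(+0.5): both edges supported."""
    graph = PathwayGraph(
        "chain", {"g", "v1", "v2"}, [SignedEdge("g", "v1", 1), SignedEdge("v1", "v2", 1)]
    )
    expr = ExpressionTable({"g": 1.0, "v1": 2.0, "v2": 0.5})
    return graph, expr


@pytest.fixture
def fan_in_graph():
    """A -act-> g <-inh- B with expr A=+1, B=+3, g=+2."""
    graph = PathwayGraph(
        "fan", {"A", "B", "g"}, [SignedEdge("A", "g", 1), SignedEdge("B", "g", -1)]
    )
    expr = ExpressionTable({"A": 1.0, "B": 3.0, "g": 2.0})
    return graph, expr
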