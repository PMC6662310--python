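"""Per-gene perturbation scoring on signed pathway graphs.

For each gene g with observed signed expression statistic e(g), an upstream
edge u->g with sign s predicts the direction sign(e(u))*s for g.  Upstream
evidence is summed into

    support(g)       = sum of |e(u)| over edges whose prediction matches sign(e(g)),
    inconsistency(g) = sum of |e(u)| over edges whose prediction opposes sign(e(g)),
    consistency(g)   = (support - inconsistency) / (support + inconsistency),

with consistency defined as 0 when there is no measured upstream evidence.
Consistency lies in [-1, 1]; negative values mark genes whose expression goes
against what their regulators predict, i.e. perturbed genes.

The downstream effect of g is quantified by impact: a breadth-first search
from g traverses an edge x->v only when the edge is *supported*
(sign(e(v)) = sign(e(x)) * sign(x->v), both nonzero), and every reached gene
contributes its magnitude damped exponentially in its BFS depth:

    impact(g) = sum over reached v of |e(v)| * exp(-alpha * depth(v)).

Consistency, impact and (optionally) the count of non-coding regulators are
combined into the triangulation score

    T(g) = consistency(g) * (1 + impact(g)) * w_reg,
    w_reg = 1 + log2(1 + n_regulators)   (or 1 with regulator weighting off),

which keeps the sign of consistency, never shrinks when impact or regulator
count grows, and is used to rank genes within a pathway: strongly negative T
flags perturbation origins with large downstream reach.

Zero expression is neutral throughout: it contributes to neither support nor
inconsistency and blocks BFS traversal (no direction, no evidence).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph_model import ExpressionTable, PathwayGraph


class ParameterError(ValueError):
    """A scoring parameter is outside its valid range."""


@dataclass
class ScoringParams:
    """Tunable scoring parameters.

    decay_rate
        Exponential decay constant alpha (per edge hop) applied to downstream
        magnitudes; must be positive.  Default 1.0 halves-ish each hop
        (e^-1 ~ 0.37).
    max_depth
        Optional cap on BFS depth; ``None`` means unbounded.
    regulator_weighting
        When True, the triangulation score is amplified by
        1 + log2(1 + n_regulators); with no assigned regulators this is a
        no-op, so the default is True.
    """

    decay_rate: float = 1.0
    max_depth: int | None = None
    regulator_weighting: bool = True

    def __post_init__(self) -> None:
        if not self.decay_rate > 0:
            raise ParameterError(f"decay_rate must be positive, got {self.decay_rate}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ParameterError(f"max_depth must be >= 1 when bounded, got {self.max_depth}")


@dataclass
class GeneScoreRecord:
    """All scores for one gene in one pathway; p-values are filled in later."""

    gene: str
    pathway_id: str
    support: float
    inconsistency: float
    consistency: float
    impact: float
    n_regulators: int
    triangulation: float
    p_triangulation: float = math.nan
    p_regulators: float = math.nan


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def upstream_consistency(
    graph: PathwayGraph, expr: ExpressionTable, gene: str
) -> tuple[float, float, float]:
    """Support, inconsistency and consistency of *gene* from its upstream edges."""
    support = 0.0
    inconsistency = 0.0
    sg = _sign(expr.get(gene))
    for u, s in graph.in_edges(gene):
        su = _sign(expr.get(u))
        if su == 0 or sg == 0:
            continue
        if su * s == sg:
            support += abs(expr.get(u))
        else:
            inconsistency += abs(expr.get(u))
    total = support + inconsistency
    consistency = 0.0 if total == 0 else (support - inconsistency) / total
    return support, inconsistency, consistency


def supported_downstream_subgraph(
    graph: PathwayGraph,
    expr: ExpressionTable,
    gene: str,
    max_depth: int | None = None,
) -> dict[str, int]:
    """BFS map of downstream genes reachable through supported edges only.

    An edge x->v is supported when sign(e(v)) = sign(e(x)) * sign(x->v) with
    both expressions nonzero.  Depth is the minimum number of supported edges
    from *gene*; the source gene itself is excluded.
    """
    graph._require(gene)
    depths: dict[str, int] = {}
    queue: deque[tuple[str, int]] = deque([(gene, 0)])
    visited = {gene}
    while queue:
        x, d = queue.popleft()
        if max_depth is not None and d >= max_depth:
            continue
        sx = _sign(expr.get(x))
        if sx == 0:
            continue
        for v, s in graph.out_edges(x):
            if v in visited:
                continue
            if _sign(expr.get(v)) == sx * s and _sign(expr.get(v)) != 0:
                visited.add(v)
                depths[v] = d + 1
                queue.append((v, d + 1))
    return depths


def impact(
    graph: PathwayGraph,
    expr: ExpressionTable,
    gene: str,
    params: ScoringParams | None = None,
) -> float:
    """Decay-weighted downstream magnitude of *gene* over its supported subgraph."""
    params = params or ScoringParams()
    sub = supported_downstream_subgraph(graph, expr, gene, params.max_depth)
    return sum(abs(expr.get(v)) * math.exp(-params.decay_rate * d) for v, d in sub.items())


def triangulation(
    consistency: float,
    impact_value: float,
    n_regulators: int,
    params: ScoringParams | None = None,
) -> float:
    """Sign-preserving combination of consistency, impact and regulator count."""
    params = params or ScoringParams()
    w_reg = 1.0 + math.log2(1 + n_regulators) if params.regulator_weighting else 1.0
    return consistency * (1.0 + impact_value) * w_reg


def score_pathway(
    graph: PathwayGraph,
    expr: ExpressionTable,
    assignments=None,
    params: ScoringParams | None = None,
) -> list[GeneScoreRecord]:
    """Score every gene of *graph*: one :class:`GeneScoreRecord` per node.

    *assignments* is an optional :class:`~tripath.noncoding.RegulatorAssignment`
    supplying per-gene non-coding regulator counts (0 when absent).  p-value
    fields are left NaN; the significance module fills them.
    """
    params = params or ScoringParams()
    compiled = CompiledPathway(graph)
    n_reg = np.zeros(len(compiled.genes), dtype=int)
    if assignments is not None:
        for i, g in enumerate(compiled.genes):
            n_reg[i] = assignments.count(g)
    e = compiled.expression_vector(expr)
    support, incons, cons, imp = compiled.component_scores(e, params)
    tri = compiled.triangulation_vector(cons, imp, n_reg, params)
    return [
        GeneScoreRecord(
            gene=g,
            pathway_id=graph.pathway_id,
            support=float(support[i]),
            inconsistency=float(incons[i]),
            consistency=float(cons[i]),
            impact=float(imp[i]),
            n_regulators=int(n_reg[i]),
            triangulation=float(tri[i]),
        )
        for i, g in enumerate(compiled.genes)
    ]


class CompiledPathway:
    """Index-based representation of a pathway for repeated (permuted) scoring.

    Gene symbols are mapped to integer indices once; scoring then works on a
    dense expression vector, which keeps the permutation test's inner loop
    cheap.  Produces results identical to the per-gene functions above.
    """

    def __init__(self, graph: PathwayGraph):
        self.graph = graph
        self.genes: list[str] = sorted(graph.nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        self.edge_u = np.array([self.index[e.source] for e in graph.edges], dtype=np.intp)
        self.edge_v = np.array([self.index[e.target] for e in graph.edges], dtype=np.intp)
        self.edge_s = np.array([e.sign for e in graph.edges], dtype=np.int8)

    def expression_vector(self, expr: ExpressionTable) -> np.ndarray:
        """Dense expression over the node order; unmeasured genes get 0."""
        return np.array([expr.get(g) for g in self.genes], dtype=float)

    def component_scores(
        self, e: np.ndarray, params: ScoringParams
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(support, inconsistency, consistency, impact) arrays for vector *e*."""
        n = len(self.genes)
        support = np.zeros(n)
        incons = np.zeros(n)
        if len(self.edge_u):
            su = np.sign(e[self.edge_u])
            sv = np.sign(e[self.edge_v])
            pred = su * self.edge_s
            measured = (su != 0) & (sv != 0)
            supporting = measured & (pred == sv)
            inconsistent = measured & (pred == -sv)
            mag_u = np.abs(e[self.edge_u])
            np.add.at(support, self.edge_v[supporting], mag_u[supporting])
            np.add.at(incons, self.edge_v[inconsistent], mag_u[inconsistent])
        else:
            supporting = np.zeros(0, dtype=bool)
        total = support + incons
        with np.errstate(invalid="ignore"):
            cons = np.where(total > 0, (support - incons) / np.where(total > 0, total, 1.0), 0.0)
        imp = self._impact_all(e, supporting, params)
        return support, incons, cons, imp

    def _impact_all(
        self, e: np.ndarray, supported_mask: np.ndarray, params: ScoringParams
    ) -> np.ndarray:
        n = len(self.genes)
        # adjacency restricted to supported edges; same condition as "supporting"
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in zip(self.edge_u[supported_mask], self.edge_v[supported_mask]):
            adj[u].append(v)
        mag = np.abs(e)
        alpha = params.decay_rate
        max_depth = params.max_depth
        decay = [1.0]
        imp = np.zeros(n)
        visited = np.full(n, -1, dtype=np.intp)
        for src in range(n):
            if not adj[src]:
                continue
            total = 0.0
            visited[src] = src
            queue = deque([(src, 0)])
            while queue:
                x, d = queue.popleft()
                if max_depth is not None and d >= max_depth:
                    continue
                nd = d + 1
                while len(decay) <= nd:
                    decay.append(math.exp(-alpha * len(decay)))
                for v in adj[x]:
                    if visited[v] != src:
                        visited[v] = src
                        total += mag[v] * decay[nd]
                        queue.append((v, nd))
            imp[src] = total
        return imp

    def triangulation_vector(
        self, cons: np.ndarray, imp: np.ndarray, n_reg: np.ndarray, params: ScoringParams
    ) -> np.ndarray:
        w = 1.0 + np.log2(1 + n_reg) if params.regulator_weighting else 1.0
        return cons * (1.0 + imp) * w

    def triangulation_scores(
        self, e: np.ndarray, n_reg: np.ndarray, params: ScoringParams
    ) -> np.ndarray:
        """Triangulation vector for expression vector *e* (permutation inner loop)."""
        _, _, cons, imp = self.component_scores(e, params)
        return self.triangulation_vector(cons, imp, n_reg, params)


def write_scores_tsv(records: Sequence[GeneScoreRecord], path, extra: Mapping[str, Mapping[str, float]] | None = None) -> None:
    """Write score records as a TSV with a stable column order, 6 sig. digits.

    *extra* optionally maps column name -> {(pathway, gene) key -> value} for
    appended columns such as a BH-adjusted p-value.
    """
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "pathway_id": r.pathway_id,
            "gene": r.gene,
            "support": r.support,
            "inconsistency": r.inconsistency,
            "consistency": r.consistency,
            "impact": r.impact,
            "n_regulators": r.n_regulators,
            "triangulation": r.triangulation,
            "p_triangulation": r.p_triangulation,
            "p_regulators": r.p_regulators,
        }
        if extra:
            for col, mapping in extra.items():
                row[col] = mapping.get((r.pathway_id, r.gene), math.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    df[float_cols] = df[float_cols].map(lambda x: float(f"{x:.6g}"))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
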