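"""Empirical and parametric significance for pathway perturbation scores.

Triangulation scores get permutation p-values: the multiset of expression
values is repeatedly re-assigned at random across the genes of the expression
table (topology and regulator counts stay fixed), triangulation is recomputed,
and

    p(g) = (1 + #{i : |T_i(g)| >= |T_obs(g)|}) / (n_permutations + 1).

The comparison is two-sided on |T| because both tails are of interest:
strongly negative scores flag perturbed genes, strongly positive ones flag
genes highly supported by their regulators.  The +1 pseudocount keeps p in
(0, 1].

Regulator counts get a Poisson upper-tail p-value, P(X >= k) with X ~
Poisson(lambda), where lambda is the mean number of regulator assignments per
gene over the annotated universe — regulator density is treated as a
genome-scale background rate rather than a per-pathway one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .graph_model import ExpressionTable, PathwayGraph
from .scoring import CompiledPathway, GeneScoreRecord, ParameterError, ScoringParams

logger = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ParameterError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )


def permutation_pvalues(
    graph: PathwayGraph,
    expr: ExpressionTable,
    assignments=None,
    params: ScoringParams | None = None,
    config: PermutationConfig | None = None,
) -> dict[str, float]:
    """Two-sided permutation p-value of the triangulation score per gene.

    Shuffling happens over *all* genes of the expression table, not only those
    in the pathway, so the null reflects the full measured value pool.
    Deterministic for a given ``config.rng_seed``.
    """
    params = params or ScoringParams()
    config = config or PermutationConfig()
    if len(expr) == 0:
        raise ParameterError("expression table is empty; cannot permute")

    compiled = CompiledPathway(graph)
    n_reg = np.zeros(len(compiled.genes), dtype=int)
    if assignments is not None:
        for i, g in enumerate(compiled.genes):
            n_reg[i] = assignments.count(g)

    table_genes = expr.genes()
    table_pos = {g: i for i, g in enumerate(table_genes)}
    values = np.array([expr.expr[g] for g in table_genes], dtype=float)
    # position of each pathway gene in the shuffled value vector (-1: unmeasured)
    pos = np.array([table_pos.get(g, -1) for g in compiled.genes], dtype=np.intp)
    measured = pos >= 0

    e_obs = compiled.expression_vector(expr)
    t_obs = np.abs(compiled.triangulation_scores(e_obs, n_reg, params))

    rng = np.random.default_rng(config.rng_seed)
    hits = np.zeros(len(compiled.genes), dtype=np.int64)
    e_perm = np.zeros(len(compiled.genes))
    for _ in range(config.n_permutations):
        shuffled = rng.permutation(values)
        e_perm[measured] = shuffled[pos[measured]]
        t_perm = np.abs(compiled.triangulation_scores(e_perm, n_reg, params))
        hits += t_perm >= t_obs
    p = (1.0 + hits) / (config.n_permutations + 1.0)
    return {g: float(p[i]) for i, g in enumerate(compiled.genes)}


def poisson_pvalue(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k); equals 1 when k = 0."""
    if k < 0 or int(k) != k:
        raise ParameterError(f"k must be a non-negative integer, got {k}")
    if not lam > 0:
        raise ParameterError(f"lambda must be positive, got {lam}")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def estimate_lambda(assignments, universe: set[str]) -> float:
    """Mean regulator assignments per gene over the annotated gene universe."""
    if not universe:
        raise ParameterError("gene universe is empty")
    total = sum(assignments.count(g) for g in universe) if assignments is not None else 0
    return total / len(universe)


def regulator_pvalues(assignments, universe: set[str], genes: Sequence[str]) -> dict[str, float]:
    """Poisson enrichment p-value of each gene's regulator count.

    With a zero background rate (no assignments anywhere) every p-value is 1
    and a warning is logged.
    """
    lam = estimate_lambda(assignments, universe)
    if lam == 0:
        logger.warning("regulator background rate is 0; all Poisson p-values set to 1")
        return {g: 1.0 for g in genes}
    counts = {g: (assignments.count(g) if assignments is not None else 0) for g in genes}
    return {g: poisson_pvalue(k, lam) for g, k in counts.items()}


def attach_significance(
    records: Sequence[GeneScoreRecord],
    p_triangulation: Mapping[str, float],
    p_regulators: Mapping[str, float] | None = None,
) -> None:
    """Fill the p-value fields of *records* in place."""
    for r in records:
        r.p_triangulation = p_triangulation[r.gene]
        if p_regulators is not None:
            r.p_regulators = p_regulators[r.gene]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional output column; off by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
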