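"""Synthetic pathway / expression / regulome fixtures with planted structure.

The generator builds study conditions in which the truth is known exactly:

* a random signed DAG whose edge signs are derived from latent per-gene
  activity signs, so that unperturbed expression propagates *consistently*
  along every edge (child sign = parent sign x edge sign).  Magnitudes are
  drawn as |N(2, sd)|, which keeps signs unambiguous even at sd = 0;
* a configurable number of planted perturbed genes whose expression sign is
  flipped against all of their upstream predictions.  Perturbations are
  planted at terminal genes (no outgoing edges) with at least one upstream
  regulator, so the inconsistency is attributable to the planted gene itself
  rather than propagated into downstream genes it solely controls;
* a synthetic regulome on one 10-Mb chromosome "chrS" laid out on a fixed
  grid (one 200-kb block per gene), wiring a planted number of regulator
  regions to each gene through one-hop loops, plus decoy loops and regions
  placed far from every promoter.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_model import (
    ExpressionTable,
    GeneAnnotation,
    PathwayGraph,
    SignedEdge,
    write_annotation,
    write_expression,
    write_pathway_graph,
)
from .noncoding import GenomicInterval, Loop, write_bed, write_bedpe

CHROM = "chrS"
CHROM_SIZE = 10_000_000
GENE_BLOCK = 200_000  # bp of synthetic chromosome reserved per gene


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults give a mid-sized pathway (30 genes, ~10% edge density, 70%
    activation edges) with one planted perturbed gene, moderate magnitude
    noise, and a regulome of 40 loops / 60 candidate regions.
    """

    n_genes: int = 30
    edge_probability: float = 0.1
    activation_fraction: float = 0.7
    n_planted_perturbed: int = 1
    expr_noise_sd: float = 0.25
    n_loops: int = 40
    n_regulators: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        for name in ("edge_probability", "activation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_planted_perturbed", "expr_noise_sd", "n_loops", "n_regulators"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_planted_perturbed > self.n_genes:
            raise ValueError("n_planted_perturbed cannot exceed n_genes")


def _latent_sign_probability(activation_fraction: float) -> float:
    # Edge sign is the product of endpoint latent signs s_u * s_v, so the
    # activation fraction is q^2 + (1-q)^2 with q = P(latent sign +).  Solve
    # for q; fractions below 1/2 take the mirrored root.
    a = min(max(activation_fraction, 0.0), 1.0)
    if a < 0.5:
        return 0.5  # q=0.5 gives the minimum attainable activation fraction 0.5
    return 0.5 * (1.0 + math.sqrt(2.0 * a - 1.0))


def make_pathway(
    spec: FixtureSpec,
) -> tuple[PathwayGraph, ExpressionTable, set[str]]:
    """Random consistent pathway with planted perturbed genes.

    Returns (graph, expression, planted) where every non-planted gene's
    expression follows all its upstream predictions and every planted gene's
    sign is flipped against all of them.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    genes = [f"G{i:03d}" for i in range(n)]

    # latent activity signs make a globally consistent assignment possible
    q = _latent_sign_probability(spec.activation_fraction)
    latent = np.where(rng.random(n) < q, 1, -1)

    # upper-triangular random DAG over a random gene order
    order = rng.permutation(n)
    edges: list[SignedEdge] = []
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    parents: dict[int, list[int]] = {i: [] for i in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < spec.edge_probability:
                u, v = int(order[a]), int(order[b])
                sign = int(latent[u] * latent[v])
                edges.append(SignedEdge(genes[u], genes[v], sign))
                children[u].append(v)
                parents[v].append(u)

    # choose planted genes: terminal genes with upstream regulators, so the
    # planted inconsistency does not cascade into solely-controlled children
    candidates = [i for i in range(n) if parents[i] and not children[i]]
    if len(candidates) < spec.n_planted_perturbed:
        # wire parentless sinks to a donor so they become eligible
        for i in range(n):
            if len(candidates) >= spec.n_planted_perturbed:
                break
            if children[i] or parents[i]:
                continue
            donor = int(rng.integers(n))
            while donor == i or i in children[donor]:
                donor = int(rng.integers(n))
            sign = int(latent[donor] * latent[i])
            edges.append(SignedEdge(genes[donor], genes[i], sign))
            children[donor].append(i)
            parents[i].append(donor)
            candidates.append(i)
    if len(candidates) < spec.n_planted_perturbed:
        # last resort: non-terminal genes with parents, fewest children first
        extra = sorted(
            (i for i in range(n) if parents[i] and i not in candidates),
            key=lambda i: len(children[i]),
        )
        candidates.extend(extra)
    if spec.n_planted_perturbed:
        if len(candidates) < spec.n_planted_perturbed:
            raise ValueError(
                "graph too sparse to plant the requested number of perturbed genes"
            )
        chosen = rng.choice(len(candidates), size=spec.n_planted_perturbed, replace=False)
        planted = {candidates[int(i)] for i in np.atleast_1d(chosen)}
    else:
        planted = set()

    magnitudes = np.abs(rng.normal(2.0, spec.expr_noise_sd, size=n))
    signs = latent.copy()
    for i in planted:
        signs[i] = -signs[i]
    expr = {genes[i]: float(signs[i] * magnitudes[i]) for i in range(n)}

    graph = PathwayGraph(
        pathway_id=f"synthetic_seed{spec.rng_seed}", nodes=set(genes), edges=edges
    )
    return graph, ExpressionTable(expr=expr), {genes[i] for i in planted}


def make_annotation(spec: FixtureSpec) -> dict[str, GeneAnnotation]:
    """Grid gene annotation on chrS: gene i's TSS at 100 kb into block i."""
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    return {
        g: GeneAnnotation(gene=g, chrom=CHROM, tss=i * GENE_BLOCK + 100_000, strand="+")
        for i, g in enumerate(genes)
    }


def make_regulome(
    spec: FixtureSpec, genes: dict[str, GeneAnnotation]
) -> tuple[list[Loop], list[GenomicInterval], dict[str, int]]:
    """Loops and regulator regions wiring planted counts to genes, plus decoys.

    Each gene receives a share of ``n_regulators`` regions, each connected to
    the gene's promoter anchor by its own one-hop loop.  Remaining loop
    budget becomes decoy loops between intervals in a dedicated band of each
    gene block, placed >= 50 kb from every TSS so neither loop nor proximity
    assignment (at defaults) can pick them up.  Returns
    (loops, regions, truth counts per gene).
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    gene_list = list(genes)
    n = len(gene_list)
    counts = rng.multinomial(spec.n_regulators, np.full(n, 1.0 / n)) if n else []

    loops: list[Loop] = []
    regions: list[GenomicInterval] = []
    truth: dict[str, int] = {}
    for i, g in enumerate(gene_list):
        tss = genes[g].tss
        truth[g] = int(counts[i])
        promoter_anchor = GenomicInterval(CHROM, tss - 500, tss + 500)
        for j in range(int(counts[i])):
            # regulator band: 20-56 kb downstream of the TSS, 400-bp regions
            start = tss + 20_000 + j * 600
            region = GenomicInterval(CHROM, start, start + 400)
            regions.append(region)
            loops.append(Loop(promoter_anchor, region, score=float(rng.integers(2, 30))))

    # decoy band sits 65-95 kb past each TSS: beyond the regulator band and
    # >= 50 kb from every TSS, so decoys are invisible at default windows
    n_decoys = max(0, spec.n_loops - sum(truth.values()))
    for j in range(n_decoys):
        block = int(rng.integers(n)) if n else 0
        base = block * GENE_BLOCK + 165_000 + (j % 14) * 2_000
        a = GenomicInterval(CHROM, base, base + 400)
        b = GenomicInterval(CHROM, base + 1_000, base + 1_400)
        loops.append(Loop(a, b, score=float(rng.integers(2, 30))))
    return loops, regions, truth


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete input set (pathway, expression, annotation, loops,
    regulators) in the formats the readers consume; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, expr, planted = make_pathway(spec)
    annotation = make_annotation(spec)
    loops, regions, truth = make_regulome(spec, annotation)

    pathway_dir = out / "pathways"
    pathway_dir.mkdir(exist_ok=True)
    paths = {
        "pathway": pathway_dir / f"{graph.pathway_id}.tsv",
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "loops": out / "loops.bedpe",
        "regulators": out / "regulators.bed",
        "truth": out / "truth.tsv",
    }
    write_pathway_graph(graph, paths["pathway"])
    write_expression(expr, paths["expression"])
    write_annotation(annotation, paths["annotation"])
    write_bedpe(loops, paths["loops"])
    write_bed(regions, paths["regulators"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tplanted_perturbed\tplanted_regulators\n")
        for g in sorted(graph.nodes):
            fh.write(f"{g}\t{int(g in planted)}\t{truth.get(g, 0)}\n")
    return paths
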