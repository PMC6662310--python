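"""Domain types and plain-text I/O for signed pathway graphs and expression tables.

A pathway is a directed graph whose nodes are gene symbols and whose edges
carry a sign: +1 for activation, -1 for inhibition.  Graphs are read from a
simple tab-separated edge list (``source<TAB>target<TAB>interaction``) so no
external pathway-database bridge is required; differential-expression input
is a two/three-column TSV mapping gene symbols to a signed statistic such as
a log2 fold change, with an optional adjusted p-value column.

Gene symbols are matched exactly after whitespace trimming; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Interaction tokens accepted in edge lists, mapped to edge signs.
SIGN_TOKENS = {"activation": +1, "inhibition": -1}
_TOKEN_OF_SIGN = {+1: "activation", -1: "inhibition"}


class GraphValidationError(ValueError):
    """A pathway graph violates a structural invariant (e.g. a self-loop)."""


class TableParseError(ValueError):
    """A tabular input file is malformed; the message carries the line number."""


@dataclass(frozen=True)
class SignedEdge:
    """A directed, signed gene-gene interaction.

    sign is +1 for activation (the source pushes the target's expression in
    the same direction) and -1 for inhibition (opposite direction).
    """

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise GraphValidationError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1, got {self.sign}"
            )
        if self.source == self.target:
            raise GraphValidationError(f"self-loop on gene {self.source!r} is not allowed")


@dataclass
class PathwayGraph:
    """A signed directed gene graph for one pathway.

    Invariants enforced at construction: every edge endpoint is a node, no
    self-loops, and no duplicated (source, target, sign) triple.  Parallel
    edges with opposite signs are allowed (curated pathways contain such
    pairs) and contribute to scoring independently.
    """

    pathway_id: str
    nodes: set[str]
    edges: list[SignedEdge]
    _in: dict[str, list[tuple[str, int]]] = field(init=False, repr=False)
    _out: dict[str, list[tuple[str, int]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        seen: set[tuple[str, str, int]] = set()
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise GraphValidationError(
                    f"edge {e.source}->{e.target} references a gene outside the node set"
                )
            triple = (e.source, e.target, e.sign)
            if triple in seen:
                raise GraphValidationError(
                    f"duplicate edge {e.source}->{e.target} ({_TOKEN_OF_SIGN[e.sign]})"
                )
            seen.add(triple)
        self._in = {g: [] for g in self.nodes}
        self._out = {g: [] for g in self.nodes}
        for e in self.edges:
            self._out[e.source].append((e.target, e.sign))
            self._in[e.target].append((e.source, e.sign))

    def in_edges(self, gene: str) -> list[tuple[str, int]]:
        """Upstream regulators of *gene* as (source, sign) pairs."""
        self._require(gene)
        return list(self._in[gene])

    def out_edges(self, gene: str) -> list[tuple[str, int]]:
        """Downstream targets of *gene* as (target, sign) pairs."""
        self._require(gene)
        return list(self._out[gene])

    def _require(self, gene: str) -> None:
        if gene not in self.nodes:
            raise KeyError(f"gene {gene!r} is not in pathway {self.pathway_id!r}")

    def to_networkx(self) -> nx.MultiDiGraph:
        """Export as a networkx MultiDiGraph with a ``sign`` edge attribute."""
        g = nx.MultiDiGraph(pathway_id=self.pathway_id)
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g


@dataclass
class ExpressionTable:
    """Per-gene signed differential-expression statistic.

    ``expr`` maps each measured gene to a finite signed real (e.g. log2 fold
    change); ``sig`` optionally maps genes to an adjusted p-value in [0, 1].
    Genes that were not measured are simply absent, never NaN.
    """

    expr: dict[str, float]
    sig: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        for g, v in self.expr.items():
            if not math.isfinite(v):
                raise TableParseError(f"expression for gene {g!r} is not finite")

    def __len__(self) -> int:
        return len(self.expr)

    def __contains__(self, gene: str) -> bool:
        return gene in self.expr

    def get(self, gene: str, default: float = 0.0) -> float:
        """Expression of *gene*, or *default* (0 = unmeasured/neutral)."""
        return self.expr.get(gene, default)

    def genes(self) -> list[str]:
        return list(self.expr)


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS-anchored annotation of one gene: chromosome, 0-based TSS, strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise TableParseError(f"gene {self.gene!r}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise TableParseError(f"gene {self.gene!r}: strand must be + or -, got {self.strand!r}")


@dataclass
class UniverseReport:
    """Measured/unmeasured breakdown produced by :func:`intersect_universe`."""

    pathway_id: str
    n_measured: int
    n_unmeasured: int
    unmeasured: set[str]


def read_pathway_graph(path: str | Path) -> PathwayGraph:
    """Read a pathway edge list.

    Format: header ``source<TAB>target<TAB>interaction``; interaction is
    ``activation`` or ``inhibition``; ``#``-prefixed lines are comments except
    ``#node:<symbol>`` lines, which declare isolated nodes.  The pathway id is
    the file stem.
    """
    path = Path(path)
    declared: list[str] = []
    edges: list[SignedEdge] = []
    nodes: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#node:"):
                declared.append(line[len("#node:"):].strip())
            continue
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if fields[:3] != ["source", "target", "interaction"]:
                raise TableParseError(
                    f"{path}:{lineno}: expected header 'source\\ttarget\\tinteraction'"
                )
            header_seen = True
            continue
        if len(fields) < 3:
            raise TableParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        src, tgt, token = fields[0], fields[1], fields[2]
        if token not in SIGN_TOKENS:
            raise TableParseError(
                f"{path}:{lineno}: unknown interaction {token!r} "
                f"(expected one of {sorted(SIGN_TOKENS)})"
            )
        try:
            edge = SignedEdge(src, tgt, SIGN_TOKENS[token])
        except GraphValidationError as exc:
            raise GraphValidationError(f"{path}:{lineno}: {exc}") from None
        edges.append(edge)
        nodes.update((src, tgt))
    if not header_seen:
        raise TableParseError(f"{path}: missing header row")
    nodes.update(declared)
    return PathwayGraph(pathway_id=path.stem, nodes=nodes, edges=edges)


def write_pathway_graph(graph: PathwayGraph, path: str | Path) -> None:
    """Write *graph* in the edge-list format read by :func:`read_pathway_graph`."""
    path = Path(path)
    endpoint_nodes = {e.source for e in graph.edges} | {e.target for e in graph.edges}
    with open(path, "w") as fh:
        for g in sorted(graph.nodes - endpoint_nodes):
            fh.write(f"#node:{g}\n")
        fh.write("source\ttarget\tinteraction\n")
        for e in graph.edges:
            fh.write(f"{e.source}\t{e.target}\t{_TOKEN_OF_SIGN[e.sign]}\n")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a ``gene<TAB>expr[<TAB>sig]`` TSV into an :class:`ExpressionTable`."""
    path = Path(path)
    expr: dict[str, float] = {}
    sig: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    has_sig = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if fields[:2] != ["gene", "expr"]:
                raise TableParseError(f"{path}:{lineno}: expected header 'gene\\texpr[\\tsig]'")
            has_sig = len(fields) >= 3 and fields[2] == "sig"
            header_seen = True
            continue
        gene = fields[0]
        if gene in expr:
            raise TableParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
        try:
            value = float(fields[1])
        except (ValueError, IndexError):
            raise TableParseError(
                f"{path}:{lineno}: non-numeric expr for gene {gene!r}"
            ) from None
        import math

        if not math.isfinite(value):
            raise TableParseError(f"{path}:{lineno}: non-finite expr for gene {gene!r}")
        expr[gene] = value
        if has_sig and len(fields) >= 3 and fields[2] != "":
            try:
                sig[gene] = float(fields[2])
            except ValueError:
                raise TableParseError(
                    f"{path}:{lineno}: non-numeric sig for gene {gene!r}"
                ) from None
    if not header_seen:
        raise TableParseError(f"{path}: missing header row")
    return ExpressionTable(expr=expr, sig=sig)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if table.sig:
            fh.write("gene\texpr\tsig\n")
            for g, v in table.expr.items():
                s = table.sig.get(g, "")
                fh.write(f"{g}\t{v:.10g}\t{s if s == '' else format(s, '.10g')}\n")
        else:
            fh.write("gene\texpr\n")
            for g, v in table.expr.items():
                fh.write(f"{g}\t{v:.10g}\n")


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a ``gene<TAB>chrom<TAB>tss<TAB>strand`` TSV (tss is 0-based).

    One record per gene; a duplicated gene symbol is an error naming the gene.
    """
    path = Path(path)
    out: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if fields[:4] != ["gene", "chrom", "tss", "strand"]:
                raise TableParseError(
                    f"{path}:{lineno}: expected header 'gene\\tchrom\\ttss\\tstrand'"
                )
            header_seen = True
            continue
        if len(fields) < 4:
            raise TableParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        gene = fields[0]
        if gene in out:
            raise TableParseError(f"{path}:{lineno}: duplicate annotation for gene {gene!r}")
        try:
            tss = int(fields[2])
        except ValueError:
            raise TableParseError(f"{path}:{lineno}: non-integer tss for gene {gene!r}") from None
        out[gene] = GeneAnnotation(gene=gene, chrom=fields[1], tss=tss, strand=fields[3])
    if not header_seen:
        raise TableParseError(f"{path}: missing header row")
    return out


def write_annotation(annotation: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for rec in annotation.values():
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")


def intersect_universe(
    graph: PathwayGraph, table: ExpressionTable
) -> tuple[PathwayGraph, ExpressionTable, UniverseReport]:
    """Reconcile a pathway's gene universe with the measured expression table.

    Topology is never altered: genes present in the graph but absent from the
    table are retained and flagged unmeasured; scoring treats their expression
    as 0, so they contribute no directional evidence.
    """
    unmeasured = {g for g in graph.nodes if g not in table}
    report = UniverseReport(
        pathway_id=graph.pathway_id,
        n_measured=len(graph.nodes) - len(unmeasured),
        n_unmeasured=len(unmeasured),
        unmeasured=unmeasured,
    )
    if report.n_measured == 0 and graph.nodes:
        logger.warning(
            "pathway %s: no gene overlaps the expression table (%d nodes all unmeasured)",
            graph.pathway_id,
            len(graph.nodes),
        )
    else:
        logger.info(
            "pathway %s: %d measured, %d unmeasured genes",
            graph.pathway_id,
            report.n_measured,
            report.n_unmeasured,
        )
    return graph, table, report
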