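"""Non-coding regulator assignment via chromatin-loop networks or TSS proximity.

Chromatin loops (ChIA-PET / HiC / HiChIP, read from BEDPE) are turned into an
anchor network: loop anchors that overlap by at least one base pair on the
same chromosome are merged transitively into single nodes, and each loop
becomes an edge between the nodes containing its anchors.  A gene's promoter
window attaches it to the nodes it overlaps; a candidate regulator region
(e.g. an open-chromatin peak, read from BED) attaches likewise, and the
regulator is assigned to the gene when their nodes lie within a configurable
number of network hops (default 1 = direct interaction, 0 hops = same node).

When no loop data are available, assignment falls back to linear proximity:
a region is assigned to a gene when its closest base lies within a
user-defined distance of the gene's TSS on the same chromosome.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from intervaltree import IntervalTree

from .graph_model import GeneAnnotation, TableParseError
from .scoring import ParameterError

#: Default promoter half-window around the TSS (bp) for loop attachment.
DEFAULT_PROMOTER_WINDOW = 2500
#: Default maximum number of network hops between promoter and regulator nodes.
DEFAULT_HOPS = 1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two anchors (possibly inter-chromosomal)."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float | None = None


@dataclass
class ChromatinNetwork:
    """Anchor-merged loop network: nodes are disjoint intervals, edges are loops."""

    nodes: list[GenomicInterval]
    edges: list[tuple[int, int]]
    graph: nx.Graph = field(repr=False)
    _trees: dict[str, IntervalTree] = field(repr=False)

    def nodes_overlapping(self, interval: GenomicInterval) -> list[int]:
        """Indices of network nodes overlapping *interval* (>= 1 bp)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(interval.start, interval.end))

    def nodes_within_hops(self, start_nodes: Iterable[int], hops: int) -> set[int]:
        """All node indices reachable from *start_nodes* in <= *hops* edges."""
        reached = set(start_nodes)
        frontier = deque((n, 0) for n in reached)
        while frontier:
            n, d = frontier.popleft()
            if d >= hops:
                continue
            for m in self.graph.neighbors(n):
                if m not in reached:
                    reached.add(m)
                    frontier.append((m, d + 1))
        return reached


@dataclass
class RegulatorAssignment:
    """Map gene -> set of assigned regulator regions, with provenance.

    Provenance per (gene, region) is ``"loop"`` or ``"proximity"``.  Regions
    are deduplicated per gene (set semantics): a region reached through two
    loops still counts once.
    """

    _by_gene: dict[str, dict[GenomicInterval, str]] = field(default_factory=dict)

    def add(self, gene: str, region: GenomicInterval, provenance: str) -> None:
        self._by_gene.setdefault(gene, {})[region] = provenance

    def genes(self) -> list[str]:
        return list(self._by_gene)

    def regions(self, gene: str) -> set[GenomicInterval]:
        return set(self._by_gene.get(gene, {}))

    def provenance(self, gene: str, region: GenomicInterval) -> str | None:
        return self._by_gene.get(gene, {}).get(region)

    def count(self, gene: str) -> int:
        return len(self._by_gene.get(gene, {}))

    def total(self) -> int:
        return sum(len(d) for d in self._by_gene.values())


def build_network(loops: Sequence[Loop]) -> ChromatinNetwork:
    """Merge loop anchors into a chromatin interaction network.

    Anchors overlapping by >= 1 bp on the same chromosome merge transitively
    into single nodes; each input loop becomes exactly one edge (a self-edge
    when both anchors land in the same merged node).
    """
    if not loops:
        raise ParameterError("cannot build a chromatin network from zero loops")
    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.extend((lp.anchor_a, lp.anchor_b))

    # sweep-merge per chromosome
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    nodes: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >=1 bp overlap (half-open)
                cur_end = max(cur_end, iv.end)
            else:
                nodes.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        nodes.append(GenomicInterval(chrom, cur_start, cur_end))

    trees: dict[str, IntervalTree] = {}
    for i, node in enumerate(nodes):
        trees.setdefault(node.chrom, IntervalTree())[node.start:node.end] = i

    def node_of(anchor: GenomicInterval) -> int:
        hits = trees[anchor.chrom].overlap(anchor.start, anchor.end)
        assert len(hits) == 1, "merged nodes must uniquely contain each anchor"
        return next(iter(hits)).data

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    edges: list[tuple[int, int]] = []
    for lp in loops:
        ia, ib = node_of(lp.anchor_a), node_of(lp.anchor_b)
        edges.append((ia, ib))
        graph.add_edge(ia, ib)
    return ChromatinNetwork(nodes=nodes, edges=edges, graph=graph, _trees=trees)


def promoter_interval(annotation: GeneAnnotation, window: int) -> GenomicInterval:
    """Promoter window [tss - w, tss + w + 1), clipped at the chromosome start."""
    return GenomicInterval(
        annotation.chrom, max(0, annotation.tss - window), annotation.tss + window + 1
    )


def assign_by_loops(
    network: ChromatinNetwork,
    genes: Mapping[str, GeneAnnotation],
    regulators: Sequence[GenomicInterval],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    hops: int = DEFAULT_HOPS,
) -> RegulatorAssignment:
    """Assign regulator regions to genes through the chromatin network.

    A regulator is assigned to a gene when a node overlapping the regulator
    lies within *hops* network edges of a node overlapping the gene's
    promoter window (0 hops = they share a node).  Genes whose promoter
    touches no anchor simply receive no loop assignments.
    """
    if promoter_window < 0:
        raise ParameterError(f"promoter_window must be >= 0, got {promoter_window}")
    if hops < 1:
        raise ParameterError(f"hops must be >= 1, got {hops}")

    reg_nodes: dict[int, list[GenomicInterval]] = {}
    for region in regulators:
        for node_idx in network.nodes_overlapping(region):
            reg_nodes.setdefault(node_idx, []).append(region)

    assignment = RegulatorAssignment()
    for gene, ann in genes.items():
        prom_nodes = network.nodes_overlapping(promoter_interval(ann, promoter_window))
        if not prom_nodes:
            continue
        for node_idx in network.nodes_within_hops(prom_nodes, hops):
            for region in reg_nodes.get(node_idx, ()):
                assignment.add(gene, region, "loop")
    return assignment


def assign_by_proximity(
    genes: Mapping[str, GeneAnnotation],
    regulators: Sequence[GenomicInterval],
    max_distance: int,
) -> RegulatorAssignment:
    """Assign each regulator to genes whose TSS lies within *max_distance* bp.

    Distance is measured from the closest base of the region to the TSS
    (0 when the region covers the TSS); assignment is same-chromosome only.
    """
    if max_distance <= 0:
        raise ParameterError(f"max_distance must be positive, got {max_distance}")
    assignment = RegulatorAssignment()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for region in regulators:
        by_chrom.setdefault(region.chrom, []).append(region)
    for gene, ann in genes.items():
        for region in by_chrom.get(ann.chrom, ()):
            if region.start <= ann.tss < region.end:
                dist = 0
            else:
                # closest base of [start, end) is start or end-1
                dist = min(abs(region.start - ann.tss), abs(region.end - 1 - ann.tss))
            if dist <= max_distance:
                assignment.add(gene, region, "proximity")
    return assignment


def count_regulators(assignment: RegulatorAssignment, gene: str) -> int:
    """Number of distinct regulator regions assigned to *gene* (0 if none)."""
    return assignment.count(gene)


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read loops from BEDPE (columns 1-6 = anchors, column 8 = optional score).

    ``track``, ``browser`` and ``#`` header lines are tolerated.
    """
    path = Path(path)
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TableParseError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from None
            score = None
            if len(fields) >= 8 and fields[7] not in ("", "."):
                try:
                    score = float(fields[7])
                except ValueError:
                    raise TableParseError(
                        f"{path}:{lineno}: non-numeric BEDPE score {fields[7]!r}"
                    ) from None
            loops.append(Loop(a, b, score))
    return loops


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            score = "." if lp.score is None else f"{lp.score:.6g}"
            fh.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}"
                f"\t{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}"
                f"\tloop{i}\t{score}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read regions from BED3+ (extra columns ignored)."""
    path = Path(path)
    regions: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                regions.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from None
    return regions


def write_bed(regions: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
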