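"""Cytoscape.js-style JSON export of scored pathways with regulator nodes.

The document has the shape ``{"elements": {"nodes": [...], "edges": [...]}}``
that Cytoscape imports directly.  Gene nodes carry the score fields
(expression, consistency, impact, triangulation, p-value, regulator count);
assigned regulator regions become extra nodes linked to their target genes by
edges with ``interaction = "noncoding"``.  The formal contract is the JSON
schema shipped at ``tripath/schemas/cytoscape.schema.json``;
:func:`validate_cytoscape_json` enforces its constraints.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Any, Sequence

from .graph_model import PathwayGraph
from .noncoding import RegulatorAssignment
from .scoring import GeneScoreRecord

_INTERACTIONS = {"activation", "inhibition", "noncoding"}
_TOKEN = {+1: "activation", -1: "inhibition"}


class ExportError(ValueError):
    """Scores and graph disagree, or a document violates the schema."""


def export_cytoscape_json(
    graph: PathwayGraph,
    records: Sequence[GeneScoreRecord],
    assignment: RegulatorAssignment | None = None,
) -> dict[str, Any]:
    """Build a Cytoscape-importable JSON document for one scored pathway."""
    by_gene = {r.gene: r for r in records}
    if set(by_gene) != graph.nodes:
        missing = graph.nodes.symmetric_difference(by_gene)
        raise ExportError(
            f"score records do not match pathway {graph.pathway_id!r} genes: "
            f"{sorted(missing)[:5]}"
        )
    nodes: list[dict[str, Any]] = []
    edges: list[dict[str, Any]] = []
    for gene in sorted(graph.nodes):
        r = by_gene[gene]
        nodes.append(
            {
                "data": {
                    "id": gene,
                    "type": "gene",
                    "consistency": r.consistency,
                    "impact": r.impact,
                    "triangulation": r.triangulation,
                    "p": None if math.isnan(r.p_triangulation) else r.p_triangulation,
                    "n_regulators": r.n_regulators,
                }
            }
        )
    eid = 0
    for e in graph.edges:
        edges.append(
            {
                "data": {
                    "id": f"e{eid}",
                    "source": e.source,
                    "target": e.target,
                    "interaction": _TOKEN[e.sign],
                }
            }
        )
        eid += 1
    if assignment is not None:
        reg_ids: set[str] = set()
        for gene in sorted(graph.nodes):
            for region in sorted(assignment.regions(gene)):
                rid = str(region)
                if rid not in reg_ids:
                    reg_ids.add(rid)
                    nodes.append(
                        {
                            "data": {
                                "id": rid,
                                "type": "regulator",
                                "chrom": region.chrom,
                                "start": region.start,
                                "end": region.end,
                            }
                        }
                    )
                edges.append(
                    {
                        "data": {
                            "id": f"e{eid}",
                            "source": rid,
                            "target": gene,
                            "interaction": "noncoding",
                            "provenance": assignment.provenance(gene, region),
                        }
                    }
                )
                eid += 1
    return {
        "format_version": "1.0",
        "pathway_id": graph.pathway_id,
        "elements": {"nodes": nodes, "edges": edges},
    }


def load_schema() -> dict[str, Any]:
    """The shipped JSON schema for exported documents."""
    text = resources.files("tripath").joinpath("schemas/cytoscape.schema.json").read_text()
    return json.loads(text)


def validate_cytoscape_json(doc: Any) -> None:
    """Check *doc* against the shipped schema's constraints; raise on violation.

    Structural validation is implemented directly (required keys, field types,
    interaction vocabulary, unique node ids, edge endpoints resolving to
    nodes).
    """
    if not isinstance(doc, dict):
        raise ExportError("document must be a JSON object")
    for key in ("format_version", "pathway_id", "elements"):
        if key not in doc:
            raise ExportError(f"missing required key {key!r}")
    elements = doc["elements"]
    if not isinstance(elements, dict) or not {"nodes", "edges"} <= set(elements):
        raise ExportError("elements must contain 'nodes' and 'edges' arrays")
    ids: set[str] = set()
    for node in elements["nodes"]:
        data = node.get("data") if isinstance(node, dict) else None
        if not isinstance(data, dict) or "id" not in data:
            raise ExportError("every node needs data.id")
        if not isinstance(data["id"], str):
            raise ExportError(f"node id must be a string, got {data['id']!r}")
        if data["id"] in ids:
            raise ExportError(f"duplicate node id {data['id']!r}")
        if data.get("type") not in ("gene", "regulator"):
            raise ExportError(f"node {data['id']!r}: type must be gene or regulator")
        ids.add(data["id"])
    edge_ids: set[str] = set()
    for edge in elements["edges"]:
        data = edge.get("data") if isinstance(edge, dict) else None
        if not isinstance(data, dict) or not {"id", "source", "target"} <= set(data):
            raise ExportError("every edge needs data.id/source/target")
        if data["id"] in edge_ids:
            raise ExportError(f"duplicate edge id {data['id']!r}")
        edge_ids.add(data["id"])
        if data["source"] not in ids or data["target"] not in ids:
            raise ExportError(f"edge {data['id']!r} endpoint not among node ids")
        if data.get("interaction") not in _INTERACTIONS:
            raise ExportError(
                f"edge {data['id']!r}: interaction must be one of {sorted(_INTERACTIONS)}"
            )


def write_cytoscape_json(doc: dict[str, Any], path) -> None:
    validate_cytoscape_json(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
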