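"""End-to-end orchestration: inputs -> scored, significance-annotated outputs.

For every pathway edge-list file in the pathway directory: reconcile the gene
universe with the expression table, assign non-coding regulators (chromatin
network when loops are given, TSS proximity otherwise, none when neither),
score every gene, attach permutation and Poisson p-values, and write

* ``results.tsv``   — one row per (pathway, gene), all score fields;
* ``summary.tsv``   — the rows passing the reporting p-value threshold;
* ``<pathway>.cyjs``— a Cytoscape-importable JSON per pathway.

The run is deterministic given the permutation seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import graph_model, noncoding, significance
from .export import export_cytoscape_json, write_cytoscape_json
from .scoring import GeneScoreRecord, ScoringParams, score_pathway
from .significance import PermutationConfig

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "pathway_id",
    "gene",
    "support",
    "inconsistency",
    "consistency",
    "impact",
    "n_regulators",
    "triangulation",
    "p_triangulation",
    "p_regulators",
]


@dataclass
class RunConfig:
    pathway_dir: Path
    expression: Path
    annotation: Path | None = None
    loops: Path | None = None
    regulators: Path | None = None
    proximity_dist: int | None = None
    promoter_window: int = noncoding.DEFAULT_PROMOTER_WINDOW
    hops: int = noncoding.DEFAULT_HOPS
    params: ScoringParams = field(default_factory=ScoringParams)
    permutations: PermutationConfig = field(default_factory=PermutationConfig)
    pvalue_threshold: float = 0.005
    fdr: bool = False
    out_dir: Path = Path("tripath_out")

    def validate(self) -> None:
        for name in ("expression", "annotation", "loops", "regulators"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if not Path(self.pathway_dir).is_dir():
            raise FileNotFoundError(f"pathway directory not found: {self.pathway_dir}")


def build_assignment(config: RunConfig):
    """Regulator assignment per the configured mode; None when no regulators.

    Loop-network assignment takes precedence; proximity is the fallback when
    no loop data are available.
    """
    if config.regulators is None or config.annotation is None:
        return None
    annotation = graph_model.read_annotation(config.annotation)
    regions = noncoding.read_bed(config.regulators)
    if config.loops is not None:
        loops = noncoding.read_bedpe(config.loops)
        network = noncoding.build_network(loops)
        return noncoding.assign_by_loops(
            network, annotation, regions, config.promoter_window, config.hops
        )
    if config.proximity_dist is not None:
        return noncoding.assign_by_proximity(annotation, regions, config.proximity_dist)
    return None


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full analysis; returns the results table (also on disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expr = graph_model.read_expression(config.expression)
    assignment = build_assignment(config)
    universe: set[str] = set()
    if config.annotation is not None:
        universe = set(graph_model.read_annotation(config.annotation))

    pathway_files = sorted(Path(config.pathway_dir).glob("*.tsv"))
    if not pathway_files:
        raise FileNotFoundError(f"no pathway .tsv files in {config.pathway_dir}")

    all_records: list[GeneScoreRecord] = []
    for pw_file in pathway_files:
        graph = graph_model.read_pathway_graph(pw_file)
        graph, expr, report = graph_model.intersect_universe(graph, expr)
        records = score_pathway(graph, expr, assignment, config.params)
        p_tri = significance.permutation_pvalues(
            graph, expr, assignment, config.params, config.permutations
        )
        p_reg = None
        if assignment is not None and universe:
            p_reg = significance.regulator_pvalues(
                assignment, universe, [r.gene for r in records]
            )
        significance.attach_significance(records, p_tri, p_reg)
        all_records.extend(records)

        doc = export_cytoscape_json(graph, records, assignment)
        write_cytoscape_json(doc, out_dir / f"{graph.pathway_id}.cyjs")
        logger.info(
            "pathway %s: %d genes (%d measured), %d regulator-assigned, %d permutations",
            graph.pathway_id,
            len(graph.nodes),
            report.n_measured,
            sum(1 for r in records if r.n_regulators > 0),
            config.permutations.n_permutations,
        )

    df = pd.DataFrame(
        [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in all_records],
        columns=RESULT_COLUMNS,
    )
    if config.fdr:
        df["q_triangulation"] = significance.benjamini_hochberg(df["p_triangulation"])
    df = df.sort_values(["pathway_id", "triangulation"], kind="stable").reset_index(drop=True)
    df.to_csv(out_dir / "results.tsv", sep="\t", index=False, float_format="%.6g")
    summary = df[df["p_triangulation"] < config.pvalue_threshold]
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info(
        "wrote %d rows (%d below p<%g) to %s",
        len(df),
        len(summary),
        config.pvalue_threshold,
        out_dir,
    )
    return df
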