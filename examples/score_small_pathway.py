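"""Score a hand-built five-gene pathway and read off the perturbed gene.

RTK activates RAS, RAS activates ERK, ERK activates MYC, and PTEN inhibits
RAS.  Expression says everything is up except MYC, which is down despite an
active upstream cascade — MYC is the perturbation origin.
"""

from tripath import ExpressionTable, PathwayGraph, ScoringParams, SignedEdge, score_pathway

graph = PathwayGraph(
    pathway_id="toy_rtk",
    nodes={"RTK", "RAS", "ERK", "MYC", "PTEN"},
    edges=[
        SignedEdge("RTK", "RAS", +1),
        SignedEdge("PTEN", "RAS", -1),
        SignedEdge("RAS", "ERK", +1),
        SignedEdge("ERK", "MYC", +1),
    ],
)
expr = ExpressionTable({"RTK": 1.8, "RAS": 2.1, "ERK": 1.2, "MYC": -0.9, "PTEN": -0.6})

records = sorted(score_pathway(graph, expr, params=ScoringParams()), key=lambda r: r.triangulation)
print(f"{'gene':6} {'consistency':>11} {'impact':>8} {'triangulation':>13}")
for r in records:
    print(f"{r.gene:6} {r.consistency:11.3f} {r.impact:8.3f} {r.triangulation:13.3f}")

# consistency < 0 means a gene contradicts its upstream regulators; the most
# negative triangulation score (MYC: up-regulated ERK predicts up, observed
# down) marks the perturbation origin.  RAS is doubly supported: RTK up and
# PTEN down both predict RAS up, and its downstream cascade is intact, so its
# positive score is amplified by impact.
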