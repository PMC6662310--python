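# tripath

Pathway-topology analysis that prioritizes *perturbed genes* inside signed
pathway graphs and links them to their *non-coding regulators*.

Classical pathway analysis asks whether a gene set is enriched in
differential genes. `tripath` instead asks, for every gene in a pathway
graph whose edges carry activation (+1) or inhibition (−1) signs: does this
gene's differential expression agree with what its upstream regulators
predict, how far does its state propagate downstream, and how many
non-coding elements (enhancer-like regions linked by chromatin loops or TSS
proximity) target it? It is aimed at regulatory genomicists who have a
differential-expression table, curated signed pathways, and optionally
ChIA-PET/HiC/HiChIP loops plus open-chromatin peaks.

## The scores

For gene *g* with signed statistic *e(g)* (e.g. log2 fold change), each
upstream edge *u → g* with sign *s* predicts direction sign(*e(u)*)·*s* for
*g*. Summing the magnitudes of agreeing and disagreeing regulators gives

    support(g)       = Σ_supporting |e(u)|
    inconsistency(g) = Σ_inconsistent |e(u)|
    consistency(g)   = (support − inconsistency) / (support + inconsistency) ∈ [−1, 1]

(0 when there is no measured upstream evidence). Negative consistency marks
perturbed genes — expression contradicting their regulators.

Downstream reach is measured by breadth-first search over *supported* edges
(x → v is supported when sign(e(v)) = sign(e(x))·s, both nonzero), with an
exponential distance decay:

    impact(g) = Σ_{v reached} |e(v)| · exp(−α · depth(v)),   α > 0.

These combine, with the count *k* of non-coding regulators assigned to *g*,
into the sign-preserving triangulation score

    T(g) = consistency(g) · (1 + impact(g)) · (1 + log2(1 + k)).

Significance: a permutation p-value per gene (expression values reshuffled
across the measured genes, two-sided on |T|, +1 pseudocount) and a Poisson
upper-tail p-value for *k* against the mean regulator count per annotated
gene.

## Worked example

`python examples/score_small_pathway.py` scores a five-gene cascade in which
everything is up-regulated except MYC:

```
gene   consistency   impact triangulation
MYC         -1.000    0.000        -1.000
PTEN         0.000    0.935         0.000
RTK          0.000    0.935         0.000
ERK          1.000    0.000         1.000
RAS          1.000    0.441         1.441
```

MYC contradicts its (active) upstream cascade — consistency −1 flags it as
the perturbation origin. RAS is supported by both RTK (activation, up) and
PTEN (inhibition, down) and still drives a consistent downstream chain, so
its positive score is amplified by impact. RTK and PTEN have no measured
regulators (consistency 0), so their triangulation is 0 regardless of
impact.

The other examples cover permutation significance
(`examples/permutation_significance.py`), loop-network regulator assignment
(`examples/regulator_assignment.py`) and the end-to-end pipeline on a
simulated study (`examples/full_pipeline.py`).

## Command line

```sh
tripath simulate --out study/ --seed 5
tripath run --pathways study/pathways --expression study/expression.tsv \
    --annotation study/annotation.tsv --loops study/loops.bedpe \
    --regulators study/regulators.bed --permutations 1000 --seed 1 --out out/
tripath export --pathway study/pathways/synthetic_seed5.tsv \
    --expression study/expression.tsv --out pathway.cyjs
```

`run` writes `results.tsv` (one row per pathway × gene), `summary.tsv`
(rows with p below `--pvalue-threshold`, default 0.005) and one
Cytoscape-importable `.cyjs` JSON per pathway. Without loop data, pass
`--proximity-dist D` to assign regulators within D bp of each TSS instead.

Input formats are plain text: pathway edge lists
(`source<TAB>target<TAB>interaction` with `activation`/`inhibition`),
expression TSV (`gene<TAB>expr[<TAB>sig]`), gene annotation TSV
(`gene<TAB>chrom<TAB>tss<TAB>strand`, 0-based TSS), BEDPE loops and BED
regulator regions.

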