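# Methods

## Model

A pathway is a directed graph over gene symbols with signed edges: +1
(activation) or −1 (inhibition). Parallel edges of opposite sign between the
same pair are allowed and contribute independently; self-loops are rejected.
Differential expression enters as one signed statistic per gene (typically a
log2 fold change). The method is deliberately agnostic to how that statistic
was produced; any signed per-gene score works, with the caveat that its
magnitude is used as an evidence weight.

### Upstream consistency

An edge *u → g* with sign *s* predicts direction sign(e(u))·s for *g*. Edges
whose prediction matches sign(e(g)) contribute |e(u)| to support(g); edges
whose prediction opposes it contribute |e(u)| to inconsistency(g). The
regulator's magnitude is the evidence weight (not the product with the
target's magnitude): the question is how strongly the regulators argue, not
how strongly the target responded. consistency(g) = (s − i)/(s + i)
normalizes to [−1, 1], making genes with different in-degrees comparable;
it is defined as 0 when s + i = 0 (no measured upstream evidence). Zero
expression is neutral everywhere: a gene with no direction provides no
evidence and blocks downstream traversal.

### Impact

Breadth-first search from *g* traverses only supported edges (target
direction equals the prediction, both endpoints nonzero). Each reached gene
is counted once at its minimum supported-edge distance d and contributes
|e(v)|·exp(−α·d). BFS semantics resolve multiple paths (minimum depth) and
cycles (visited set; the source never re-enters its own subgraph). α
(`decay_rate`, unitless per edge hop, default 1.0) sets how quickly distant
genes stop mattering: at α = 1 a gene two hops away is discounted to
e⁻² ≈ 0.14 of its magnitude. `max_depth` (default unbounded) can cap the
search; pathway graphs are small enough that the cap is rarely needed.

### Triangulation

T(g) = consistency · (1 + impact) · w_reg, with w_reg = 1 + log2(1 + k) when
regulator weighting is on (default) and 1 otherwise, k being the gene's
non-coding regulator count. The combination is multiplicative with +1
offsets so that zero impact or zero regulators leave consistency unchanged
rather than annihilating it, the sign of T always equals the sign of
consistency, and |T| is non-decreasing in both impact and k. The log2
damping keeps large regulator counts from dominating the score. Both tails
are informative: strongly negative T marks perturbation origins with large
downstream reach, strongly positive T marks genes firmly in line with their
pathway context.

## Significance

### Permutation test

The multiset of expression values is reshuffled uniformly across all genes
of the expression table — not only the pathway's genes — so the null pool is
the full measured distribution. Topology and regulator counts stay fixed; T
is recomputed per permutation and

p(g) = (1 + #{i : |T_i(g)| ≥ |T_obs(g)|}) / (N + 1),

two-sided on |T| with a +1 pseudocount (p ∈ [1/(N+1), 1], never 0). Results
are reproducible given the RNG seed. No multiple-testing correction is
applied by default, matching the raw-threshold reporting convention for this
kind of screen; a Benjamini–Hochberg column is available behind the `--fdr`
flag.

A structural caveat: |T| is a discrete-ish statistic. A gene with a single
upstream regulator has |consistency| = 1 under every permutation, and a
terminal gene has impact 0 under every permutation, so for such genes |T| is
partly or wholly determined by topology and the empirical p-value is
conservative (up to p ≡ 1 when topology fixes |T| entirely). This is
correct behaviour — no permutation evidence can exist there — but it means
pooled p-values are only approximately uniform under the null, with the
approximation improving as in/out-degrees grow. The null-calibration check
therefore uses random graphs in which every gene has three upstream
regulators; there the largest atom of |T|'s null distribution is small and
the pooled Kolmogorov–Smirnov distance from uniform is ≈ 0.02 at 50 genes ×
200 permutations × 100 replicates. On graphs dominated by in-degree-1 genes
the same check would fail for the structural reason above, not because the
p-values are invalid (they remain conservative, never anti-conservative).

### Poisson regulator enrichment

The background rate λ is the mean number of regulator assignments per gene
over the annotated gene universe (a genome-scale background, not
per-pathway). Each gene's count k gets the upper tail p = P(X ≥ k),
X ~ Poisson(λ), computed via the survival function; p = 1 when k = 0, and
when λ = 0 all p-values are reported as 1 with a warning.

## Non-coding regulator assignment

Coordinates are 0-based half-open throughout (BED convention). Loop anchors
overlapping by ≥ 1 bp on the same chromosome are merged transitively into
network nodes (so the node set is a disjoint union of contiguous intervals);
each loop becomes one edge, inter-chromosomal loops included, self-edges
allowed. A gene attaches through its promoter window [tss − w, tss + w + 1)
(default w = 2500 bp); a regulator region attaches to every node it
overlaps; assignment requires the two node sets to be within `hops` edges
(default 1 = direct interaction; sharing a node counts). Regions are
deduplicated per gene — a region reached via two loops counts once.

Proximity fallback (used only when no loops are supplied): a region is
assigned when the closest base of [start, end) lies within D bp of the TSS
on the same chromosome; the closest-edge distance is conservative and
invariant to coordinate order. The promoter window and hop defaults are this
package's documented choices; they are flags, not claims about any
particular dataset.

## Synthetic data generator

The generator produces study conditions with exactly known truth:

* **Pathway**: a uniform-random-order upper-triangular DAG (edge probability
  0.1 over 30 genes by default). Edge signs derive from latent per-gene
  activity signs (sign(u→v) = s_u·s_v), which guarantees a globally
  self-consistent expression assignment exists — every non-planted gene's
  sign satisfies all its upstream predictions simultaneously. The
  activation fraction (default 0.7) is matched in expectation by setting the
  latent + probability to the root of q² + (1−q)² = a. Magnitudes are
  |N(2, sd)| (default sd 0.25; sd 0 keeps signs unambiguous for exact
  tests).
* **Planted perturbations** flip a gene's sign against all its upstream
  predictions. Planting targets terminal genes with ≥ 1 regulator (adding
  one edge when none qualifies): flipping an internal gene would also make
  every child it solely controls inconsistent, obscuring which gene is the
  perturbation origin. Under zero noise the planted gene is the unique gene
  with negative consistency, so it attains the strictly most negative
  triangulation score.
* **Regulome**: one synthetic 10-Mb chromosome "chrS", one 200-kb block per
  gene with the TSS 100 kb into the block, promoter anchors ±500 bp,
  planted regulator regions (400 bp, spaced 600 bp) 20–56 kb downstream of
  the TSS each wired by its own one-hop loop, and decoy loops confined to a
  band 65–95 kb past the TSS — ≥ 50 kb from every TSS, so decoys are
  invisible to both assignment modes at the defaults.

What the generator does **not** emulate: realistic RNA-seq count noise and
dispersion, correlated expression beyond the pathway's own edges, realistic
loop length distributions or contact frequencies, overlapping genes, minus
strand geometry beyond the annotation field, and multi-pathway gene sharing.
Passing the planted-recovery and calibration checks therefore demonstrates
algorithmic correctness and statistical validity under clean conditions, not
performance on real tumor/normal contrasts.

## Numerical choices and conventions

* Unmeasured genes score as e = 0 (no evidence, traversal-blocking) and are
  reported with consistency 0 and p = 1.
* Equal support and inconsistency give consistency exactly 0 and hence
  T = 0, p = 1 (|T_i| ≥ 0 always).
* Impact BFS and the permutation loop run on an integer-indexed compilation
  of the graph; results are identical to the per-gene reference functions
  (tested to 1e-12 against exhaustive path enumeration).
* Results TSVs are written with 6 significant digits and a stable column
  order; reruns with the same seed are byte-identical.
* The exported Cytoscape JSON is validated against the schema shipped in
  `tripath/schemas/cytoscape.schema.json` by a built-in structural
  validator.

## Problem sizes

The test-suite and acceptance-script study sizes — 200 random ≤10-node
graphs for the impact oracle, λ ∈ {0.1, 1, 5, 20} × k ≤ 50 for the Poisson
check, 100 replicates × 200 permutations × 50 genes for calibration, 100
30-gene fixtures for planted recovery, 200 ≤50-loop regulomes for the
assignment oracle — were chosen as the smallest sizes at which the checked
properties are statistically meaningful; all are exercised as written.

## Known limitations

* Only activation/inhibition edge semantics are supported; unsigned
  interaction types (binding, complex membership, expression) must be
  dropped or recoded by the user before import.
* Gene matching is exact string equality after whitespace trimming; no
  alias or identifier mapping.
* The permutation test is conservative for topologically constrained genes
  (see above); interpret p = 1 on in-degree-0 genes as "no evidence
  possible", not "tested and null".
* λ for the Poisson test is a single global rate; locally clustered
  regulatory landscapes (e.g. super-enhancer neighborhoods) will inflate
  counts relative to it, which is the intended direction of the test but
  means the p-value is an enrichment screen, not a calibrated error rate.
* One TSS per gene; alternative promoters are not modeled.
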