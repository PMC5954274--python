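# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `granulome`, in the package's own terms.

## Block-order genomes and distances

A genome is a set of linear chromosomes over signed synteny blocks; block
`b` has extremities tail `2b` and head `2b+1`, and a genome is equivalently
a matching on extremities (unmatched = telomere). All coordinates anywhere
in the package are ordinal gene positions, never base pairs, because every
threshold the analysis uses (resolution level, merge gap) is a gene count.

**DCJ distance.** `d = N − (C + I/2)` on the adjacency graph of the two
matchings, where a path is *odd* when it has an odd number of vertices in
the extremity drawing. The implementation is exact for all linear genomes
with equal block content; circular chromosomes are rejected at every
boundary (plant nuclear genomes are linear).

**Breakpoint distance and reuse.** `b = N − a − e/2`, counting a shared
telomere as half an agreement. Under this convention `d ≤ b ≤ 2d`, so
`r = 2d/b` spans exactly `[1, 2]`; both bounds are exercised by tests and
the acceptance script. `r` is undefined (raises) for identical genomes.

**Scenarios.** Sorting is greedy: every DCJ operation that (i) reduces the
distance by exactly 1 and (ii) keeps all chromosomes linear is enumerated;
among them one of the prioritised type is applied (ties broken by lowest
cut extremities, so scenarios are reproducible). Candidate generation can
ignore material already agreeing with the target: any operation cutting a
finished component loses at least as much as it gains, since a single DCJ
changes `C + I/2` by at most one. A step is classified by its cuts: one
chromosome → reversal, two chromosomes → translocation, a lone cut →
fission, a lone join → fusion. When no linear-safe reducing operation
exists — the block-interchange situation, e.g. `(1 2 3)` vs `(2 1 3)` — a
circular piece is excised and reabsorbed by the very next step; the pair is
labelled `excision`/`reintegration`, each half still reduces the distance
by 1, and the scenario length always equals the DCJ distance. (The claim
that a linear-safe reducing operation always exists is false; the
restricted-sorting resolution above is the standard one.)

## DCJ median

The median minimises `d(m,A)+d(m,B)+d(m,C) = 3N − Σ_k (C_k + I_k/2)`, so
the solver maximises weighted component counts of a candidate median
matching against the three inputs.

* **Component decomposition.** The union of the three input matchings
  splits the extremities into connected components; a median adjacency
  joining two components can never close a cycle in any input, so
  components are optimised independently and the optimum is exact.
* **Per-component search.** Depth-first over pairing decisions, with chain
  bookkeeping per input genome (cycles are counted the moment they close,
  path parities read off at the leaves). Two admissible bounds prune the
  search: per genome, future cycles are limited by both remaining median
  edges and live chains; and per genome *pair*, `contrib_i + contrib_j ≤
  v/2 + contrib(G_i,G_j)` — the triangle inequality of the matching metric
  on the component. Each input genome's own matching seeds the incumbent.
* **Enumeration.** The exact optimum is established first by the
  aggressively pruned single-solution search; co-optimal matchings are then
  enumerated under a node budget (500k nodes/component). If the budget
  trips, the score is still exact and the median set is flagged
  `truncated`. Assemblies are combined best-first across components; any
  assembly inducing a circular chromosome is skipped (with automatic
  widening of the per-component slack window in the rare case every best
  assembly is circular). Medians are canonicalised (chromosomes flipped to
  their lexicographically smaller reading and sorted) before counting, so
  "number of distinct medians" is well defined; the count refers to
  component-respecting medians in this canonical form.
* **Checked invariants.** Every run asserts
  `⌈(d_AB+d_AC+d_BC)/2⌉ ≤ score ≤ min_leaf Σd` and that the
  representative's distance triple sums to the score.

**Breakpoint median.** Extremity graph with candidate adjacencies weighted
by the number of input genomes containing them and telomere bonuses (half
weight) realised as edges to private cap vertices; a maximum-weight
matching (networkx, exact) minimises the summed breakpoint distance. A
cycle forced by the matching is broken at its lightest adjacency and
logged.

## Three-way blocks and the informativeness filter

Two pairwise tables sharing the pivot genome are sorted along the pivot and
intersected; partial overlaps split at interior boundaries. Counterpart
intervals are split *proportionally*: gene boundaries are mapped linearly
from the pivot span to the counterpart span (respecting strand), with
floor-consistent rounding so disjoint inputs give disjoint outputs and
same-size spans map exactly. Colour (ancestral-chromosome label, 1–21)
must agree between the parents; conflicts are skipped and logged. The
third table, which does not involve the pivot, is used as a consistency
audit (colour confirmation; in strict mode, a warning when a block spans
several third-table blocks) rather than a second splitting axis — in the
regime emulated here it contributes virtually no extra breakpoints.

A pivot scaffold is informative only if it carries two successive blocks
whose junction (the oriented pair of block extremities, invariant under
reading direction) is absent in at least one other genome; anything else
cannot witness rearrangement and is dropped.

## Resolution degradation

Level `L` deletes blocks with fewer than `L` genes; block size is the
*minimum* per-genome gene count (conservative under fractionation;
configurable to mean/max). Deletion exposes neighbours that merge when
they are (i) consecutive among retained blocks on all three genomes,
(ii) separated by fewer than `merge_gap = 250` genes on all three —
absolute gene coordinates make genes of deleted blocks count automatically,
(iii) same colour, and (iv) by default, joined by the *same* junction in
all three genomes. Requirement (iv) is the package's resolution of an
ambiguity: merging pairs with conflicting orientations (and repairing signs
afterwards by search) is what a noisy-data analysis does, but in a clean
world it destroys rearrangement evidence outright, so the lossy behaviour
is available behind `require_consistent_junction=False` and merged blocks
built that way carry `polarity_determinate=False`. Mergers sweep left to
right along the pivot and repeat to a fixpoint, so chains collapse
transitively; gene content is conserved at every level
(`genes_not_included + genes_remaining = const`), and blocks/genes are
monotone in `L`.

**Polarity search.** Indeterminate signs are fixed by greedy
first-improvement search on the exact DCJ median score: scan (block,
genome) pairs in order, keep a flip only if it strictly lowers the score,
repeat passes to quiescence (max 20; the integer objective guarantees
termination). Trials are pre-screened with the pairwise lower bound
`⌈Σ pairwise d / 2⌉ ≥ current score`, which rejects clearly harmful flips
without paying for an exact median of a deliberately tangled triple.

## Translocation estimator

With uniform breakpoint density, after `t_i` translocations chromosome `i`
of the descendant carries no fragment of source chromosome `j` with
probability `(1 − p(j)/(1−p(i)))^{t_i}`; summing expectations of the
conserved-synteny counts `c_i` and substituting `t_i ≈ 2 t p(i)` gives
three estimating equations: the equal-chromosome-number form (`eq5`), the
general form with target length fractions `q` (`eq6`), and its equal-length
closed form (`eq7`): `1 − S/(cd) = (1 − 1/d)^{1+2t̂/c}`. `eq5`/`eq6` are
solved by bracketed root finding (Brent, tolerance 1e−9, bracket `[0,
50cd]`; their right sides are monotone decreasing in `t̂`, so the bracket
is safe). Omitting the factor 2 exactly doubles the estimate — appropriate
when breakpoint reuse is high, and a pure rescaling. `S ≥ cd` (complete
mixing) and `d = 1` raise; small negative closed-form values clamp to 0
with a warning. The model ignores second-order fragment transfers, so
large `t` is systematically underestimated — by design, the estimate is a
lower bound in spirit. Recovery simulations (reciprocal translocations,
breakpoints uniform by length, fragment-origin bookkeeping) show mean
recovery within a few percent at `t = 5`, `c = d = 8` and the expected
saturation bias at large `t`.

## Synthetic world

The generator states a desk-scale world with the structure the analysis
assumes, scaled from the real regime it emulates (≈200 three-way blocks,
≈68 genes/block, 21 ancestral colours, a fast translocation-rich pivot
lineage, a conservative sister, a conservative outgroup):

* ancestor: 60 blocks on 5 chromosomes, colours by chromosome of origin,
  gene counts lognormal (median 70, clipped to [5, 400], σ = 0.9);
* branches (`n_ops`, mix): pivot 13 (0.55 reversal / 0.35 translocation /
  0.10 fusion+fission), sister 7 (0.85 reversal), outgroup 10 (0.60
  reversal / 0.30 translocation / 0.10), proportioned after the published
  three-genome comparison's full-resolution distances and their
  coarse-resolution survivors;
* inversions are local: their gene span is exponential (mean 60 genes);
* **refining evolution**: operation breakpoints fall on gene positions, and
  a breakpoint interior to a block splits it — in the ancestor and every
  descendant at once. Block sizes therefore *correlate with rearrangement
  history*: a conservative, small-inversion lineage stores its signal in
  exactly the blocks a coarse analysis deletes. This coupling, not any
  parameter, is what produces the resolution-blurring effect;
* fractionation: a Poisson(2) number of genes eroded per block end per
  leaf; pivot assembly fragmented by scaffold breaks (p = 0.08 per block
  boundary); pairwise tables report maximal same-colour runs contiguous in
  both genomes, with cumulative gene coordinates, per-genome strands and
  eroded gene counts — what a synteny mapper would emit.

What a green end-to-end test establishes: on data with this structure the
pipeline reconstructs true pairwise distances exactly (clean settings), the
median separates fast from slow lineages at full resolution, and
coarsening blurs the separation while driving `r` toward 2. What it does
not establish: behaviour under paralogy (the world has none, mirroring the
deliberate choice of genomes without recent polyploidy), gene-level noise
in block calls, or assembly errors beyond clean scaffold breaks.

Simpler non-refining operations (`evolve` on a fixed block set) remain the
public single-genome API and the basis of the estimator experiments.
Because refinement renames blocks as it splits them, recorded scenarios are
positional rather than replayable scripts; the generator's guarantee is
tested as distance consistency (`d(ancestor, leaf) ≤` branch op count,
scenario length = op count) instead of literal replay.

## Known limitations

* Exact median enumeration is exponential in component size; tangled
  coarse-resolution instances can exceed the node budget (flagged
  `truncated`, score still exact). Instances in the default world solve in
  milliseconds to seconds.
* The coarse-level separation gap between fast and slow lineages shrinks
  by ~40% on average in the default world, bounded below by surviving
  chromosome-scale translocation junctions, which no resolution loss
  erases.
* The greedy scenario search brackets, but does not enumerate, the
  translocation/reversal counts of optimal scenarios; exhaustive
  enumeration is used as the oracle only at toy sizes.
* `eq5` is exposed for equal chromosome numbers only; with `c ≠ d` use
  `eq6` (the general model) or `eq7` (near-equal lengths).
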