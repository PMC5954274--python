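# granulome

Resolution (granularity) effects in block-level ancestral genome
reconstruction.

Comparative genomics at the synteny-block level must choose a resolution:
drop every block with fewer than *L* genes and the analysis gets cleaner but
blinder. `granulome` is a pipeline for measuring exactly what that choice
costs. It builds three-way synteny blocks from pairwise block tables (the
kind a synteny mapper such as SynMap emits), degrades them over a schedule
of resolution levels, reconstructs the ancestor of three genomes as an exact
DCJ median at every level, and tracks how distances, operation spectra,
breakpoint reuse, and model-based translocation estimates deform as
resolution is lost. A ground-truthed simulator of a coloured ancestor and
three descendant lineages makes the whole pipeline testable without any
external data.

## The quantities at its core

* **DCJ distance** `d(A,B) = N − (C + I/2)` — minimum number of
  double-cut-and-join operations between two genomes on the same `N` signed
  blocks, read off the adjacency graph (`C` cycles, `I` odd paths).
* **Breakpoint distance** `b = N − a − e/2` (`a` shared adjacencies, `e`
  shared telomeres), and the **breakpoint reuse** statistic `r = 2d/b`,
  which runs from 1 (every operation creates two fresh breakpoints) to 2
  (genomes mutually random).
* **DCJ median** — a genome `m` minimising `d(m,A)+d(m,B)+d(m,C)`; solved
  exactly by branch-and-bound over the component decomposition of the
  multiple adjacency graph, with enumeration of all co-optimal medians.
  A **breakpoint median** via maximum-weight matching is also provided.
* **Rearrangement scenarios** — greedy optimal sorting with translocations
  or reversals prioritised, classifying every step (reversal,
  translocation, fusion, fission; forced block interchanges appear as
  excision/reintegration pairs).
* **Translocation estimator** — a non-constructive probabilistic estimate
  `t̂` of the translocation count from conserved-synteny counts `c_i` and
  chromosome length fractions, in closed form
  `1 − S/(cd) = (1 − 1/d)^(1+2t̂/c)` (with `S = Σ c_i`) or via the general
  per-chromosome-length forms solved numerically.

## Worked example

```python
from granulome.pipeline import run, reuse_trend

summary = run({"seed": 1, "scenarios": False, "median_cap": 2000})
print(summary.table[["level", "blocks_after_mergers", "median_total",
                     "d_m_rhazya", "d_m_coffee", "r_rhazya_coffee"]])
print(reuse_trend(summary))
```

prints (abridged):

```
 level  blocks_after_mergers  median_total  d_m_rhazya  d_m_coffee  r_rhazya_coffee
     0                    66            38       21.00        7.00            1.244
    30                    31            25       18.00        2.50            1.702
    70                    19            16       11.40        1.30            1.714
TrendFit(slope=0.00639, intercept=1.262, r_squared=0.476)
```

Reading it: at full resolution (level 0) the fast, translocation-rich
lineage (`rhazya`) sits 21 DCJ operations from the reconstructed ancestor
while the conservative lineage (`coffee`) sits 7 — a 3× rate difference.
By level 70 most small blocks are gone, the median score has collapsed from
38 to 16, and the rate difference has blurred (11.4 vs 1.3 on a third of
the blocks). Breakpoint reuse climbs from 1.24 toward 2 with a positive
fitted slope: the coarsened genomes are drifting toward mutual randomness,
which is the signature artefact of resolution loss, not of genuine
breakpoint reuse.

The same stages are scriptable from a shell — `granulome simulate`,
`granulome blocks build`, `granulome distance|scenario|median|estimate-t`,
and `granulome run config.yaml` for the full sweep.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly simulated genomes, the extreme values of the
breakpoint-reuse statistic: its maximum over 200 independently shuffled
50-block genome pairs and its minimum over a mixed collection spanning
light to saturating rearrangement, writing both to the JSON file given by
`--out`.
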