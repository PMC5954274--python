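"""The resolution-degradation engine.

Resolution level ``L`` means: ignore every three-way block attributed fewer
than ``L`` genes (block size is the minimum per-genome gene count by
default, the conservative choice under fractionation).  Removing small
blocks exposes pairs of surviving blocks that sit close together on all
three genomes - separated by fewer than ``merge_gap`` genes (genes of the
deleted blocks in between included) - and such pairs are combined, provided
they carry the same ancestral colour.  Merging may leave the combined
block's reading direction inconsistent between genomes; those blocks are
flagged polarity-indeterminate and their signs are fixed afterwards by a
greedy local search on the median score (:func:`resolve_polarity`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .blocks import _junction
from .median import dcj_median
from .model import BlockTable, Placement, SignedBlockGenome, SyntenyBlockRecord, genome_from_table

__all__ = [
    "ResolutionSchedule",
    "LevelReport",
    "LevelResult",
    "apply_level",
    "merge_neighbours",
    "resolve_polarity",
    "sweep",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0, 10, 20, 30, 40, 50, 60, 70)


@dataclass(frozen=True)
class ResolutionSchedule:
    """Which levels to sweep and how to merge."""

    levels: tuple[int, ...] = DEFAULT_LEVELS
    merge_gap: int = 250
    colour_rule: bool = True
    require_consistent_junction: bool = True
    size_rule: str = "min"  # min | mean | max over per-genome gene counts

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if self.merge_gap <= 0:
            raise ValueError("merge_gap must be positive")
        if self.size_rule not in ("min", "mean", "max"):
            raise ValueError(f"unknown size rule {self.size_rule!r}")


@dataclass
class LevelReport:
    """One row of the per-level accounting table."""

    level: int
    blocks_deleted: int
    blocks_remaining: int
    blocks_after_mergers: int
    genes_not_included: int
    genes_remaining: int


@dataclass
class LevelResult:
    report: LevelReport
    table: BlockTable
    genomes: dict[str, SignedBlockGenome]
    indeterminate: list[tuple[str, int]]  # (genome, signed-block id) to search over


def block_size(r: SyntenyBlockRecord, rule: str = "min") -> float:
    counts = list(r.genes.values())
    if rule == "min":
        return min(counts)
    if rule == "max":
        return max(counts)
    return sum(counts) / len(counts)


def apply_level(
    t: BlockTable, level: int, size_rule: str = "min"
) -> tuple[BlockTable, BlockTable]:
    """Split the table into (retained, deleted) at resolution level ``level``.

    A block is retained when its size (per ``size_rule`` over the per-genome
    gene counts) is at least ``level``; level 0 keeps everything.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    kept, deleted = [], []
    for r in t.records:
        (kept if block_size(r, size_rule) >= level else deleted).append(r)
    return BlockTable(kept, t.genome_names), BlockTable(deleted, t.genome_names)


def _orders(t: BlockTable):
    """Per genome: block ordering info for adjacency and gap tests."""
    info = {}
    for g in t.genome_names:
        by_scaf: dict[str, list] = {}
        for r in t.records:
            by_scaf.setdefault(r.placements[g].scaffold, []).append(r)
        pos: dict[str, tuple[str, int]] = {}
        for scaf, recs in by_scaf.items():
            recs.sort(key=lambda r: r.placements[g].start)
            for i, r in enumerate(recs):
                pos[r.block_id] = (scaf, i)
        info[g] = (by_scaf, pos)
    return info


def _gap(r1, r2, g: str) -> int:
    p1, p2 = r1.placements[g], r2.placements[g]
    if p1.start > p2.start:
        p1, p2 = p2, p1
    return p2.start - p1.end - 1


def _merge_pair(r1, r2, genome_names, pivot: str) -> SyntenyBlockRecord:
    """Combine two records; the merged unit is defined by the pivot reading."""
    if r1.placements[pivot].start > r2.placements[pivot].start:
        r1, r2 = r2, r1
    pivot_junction = _junction(r1, r2, pivot)
    determinate = r1.polarity_determinate and r2.polarity_determinate
    placements, genes = {}, {}
    for g in genome_names:
        p1, p2 = r1.placements[g], r2.placements[g]
        first, second = (r1, r2) if p1.start <= p2.start else (r2, r1)
        same_junction = _junction(r1, r2, g) == pivot_junction
        if g == pivot:
            strand = "+"
        else:
            # with a conserved junction the pair reads as the pivot-defined
            # unit, forward exactly when the pivot-earlier part comes first;
            # otherwise the unit's reading in g is genuinely ambiguous and
            # the same rule just seeds the polarity search
            if not same_junction:
                determinate = False
            strand = "+" if first is r1 else "-"
        placements[g] = Placement(
            p1.scaffold,
            min(p1.start, p2.start),
            max(p1.end, p2.end),
            strand,
        )
        genes[g] = r1.genes[g] + r2.genes[g]
    return SyntenyBlockRecord(
        block_id=f"{r1.block_id}+{r2.block_id}",
        colour=r1.colour,
        placements=placements,
        genes=genes,
        polarity_determinate=determinate,
    )


def merge_neighbours(
    t: BlockTable,
    deleted: BlockTable | None = None,
    gap: int = 250,
    colour_rule: bool = True,
    pivot: str | None = None,
    require_consistent_junction: bool = True,
) -> BlockTable:
    """Iteratively combine remaining blocks that became close neighbours.

    Two retained records merge when they are adjacent (consecutive among
    retained blocks, same scaffold) on all three genomes, separated by fewer
    than ``gap`` genes on all three (gene indices are absolute scaffold
    positions, so genes of deleted blocks in between count automatically),
    and share a colour when ``colour_rule`` is set.  By default the pair
    must also form the same extremity junction in every genome (consistent
    order and orientation), so a merged block has one well-defined reading
    everywhere and merging never destroys rearrangement evidence; with
    ``require_consistent_junction=False`` pairs with conflicting readings
    merge too, their polarity flagged indeterminate for the sign search -
    lossier, but it mirrors analyses that combine noisy blocks first and
    repair signs afterwards.  Mergers run left to right along the pivot
    genome and repeat to a fixpoint, so chains of neighbours collapse
    transitively.  ``deleted`` is accepted for gap accounting symmetry but
    carries no extra information here, because coordinates are never
    renumbered after deletion.
    """
    del deleted  # gaps are measured on absolute coordinates
    pivot = pivot or t.genome_names[0]
    records = list(t.records)
    while True:
        table = BlockTable(records, t.genome_names)
        info = _orders(table)
        piv_by_scaf, _ = info[pivot]
        consumed: set[str] = set()
        merges = []
        for scaf in sorted(piv_by_scaf):
            recs = piv_by_scaf[scaf]
            for r1, r2 in zip(recs, recs[1:]):
                if r1.block_id in consumed or r2.block_id in consumed:
                    continue
                ok = True
                for g in t.genome_names:
                    _, pos = info[g]
                    s1, i1 = pos[r1.block_id]
                    s2, i2 = pos[r2.block_id]
                    if s1 != s2 or abs(i1 - i2) != 1:
                        ok = False
                        reason = f"not adjacent in {g}"
                        break
                    gp = _gap(r1, r2, g)
                    if gp >= gap:
                        ok = False
                        reason = f"gap {gp} in {g}"
                        break
                if ok and colour_rule and r1.colour != r2.colour:
                    ok = False
                    reason = f"colours {r1.colour} vs {r2.colour}"
                if ok and require_consistent_junction:
                    jp = _junction(r1, r2, pivot)
                    if any(
                        _junction(r1, r2, g) != jp
                        for g in t.genome_names
                        if g != pivot
                    ):
                        ok = False
                        reason = "inconsistent junction"
                if ok:
                    merges.append((r1, r2))
                    consumed.add(r1.block_id)
                    consumed.add(r2.block_id)
                else:
                    logger.debug(
                        "refusing merge %s+%s: %s", r1.block_id, r2.block_id, reason
                    )
        if not merges:
            return table
        merged = {id(r1): _merge_pair(r1, r2, t.genome_names, pivot) for r1, r2 in merges}
        second = {r2.block_id for _, r2 in merges}
        new_records = []
        for r in records:
            if id(r) in merged:
                new_records.append(merged[id(r)])
            elif r.block_id not in second:
                new_records.append(r)
        records = new_records


def resolve_polarity(
    genomes: Sequence[SignedBlockGenome],
    indeterminate: Sequence[tuple[str, int]],
    objective: Callable[[Sequence[SignedBlockGenome]], float] | None = None,
    max_passes: int = 20,
) -> tuple[dict[tuple[str, int], int], float, list[SignedBlockGenome]]:
    """Greedy sign search for polarity-indeterminate blocks.

    ``indeterminate`` lists (genome name, unsigned block id) pairs whose sign
    is unresolved.  Blocks are scanned in (block id, genome) order; each flip
    is kept only when it strictly improves the objective (by default the DCJ
    median total score of the three genomes); full passes repeat until one
    makes no change or ``max_passes`` is hit.  Deterministic; the objective
    is integer-valued so termination is guaranteed.
    """
    lower_bound = None
    if objective is None:
        def objective(gs):
            return dcj_median(*gs, enumerate_all=False).total_score

        def lower_bound(gs):
            from .rearrangement import dcj_distance

            d = (
                dcj_distance(gs[0], gs[1])
                + dcj_distance(gs[0], gs[2])
                + dcj_distance(gs[1], gs[2])
            )
            return -(-d // 2)

    genomes = list(genomes)
    order = sorted(indeterminate, key=lambda it: (it[1], it[0]))
    score = objective(genomes)
    if not order:
        return {}, score, genomes

    def flip(gs, gname, block):
        out = []
        for g in gs:
            if g.name != gname:
                out.append(g)
                continue
            chroms = tuple(
                tuple(-x if abs(x) == block else x for x in c) for c in g.chromosomes
            )
            out.append(SignedBlockGenome(g.name, chroms))
        return out

    for _ in range(max_passes):
        improved = False
        for gname, block in order:
            trial = flip(genomes, gname, block)
            # a cheap pairwise bound rejects clearly-worse flips without
            # paying for an exact median of a badly tangled trial triple
            if lower_bound is not None and lower_bound(trial) >= score:
                continue
            s = objective(trial)
            if s < score:
                genomes, score = trial, s
                improved = True
        if not improved:
            break
    signs = {}
    by_name = {g.name: g for g in genomes}
    for gname, block in order:
        g = by_name[gname]
        sign = next(
            1 if x == block else -1
            for c in g.chromosomes
            for x in c
            if abs(x) == block
        )
        signs[(gname, block)] = sign
    return signs, score, genomes


def sweep(
    t: BlockTable,
    schedule: ResolutionSchedule | None = None,
    pivot: str | None = None,
) -> list[LevelResult]:
    """Run the full deletion + merger cascade over every level.

    Gene conservation holds at every level:
    ``genes_not_included + genes_remaining`` equals the total gene content of
    the input table (counted on the pivot genome).
    """
    schedule = schedule or ResolutionSchedule()
    pivot = pivot or t.genome_names[0]
    total = t.total_genes(pivot)
    ids = t.block_index()
    results = []
    for level in schedule.levels:
        kept, deleted = apply_level(t, level, schedule.size_rule)
        merged = merge_neighbours(
            kept,
            deleted,
            gap=schedule.merge_gap,
            colour_rule=schedule.colour_rule,
            pivot=pivot,
            require_consistent_junction=schedule.require_consistent_junction,
        )
        remaining = merged.total_genes(pivot)
        report = LevelReport(
            level=level,
            blocks_deleted=len(deleted),
            blocks_remaining=len(kept),
            blocks_after_mergers=len(merged),
            genes_not_included=total - remaining,
            genes_remaining=remaining,
        )
        merged_ids = merged.block_index()
        if len(merged) == 0:
            results.append(LevelResult(report, merged, {}, []))
            continue
        genomes = {
            g: genome_from_table(merged, g, block_ids=merged_ids)
            for g in t.genome_names
        }
        indeterminate = [
            (g, merged_ids[r.block_id])
            for r in merged.records
            if not r.polarity_determinate
            for g in t.genome_names
            if g != pivot
        ]
        results.append(LevelResult(report, merged, genomes, indeterminate))
    return results
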