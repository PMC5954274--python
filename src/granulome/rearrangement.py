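"""Pairwise rearrangement measures: DCJ distance, breakpoint distance,
breakpoint reuse, and greedy optimal sorting scenarios.

The DCJ (double-cut-and-join) distance between two genomes on the same block
set is ``d = N - (C + I/2)``, read off the adjacency graph (``N`` blocks,
``C`` cycles, ``I`` odd paths).  The multichromosomal breakpoint distance is
``b = N - a - e/2`` where ``a`` counts shared adjacencies and ``e`` shared
telomeres; with these conventions the reuse statistic ``r = 2d/b`` spans
exactly [1, 2], reaching 2 as the two genomes approach independent random
block orders.

Sorting scenarios are produced greedily: at every step all DCJ operations
that reduce the distance by 1 *and keep every chromosome linear* are
enumerated, each is classified (reversal / translocation / fusion / fission)
by the chromosomes its two cuts touch, and one is applied - preferring the
prioritized operation type, with deterministic lowest-extremity tie-breaking.
When no such operation exists (a block interchange is forced), a circular
piece is excised and reabsorbed by the very next step; the pair is labelled
``excision``/``reintegration`` and each half still reduces the distance by
1, so both priority modes always yield scenarios of exactly optimal length
and bracket the translocation/reversal counts achievable by optimal
scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from . import _adjacency as adj
from .model import SignedBlockGenome, UndefinedValueError

__all__ = [
    "AdjacencyGraph",
    "ScenarioStep",
    "RearrangementScenario",
    "dcj_distance",
    "breakpoint_distance",
    "reuse_rate",
    "sort_scenario",
    "normalized_total",
]

logger = logging.getLogger(__name__)

PriorityMode = Literal["translocations-first", "reversals-first"]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Two-genome extremity/adjacency structure with its component counts."""

    blocks: frozenset[int]
    cycles: int
    odd_paths: int

    @classmethod
    def build(cls, a: SignedBlockGenome, b: SignedBlockGenome) -> "AdjacencyGraph":
        blocks = adj.check_same_content(a, b)
        pa, pb = adj.partner_map(a), adj.partner_map(b)
        cycles, odd = adj.component_stats(pa, pb, blocks)
        return cls(blocks=blocks, cycles=cycles, odd_paths=odd)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def distance(self) -> int:
        twice = 2 * self.n_blocks - 2 * self.cycles - self.odd_paths
        return twice // 2


def dcj_distance(a: SignedBlockGenome, b: SignedBlockGenome) -> int:
    """Minimum number of double-cut-and-join operations from ``a`` to ``b``."""
    return AdjacencyGraph.build(a, b).distance


def breakpoint_distance(a: SignedBlockGenome, b: SignedBlockGenome) -> float:
    """Multichromosomal breakpoint distance, telomeric agreement at half weight."""
    blocks = adj.check_same_content(a, b)
    common_adj = len(adj.adjacency_set(a) & adj.adjacency_set(b))
    common_tel = len(adj.telomere_set(a) & adj.telomere_set(b))
    return len(blocks) - common_adj - common_tel / 2


def reuse_rate(a: SignedBlockGenome, b: SignedBlockGenome) -> float:
    """Breakpoint reuse r = 2d/b; undefined for identical genomes (b = 0)."""
    bp = breakpoint_distance(a, b)
    if bp == 0:
        raise UndefinedValueError("breakpoint reuse undefined: genomes share all adjacencies")
    return 2 * dcj_distance(a, b) / bp


def normalized_total(score: int | float, n_blocks: int) -> float:
    """Distance (or median score) per block."""
    if n_blocks <= 0:
        raise UndefinedValueError("normalization requires a positive block count")
    return score / n_blocks


# ---------------------------------------------------------------------------
# sorting scenarios
# ---------------------------------------------------------------------------

OpType = Literal["reversal", "translocation", "fusion", "fission"]


@dataclass(frozen=True)
class ScenarioStep:
    kind: str
    cuts: tuple[tuple[int, ...], ...]  # the A-adjacencies/telomeres cut
    joins: tuple[tuple[int, ...], ...]  # the adjacencies/telomeres created


@dataclass
class RearrangementScenario:
    source: str
    target: str
    priority_mode: str
    operations: list[ScenarioStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.operations)

    def count(self, kind: str) -> int:
        return sum(1 for op in self.operations if op.kind == kind)


def _apply(pm: dict[int, int], cuts, joins) -> dict[int, int]:
    new = dict(pm)
    for pair in cuts:
        if len(pair) == 2:
            x, y = pair
            del new[x]
            del new[y]
    for pair in joins:
        if len(pair) == 2:
            x, y = pair
            new[x] = y
            new[y] = x
    return new


def _candidate_ops(pm: dict[int, int], pmb: dict[int, int], blocks) -> list:
    """All DCJ operations on ``pm`` touching unsorted material.

    Elements already agreeing with the target (common adjacencies, common
    telomeres) sit in finished components of the adjacency graph; an
    operation cutting them can never reduce the distance, so they are not
    enumerated.  Returned as (cuts, joins) pairs.
    """
    active_adj = []
    seen = set()
    for x, y in pm.items():
        if x > y:
            continue
        if pmb.get(x) == y:
            continue
        active_adj.append((x, y))
    active_tel = []
    for b in blocks:
        for e in (adj.tail(b), adj.head(b)):
            if e not in pm and e in pmb:
                active_tel.append(e)
    ops = []
    for i, (p, q) in enumerate(active_adj):
        # cut a single adjacency into two telomeres
        ops.append((((p, q),), ((p,), (q,))))
        for r, s in active_adj[i + 1:]:
            ops.append((((p, q), (r, s)), ((p, r), (q, s))))
            ops.append((((p, q), (r, s)), ((p, s), (q, r))))
        for t in active_tel:
            ops.append((((p, q), (t,)), ((p, t), (q,))))
            ops.append((((p, q), (t,)), ((q, t), (p,))))
    for i, t1 in enumerate(active_tel):
        for t2 in active_tel[i + 1:]:
            ops.append((((t1,), (t2,)), ((t1, t2),)))
    return ops


def _component_contrib(pa: dict[int, int], pb: dict[int, int], seeds) -> float:
    """Summed C + I/2 contribution of the adjacency-graph components that
    contain any of the seed extremities."""
    done: set[int] = set()
    total = 0.0
    for s in seeds:
        if s in done:
            continue
        verts = {s}
        frontier = [s]
        while frontier:
            v = frontier.pop()
            for pm in (pa, pb):
                w = pm.get(v)
                if w is not None and w not in verts:
                    verts.add(w)
                    frontier.append(w)
        done |= verts
        if all(v in pa and v in pb for v in verts):
            total += 1.0  # cycle
        else:
            total += 0.5 * (len(verts) % 2)  # odd path
    return total


def _join_closes_cycle(pm: dict[int, int], ext: int) -> bool:
    """Walk the chromosome from ``ext``; True when it comes back around."""
    cur = ext
    while True:
        other = cur ^ 1  # the other extremity of the same block
        nxt = pm.get(other)
        if nxt is None:
            return False
        if nxt == ext:
            return True
        cur = nxt


def _classify(chrom_of: dict[int, int], cuts) -> str:
    involved = {chrom_of[e // 2] for pair in cuts for e in pair}
    if len(cuts) == 1:
        return "fission"  # one adjacency cut into two telomeres
    if all(len(pair) == 1 for pair in cuts):
        return "fusion"  # two telomeres joined
    return "reversal" if len(involved) == 1 else "translocation"


def sort_scenario(
    a: SignedBlockGenome,
    b: SignedBlockGenome,
    priority_mode: PriorityMode = "translocations-first",
) -> RearrangementScenario:
    """Greedy optimal DCJ sorting of ``a`` into ``b`` with typed operations.

    Every applied operation reduces the DCJ distance by exactly 1 and never
    creates a circular chromosome, so the scenario length always equals
    ``dcj_distance(a, b)``.
    """
    if priority_mode not in ("translocations-first", "reversals-first"):
        raise ValueError(f"unknown priority mode {priority_mode!r}")
    preferred = (
        "translocation" if priority_mode == "translocations-first" else "reversal"
    )
    blocks = sorted(adj.check_same_content(a, b))
    pm = adj.partner_map(a)
    pmb = adj.partner_map(b)
    scenario = RearrangementScenario(a.name, b.name, priority_mode)
    d = adj.dcj_distance_matchings(pm, pmb, blocks)
    while d > 0:
        chroms, circ = adj.chromosomes_from_matching(pm, blocks)
        assert not circ
        chrom_of = {abs(x): i for i, c in enumerate(chroms) for x in c}
        best: dict[str, tuple] = {}
        for cuts, joins in _candidate_ops(pm, pmb, blocks):
            seeds = [e for pair in cuts for e in pair]
            before = _component_contrib(pm, pmb, seeds)
            new_pm = _apply(pm, cuts, joins)
            if _component_contrib(new_pm, pmb, seeds) - before != 1.0:
                continue
            if any(
                len(pair) == 2 and _join_closes_cycle(new_pm, pair[0])
                for pair in joins
            ):
                continue
            kind = _classify(chrom_of, cuts)
            key = tuple(sorted(seeds))
            if kind not in best or key < best[kind][0]:
                best[kind] = (key, cuts, joins, new_pm)
        if not best:
            # block-interchange situation: no single linear-safe operation
            # reduces the distance, but excising a circular piece and
            # immediately reintegrating it does (two steps, each reducing
            # the distance by 1, the circular state purely transient)
            pm, steps = _excision_pair(pm, pmb, blocks, d)
            scenario.operations.extend(steps)
            d -= 2
            continue
        if preferred in best:
            kind = preferred
        else:
            kind = min(best, key=lambda k: best[k][0])
        _, cuts, joins, new_pm = best[kind]
        scenario.operations.append(
            ScenarioStep(kind=kind, cuts=tuple(cuts), joins=tuple(joins))
        )
        pm = new_pm
        d -= 1
    return scenario


def _excision_pair(pm, pmb, blocks, d):
    """Excise a circular intermediate and reabsorb it, both steps optimal.

    Needed when (and only when) a block interchange is the only way to keep
    making progress: sorting multichromosomal linear genomes by DCJ attains
    the plain DCJ distance as long as a circular excision may be undone by
    the immediately following operation.
    """
    cands = []
    for cuts, joins in _candidate_ops(pm, pmb, blocks):
        seeds = [e for pair in cuts for e in pair]
        before = _component_contrib(pm, pmb, seeds)
        mid_pm = _apply(pm, cuts, joins)
        if _component_contrib(mid_pm, pmb, seeds) - before != 1.0:
            continue
        cands.append((tuple(sorted(seeds)), cuts, joins, mid_pm))
    for _, cuts1, joins1, mid_pm in sorted(cands, key=lambda c: c[0]):
        for cuts2, joins2 in _candidate_ops(mid_pm, pmb, blocks):
            seeds = [e for pair in cuts2 for e in pair]
            before = _component_contrib(mid_pm, pmb, seeds)
            new_pm = _apply(mid_pm, cuts2, joins2)
            if _component_contrib(new_pm, pmb, seeds) - before != 1.0:
                continue
            _, circ = adj.chromosomes_from_matching(new_pm, blocks)
            if circ:
                continue
            steps = [
                ScenarioStep(kind="excision", cuts=tuple(cuts1), joins=tuple(joins1)),
                ScenarioStep(kind="reintegration", cuts=tuple(cuts2), joins=tuple(joins2)),
            ]
            logger.debug("block interchange: excision/reintegration pair applied")
            return new_pm, steps
    raise RuntimeError("no optimal excision/reintegration pair found")  # pragma: no cover
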