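"""Extremity/adjacency machinery shared by the distance and median code.

Each block ``b`` has a tail extremity ``2b`` and a head extremity ``2b+1``.
A genome is equivalently a *matching* on its extremities: each interior
adjacency pairs the right extremity of one signed block with the left
extremity of the next; extremities left unmatched are telomeres.  All
distance computations reduce to component counts on the union of two such
matchings.
"""

from __future__ import annotations

from typing import Iterable

from .model import ContentMismatchError, SignedBlockGenome

__all__ = [
    "tail",
    "head",
    "left_ext",
    "right_ext",
    "partner_map",
    "adjacency_set",
    "telomere_set",
    "check_same_content",
    "component_stats",
    "dcj_distance_matchings",
    "chromosomes_from_matching",
]


def tail(b: int) -> int:
    return 2 * b


def head(b: int) -> int:
    return 2 * b + 1


def left_ext(x: int) -> int:
    """Extremity entered first when reading signed block ``x`` left to right."""
    return tail(x) if x > 0 else head(-x)


def right_ext(x: int) -> int:
    return head(x) if x > 0 else tail(-x)


def partner_map(g: SignedBlockGenome) -> dict[int, int]:
    """Adjacency matching of a genome: extremity -> adjacent extremity."""
    pm: dict[int, int] = {}
    for chrom in g.chromosomes:
        prev = None
        for x in chrom:
            l, r = left_ext(x), right_ext(x)
            if prev is not None:
                pm[prev] = l
                pm[l] = prev
            prev = r
    return pm


def adjacency_set(g: SignedBlockGenome) -> frozenset[frozenset[int]]:
    pm = partner_map(g)
    return frozenset(frozenset((a, b)) for a, b in pm.items() if a < b)


def telomere_set(g: SignedBlockGenome) -> frozenset[int]:
    pm = partner_map(g)
    exts = []
    for b in g.blocks():
        exts += [tail(b), head(b)]
    return frozenset(e for e in exts if e not in pm)


def check_same_content(a: SignedBlockGenome, b: SignedBlockGenome) -> frozenset[int]:
    ba, bb = a.blocks(), b.blocks()
    if ba != bb:
        raise ContentMismatchError(ba - bb, bb - ba)
    return ba


def component_stats(
    pa: dict[int, int], pb: dict[int, int], blocks: Iterable[int]
) -> tuple[int, int]:
    """Cycles and odd paths of the adjacency graph of two matchings.

    The graph has one vertex per extremity and an edge for every adjacency of
    either matching, so every component is a path or an alternating cycle.  A
    path is *odd* when it has an odd number of vertices (equivalently, an odd
    number of edges in the classical adjacency-graph drawing where extremities
    are the edges).
    """
    verts: list[int] = []
    for b in blocks:
        verts.append(tail(b))
        verts.append(head(b))
    visited: set[int] = set()
    cycles = 0
    odd_paths = 0
    # paths: start from vertices missing at least one of the two edges
    for v in verts:
        if v in visited:
            continue
        in_a, in_b = v in pa, v in pb
        if in_a and in_b:
            continue
        visited.add(v)
        count = 1
        if not in_a and not in_b:
            odd_paths += count % 2
            continue
        use_a = in_a
        cur = v
        while True:
            pm = pa if use_a else pb
            if cur not in pm:
                break
            cur = pm[cur]
            if cur in visited:  # pragma: no cover - defensive
                break
            visited.add(cur)
            count += 1
            use_a = not use_a
        odd_paths += count % 2
    # remaining components are cycles
    for v in verts:
        if v in visited:
            continue
        cycles += 1
        cur, use_a = v, True
        while True:
            visited.add(cur)
            cur = (pa if use_a else pb)[cur]
            use_a = not use_a
            if cur == v and use_a:
                break
            if cur in visited and cur != v:
                break
    return cycles, odd_paths


def dcj_distance_matchings(
    pa: dict[int, int], pb: dict[int, int], blocks: Iterable[int]
) -> int:
    """d = N - (C + I/2) on the adjacency graph of the two matchings."""
    blocks = list(blocks)
    cycles, odd = component_stats(pa, pb, blocks)
    twice = 2 * len(blocks) - 2 * cycles - odd
    assert twice % 2 == 0, "DCJ distance must be integral"
    return twice // 2


def chromosomes_from_matching(
    pm: dict[int, int], blocks: Iterable[int]
) -> tuple[tuple[tuple[int, ...], ...], tuple[tuple[int, ...], ...]]:
    """Assemble a matching back into (linear chromosomes, circular chromosomes).

    Circular chromosomes are returned separately so callers can reject or
    break them; they arise only from matchings not produced by
    :func:`partner_map` on a valid genome.
    """
    blocks = sorted(set(blocks))
    visited: set[int] = set()
    linear: list[tuple[int, ...]] = []
    circular: list[tuple[int, ...]] = []

    def walk(start_ext: int) -> tuple[int, ...]:
        chain: list[int] = []
        e = start_ext
        while True:
            b = e // 2
            visited.add(b)
            if e == tail(b):
                chain.append(b)
                out = head(b)
            else:
                chain.append(-b)
                out = tail(b)
            nxt = pm.get(out)
            if nxt is None or (nxt // 2) in visited:
                return tuple(chain)
            e = nxt

    for b in blocks:
        for e in (tail(b), head(b)):
            if b not in visited and e not in pm:
                linear.append(walk(e))
                break
    for b in blocks:
        if b not in visited:
            circular.append(walk(tail(b)))
    return tuple(linear), tuple(circular)
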