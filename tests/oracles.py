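"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive and self-contained: genomes are
matchings on block extremities (tail(b) = 2b, head(b) = 2b+1), DCJ distance
is breadth-first search over all single operations, medians and matchings
are exhaustive enumerations.  Nothing imports the package's distance or
median algorithms, only its genome container.
"""

from __future__ import annotations

import itertools
from collections import deque

from granulome import SignedBlockGenome


def tail(b: int) -> int:
    return 2 * b


def head(b: int) -> int:
    return 2 * b + 1


def edge(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def matching_of(g: SignedBlockGenome) -> frozenset[tuple[int, int]]:
    edges = set()
    for chrom in g.chromosomes:
        prev = None
        for x in chrom:
            b = abs(x)
            left, right = (tail(b), head(b)) if x > 0 else (head(b), tail(b))
            if prev is not None:
                edges.add(edge(prev, left))
            prev = right
    return frozenset(edges)


def extremities(blocks) -> list[int]:
    out = []
    for b in blocks:
        out += [tail(b), head(b)]
    return out


def dcj_neighbors(state: frozenset, blocks) -> set[frozenset]:
    """All matchings reachable by one double-cut-and-join operation."""
    adjacencies = sorted(state)
    matched = {e for pair in adjacencies for e in pair}
    telomeres = [e for e in extremities(blocks) if e not in matched]
    out: set[frozenset] = set()
    for i, (p, q) in enumerate(adjacencies):
        base = state - {(p, q)}
        out.add(base)  # cut into two telomeres
        for r, s in adjacencies[i + 1:]:
            base2 = base - {(r, s)}
            out.add(base2 | {edge(p, r), edge(q, s)})
            out.add(base2 | {edge(p, s), edge(q, r)})
        for t in telomeres:
            out.add(base | {edge(p, t)})
            out.add(base | {edge(q, t)})
    for t1, t2 in itertools.combinations(telomeres, 2):
        out.add(state | {edge(t1, t2)})
    out.discard(state)
    return out


def bfs_distances(start: frozenset, blocks) -> dict[frozenset, int]:
    """BFS over the whole matching space from ``start``."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        d = dist[s]
        for t in dcj_neighbors(s, blocks):
            if t not in dist:
                dist[t] = d + 1
                queue.append(t)
    return dist


def bfs_dcj_distance(a: SignedBlockGenome, b: SignedBlockGenome) -> int:
    blocks = sorted({abs(x) for c in a.chromosomes for x in c})
    target = matching_of(b)
    start = matching_of(a)
    if start == target:
        return 0
    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        for t in dcj_neighbors(s, blocks):
            if t == target:
                return dist[s] + 1
            if t not in dist:
                dist[t] = dist[s] + 1
                queue.append(t)
    raise AssertionError("unreachable target")


def _canon(chroms) -> tuple:
    out = []
    for c in chroms:
        rev = tuple(-x for x in reversed(c))
        out.append(min(tuple(c), rev))
    return tuple(sorted(out))


def all_linear_genomes(n: int, name: str = "g") -> list[SignedBlockGenome]:
    """Every genome on blocks 1..n (all orders, signs, chromosome splits)."""
    seen = set()
    out = []
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            seq = [p * s for p, s in zip(perm, signs)]
            for cuts in itertools.product((0, 1), repeat=n - 1):
                chroms = []
                cur = [seq[0]]
                for x, c in zip(seq[1:], cuts):
                    if c:
                        chroms.append(tuple(cur))
                        cur = [x]
                    else:
                        cur.append(x)
                chroms.append(tuple(cur))
                key = _canon(chroms)
                if key not in seen:
                    seen.add(key)
                    out.append(SignedBlockGenome(name, key))
    return out


def chromosome_size_profiles(n: int):
    """One canonical genome per chromosome-size partition of n.

    DCJ distance is invariant under simultaneous relabelling/sign flips of
    both genomes, and any genome can be relabelled to consecutive positive
    blocks per chromosome, so these representatives cover all genome pairs
    up to symmetry.
    """
    def partitions(n, largest):
        if n == 0:
            yield ()
            return
        for k in range(min(n, largest), 0, -1):
            for rest in partitions(n - k, k):
                yield (k,) + rest

    reps = []
    for part in partitions(n, n):
        chroms = []
        nxt = 1
        for size in part:
            chroms.append(tuple(range(nxt, nxt + size)))
            nxt += size
        reps.append(SignedBlockGenome("rep", tuple(chroms)))
    return reps


# ---------------------------------------------------------------------------
# matchings / medians
# ---------------------------------------------------------------------------


def max_weight_matching_brute(nodes, weighted_edges) -> float:
    """Exhaustive maximum-weight matching over an explicit edge list."""
    edges = list(weighted_edges)

    def rec(i, used, total):
        if i == len(edges):
            return total
        a, b, w = edges[i]
        best = rec(i + 1, used, total)
        if a not in used and b not in used:
            best = max(best, rec(i + 1, used | {a, b}, total + w))
        return best

    return rec(0, frozenset(), 0.0)


def chromosomes_of_matching(state: frozenset, blocks):
    """(linear chromosomes, circular chromosomes) of a matching - naive walk."""
    pm = {}
    for a, b in state:
        pm[a] = b
        pm[b] = a
    visited = set()
    linear, circular = [], []

    def walk(e):
        chain = []
        while True:
            b = e // 2
            visited.add(b)
            chain.append(b if e == tail(b) else -b)
            out = e ^ 1
            nxt = pm.get(out)
            if nxt is None or (nxt // 2) in visited:
                return chain
            e = nxt

    for b in sorted(blocks):
        if b in visited:
            continue
        if tail(b) not in pm:
            linear.append(walk(tail(b)))
        elif head(b) not in pm:
            linear.append(walk(head(b)))
    for b in sorted(blocks):
        if b not in visited:
            circular.append(walk(tail(b)))
    return linear, circular


def optimal_scenario_bounds(a: SignedBlockGenome, b: SignedBlockGenome):
    """Min/max per-operation-type counts over ALL optimal linear scenarios.

    Enumerates every shortest path of linear-safe distance-reducing DCJ
    operations from ``a`` to ``b``, classifying each step independently of
    the package (reversal / translocation / fusion / fission by the
    chromosomes touched and the chromosome-count change).
    """
    blocks = sorted({abs(x) for c in a.chromosomes for x in c})
    target = matching_of(b)
    dist = bfs_distances(target, blocks)

    def classify(state, nxt):
        lin, circ = chromosomes_of_matching(state, blocks)
        assert not circ
        chrom_of = {abs(x): i for i, c in enumerate(lin) for x in c}
        cut = state - nxt
        added = nxt - state
        # every touched extremity counts: cut adjacencies and new joins
        # (a telomere pulled into a join has no cut edge of its own)
        involved = {chrom_of[e // 2] for pair in (cut | added) for e in pair}
        lin2, _ = chromosomes_of_matching(nxt, blocks)
        if not cut:
            return "fusion"
        if len(lin2) > len(lin):
            return "fission"
        if len(lin2) < len(lin):
            return "fusion"
        return "reversal" if len(involved) == 1 else "translocation"

    kinds = ("reversal", "translocation", "fusion", "fission")
    memo: dict[frozenset, dict[str, tuple[int, int]]] = {}

    def rec(state):
        if state == target:
            return {k: (0, 0) for k in kinds}
        if state in memo:
            return memo[state]
        d = dist[state]
        best = {k: [10**9, -(10**9)] for k in kinds}
        for nxt in dcj_neighbors(state, blocks):
            if dist.get(nxt) != d - 1:
                continue
            _, circ = chromosomes_of_matching(nxt, blocks)
            if circ:
                # block interchange: allow the circular state only as a
                # transient, resolved by the immediately following step
                for nxt2 in dcj_neighbors(nxt, blocks):
                    if dist.get(nxt2) != d - 2:
                        continue
                    _, circ2 = chromosomes_of_matching(nxt2, blocks)
                    if circ2:
                        continue
                    sub = rec(nxt2)
                    for k in kinds:
                        lo, hi = sub[k]
                        best[k][0] = min(best[k][0], lo)
                        best[k][1] = max(best[k][1], hi)
                continue
            kind = classify(state, nxt)
            sub = rec(nxt)
            for k in kinds:
                lo, hi = sub[k]
                inc = 1 if k == kind else 0
                best[k][0] = min(best[k][0], lo + inc)
                best[k][1] = max(best[k][1], hi + inc)
        result = {k: (lo, hi) for k, (lo, hi) in best.items()}
        memo[state] = result
        return result

    return rec(matching_of(a))
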