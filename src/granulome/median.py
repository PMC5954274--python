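"""Exact DCJ median of three genomes, with enumeration of co-optimal
medians, and the breakpoint median by maximum-weight matching.

The DCJ median minimises ``d(M,A) + d(M,B) + d(M,C)``.  Writing the three
input genomes as matchings on block extremities, the score of a candidate
median matching ``M`` is ``3N - sum_k (C_k + I_k/2)``, so the problem is to
maximise the total number of (weighted) adjacency-graph components formed
against the three inputs.  The solver

1. splits the extremity set into connected components of the union of the
   three input matchings (cycles never span components, so components can be
   optimised independently),
2. enumerates, per component, all matchings within a small score slack of
   the component optimum by depth-first search with an admissible bound on
   the achievable component score, and
3. assembles per-component choices in order of total score (best first),
   keeping assemblies whose induced genome is linear; all linear assemblies
   at the best achievable score are reported, deduplicated after
   canonicalisation.

The search space is restricted to medians whose adjacencies stay inside
union components; joining unrelated components can never close an extra
cycle, so the component-respecting optimum is the global optimum, and the
enumerated set is the set of distinct such medians (up to ``cap``).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import networkx as nx

from . import _adjacency as adj
from .model import SignedBlockGenome
from .rearrangement import dcj_distance

__all__ = ["MedianResult", "dcj_median", "breakpoint_median", "median_distance_profile"]

logger = logging.getLogger(__name__)


@dataclass
class MedianResult:
    """All enumerated co-optimal medians with their common total score."""

    medians: tuple[SignedBlockGenome, ...]
    total_score: int
    distances: tuple[int, int, int]  # representative median to A, B, C
    truncated: bool = False
    level: int | None = None

    @property
    def representative(self) -> SignedBlockGenome:
        return self.medians[0]

    @property
    def n_medians(self) -> int:
        return len(self.medians)


def _union_components(pms, blocks):
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for b in blocks:
        parent[adj.tail(b)] = adj.tail(b)
        parent[adj.head(b)] = adj.head(b)
    for pm in pms:
        for x, y in pm.items():
            union(x, y)
    comps: dict[int, list[int]] = {}
    for b in blocks:
        for e in (adj.tail(b), adj.head(b)):
            comps.setdefault(find(e), []).append(e)
    return [sorted(v) for v in sorted(comps.values())]


class _ComponentSolver:
    """Enumerate matchings of one union component by score.

    Chains of the partial alternating structure (median edges + one genome's
    edges) are tracked per genome through endpoint maps, so cycles are
    counted the moment they close and path parities are read off at the
    leaves.  The DFS bound assumes every future median edge closes one cycle
    per genome and every open chain ends as an odd path, which dominates any
    completion.
    """

    def __init__(self, verts: list[int], pms) -> None:
        self.verts = verts
        self.k = len(pms)
        self.chain_end: list[dict[int, int]] = []
        self.chain_len: list[dict[int, int]] = []
        self.chains: list[int] = []
        for pm in pms:
            end: dict[int, int] = {}
            length: dict[int, int] = {}
            for v in verts:
                end[v] = v
                length[v] = 1
            n_chains = len(verts)
            for v in verts:
                w = pm.get(v)
                if w is not None and v < w:
                    end[v] = w
                    end[w] = v
                    length[v] = length[w] = 2
                    n_chains -= 1
            self.chain_end.append(end)
            self.chain_len.append(length)
            self.chains.append(n_chains)
        self.closed = [0.0] * self.k
        self.best = float("-inf")
        self.solutions: list[tuple[float, frozenset]] = []
        # static pairwise relaxation: for any median matching M,
        # contrib_i(M) + contrib_j(M) <= v/2 + contrib(G_i, G_j)
        # (triangle inequality of the component matching metric)
        self.pair_bound = {}
        for i in range(self.k):
            for j in range(i + 1, self.k):
                self.pair_bound[(i, j)] = len(verts) / 2 + self._mutual_contrib(
                    pms[i], pms[j]
                )

    def _mutual_contrib(self, pa, pb) -> float:
        """Cycles + odd-paths/2 of two genome matchings on this component."""
        visited: set[int] = set()
        total = 0.0
        for s in self.verts:
            if s in visited:
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
            visited |= verts
            if all(v in pa and v in pb for v in verts):
                total += 1.0
            else:
                total += 0.5 * (len(verts) % 2)
        return total

    # -- chain bookkeeping ---------------------------------------------------

    def _add_edge(self, u: int, v: int):
        """Attach median edge (u, v); returns an undo record.

        In every genome's partial alternating structure, u and v are chain
        endpoints (their median edge was unassigned until now).  If they end
        the same chain, the edge closes an alternating cycle; otherwise the
        two chains merge, the far endpoints surviving as the new endpoints.
        """
        undo = []
        for k in range(self.k):
            end, length = self.chain_end[k], self.chain_len[k]
            eu, ev = end[u], end[v]
            if eu == v:  # closes an alternating cycle in genome k
                undo.append((k, "cyc", u, v, length[u]))
                self.closed[k] += 1.0
                self.chains[k] -= 1
                del end[u], end[v], length[u], length[v]
            else:
                lu, lv = length[u], length[v]
                undo.append((k, "mrg", u, v, eu, ev, lu, lv))
                self.chains[k] -= 1
                if eu != u:
                    del end[u], length[u]
                if ev != v:
                    del end[v], length[v]
                end[eu], end[ev] = ev, eu
                length[eu] = length[ev] = lu + lv
        return undo

    def _undo_edge(self, undo) -> None:
        for rec in reversed(undo):
            k = rec[0]
            end, length = self.chain_end[k], self.chain_len[k]
            if rec[1] == "cyc":
                _, _, u, v, lu = rec
                self.closed[k] -= 1.0
                self.chains[k] += 1
                end[u], end[v] = v, u
                length[u] = length[v] = lu
            else:
                _, _, u, v, eu, ev, lu, lv = rec
                self.chains[k] += 1
                end[u], end[eu] = eu, u
                length[u] = length[eu] = lu
                end[v], end[ev] = ev, v
                length[v] = length[ev] = lv

    def _path_bonus(self) -> float:
        total = 0.0
        for k in range(self.k):
            end = self.chain_end[k]
            length = self.chain_len[k]
            for v, e in end.items():
                if v <= e:
                    total += (length[v] % 2) * 0.5
        return total

    def _open_chains(self) -> int:
        n = 0
        for k in range(self.k):
            for v, e in self.chain_end[k].items():
                if v <= e:
                    n += 1
        return n

    # -- search --------------------------------------------------------------

    def _score_matching(self, edges) -> float:
        undos = [self._add_edge(u, v) for u, v in edges]
        score = sum(self.closed) + self._path_bonus()
        for undo in reversed(undos):
            self._undo_edge(undo)
        return score

    def _seed_incumbents(self) -> None:
        """Prime the search with each genome's own matching (a valid median
        candidate), so the bound prunes from the first branch."""
        vset = set(self.verts)
        for k in range(self.k):
            edges = sorted(
                (v, w)
                for v, w in self.chain_end[k].items()
                if v < w and self.chain_len[k][v] == 2 and w in vset
            )
            score = self._score_matching(edges)
            if score > self.best:
                self.best = score
                if self.first_only:
                    self.solutions = [(score, frozenset(edges))]

    def solve(
        self,
        slack: float,
        cap: int = 200_000,
        first_only: bool = False,
        known_best: float | None = None,
        node_budget: int | None = None,
    ):
        self.slack = slack
        self.cap = cap
        self.first_only = first_only
        self.truncated = False
        self.nodes = 0
        self.node_budget = node_budget
        if known_best is not None:
            self.best = known_best
        self._seed_incumbents()
        self._dfs([v for v in self.verts], [])
        cutoff = self.best - self.slack
        return (
            self.best,
            [(s, m) for s, m in self.solutions if s >= cutoff - 1e-9],
            self.truncated,
        )

    def _dfs(self, remaining: list[int], edges: list[tuple[int, int]]) -> None:
        if self.node_budget is not None:
            self.nodes += 1
            if self.nodes > self.node_budget:
                self.truncated = True
                return
        if not remaining:
            score = sum(self.closed) + self._path_bonus()
            if score > self.best:
                self.best = score
                if self.first_only:
                    self.solutions = [(score, frozenset(edges))]
                    return
            if self.first_only:
                return
            if score >= self.best - self.slack - 1e-9:
                if len(self.solutions) < self.cap:
                    self.solutions.append((score, frozenset(edges)))
                else:
                    self.truncated = True
            return
        # per genome, future cycle closures are limited both by the number
        # of median edges still placeable and by the number of live chains
        # (surviving chains add at most 1/2 each as odd paths); on top of
        # that, each genome pair is jointly capped by the static pairwise
        # relaxation
        half_edges = len(remaining) // 2
        dyn = [
            self.closed[k] + 0.5 * self.chains[k] + 0.5 * min(half_edges, self.chains[k])
            for k in range(self.k)
        ]
        if self.k == 3:
            bound = 0.5 * (
                min(dyn[0] + dyn[1], self.pair_bound[(0, 1)])
                + min(dyn[0] + dyn[2], self.pair_bound[(0, 2)])
                + min(dyn[1] + dyn[2], self.pair_bound[(1, 2)])
            )
        else:
            bound = sum(dyn)
        if self.first_only:
            if bound <= self.best + 1e-9:
                return
        elif bound < self.best - self.slack - 1e-9:
            return
        v = remaining[0]
        rest = remaining[1:]
        # try cycle-closing partners first: finds strong completions early,
        # which makes the bound bite sooner
        def gain(u):
            return sum(1 for k in range(self.k) if self.chain_end[k].get(v) == u)

        order = sorted(range(len(rest)), key=lambda i: (-gain(rest[i]), rest[i]))
        for i in order:
            u = rest[i]
            undo = self._add_edge(v, u)
            edges.append((v, u))
            self._dfs(rest[:i] + rest[i + 1:], edges)
            edges.pop()
            self._undo_edge(undo)
        # leave v as a median telomere
        self._dfs(rest, edges)


_component_cache: dict = {}
_COMPONENT_CACHE_MAX = 50_000


def _solve_component(verts, pms, slack, cap, first_only=False):
    restricted = []
    vset = set(verts)
    for pm in pms:
        restricted.append({x: y for x, y in pm.items() if x in vset})
    key = (
        tuple(verts),
        tuple(tuple(sorted(pm.items())) for pm in restricted),
        round(slack, 6),
        first_only,
    )
    hit = _component_cache.get(key)
    if hit is not None:
        return hit
    # process vertices in union-graph traversal order: each new vertex is a
    # neighbour of the processed region, so chains merge and close early and
    # the bound tightens quickly
    order: list[int] = []
    seen: set[int] = set()
    for s in verts:
        if s in seen:
            continue
        stack = [s]
        seen.add(s)
        while stack:
            v = stack.pop()
            order.append(v)
            for pm in restricted:
                w = pm.get(v)
                if w is not None and w not in seen:
                    seen.add(w)
                    stack.append(w)
    solver = _ComponentSolver(order, restricted)
    if first_only:
        best, sols, truncated = solver.solve(slack, cap, first_only=True)
    else:
        # establish the exact optimum with the aggressively pruned search,
        # then enumerate co-optimal matchings under a node budget; if the
        # budget trips, the optimum stays exact and the set is flagged
        probe = _ComponentSolver(list(order), restricted)
        exact_best, seed_sols, _ = probe.solve(slack, cap, first_only=True)
        best, sols, truncated = solver.solve(
            slack, cap, known_best=exact_best, node_budget=500_000
        )
        found = {m for _, m in sols}
        for s, m in seed_sols:
            if m not in found:
                sols.append((s, m))
    # group matchings by deficit from the component optimum
    options: dict[float, list[frozenset]] = {}
    for s, m in sols:
        options.setdefault(round(best - s, 6), []).append(m)
    ranked = sorted(options.items())
    result = (best, [(d, sorted(ms, key=sorted)) for d, ms in ranked], truncated)
    if len(_component_cache) < _COMPONENT_CACHE_MAX:
        _component_cache[key] = result
    return result


def _assemblies_by_deficit(per_comp_options):
    """Yield (total_deficit, matching-choice tuple) in nondecreasing deficit.

    Components with a single zero-deficit option are fixed outside the heap;
    the heap runs over the (few) components with real alternatives.
    """
    flat = []
    for opts in per_comp_options:
        choices = [(d, m) for d, ms in opts for m in ms]
        flat.append(choices)
    heap = [(0.0, tuple(0 for _ in flat))]
    seen = {tuple(0 for _ in flat)}
    while heap:
        deficit, idx = heapq.heappop(heap)
        yield deficit, tuple(flat[i][j][1] for i, j in enumerate(idx))
        for i in range(len(flat)):
            if idx[i] + 1 < len(flat[i]):
                nxt = idx[:i] + (idx[i] + 1,) + idx[i + 1:]
                if nxt not in seen:
                    seen.add(nxt)
                    d2 = deficit - flat[i][idx[i]][0] + flat[i][idx[i] + 1][0]
                    heapq.heappush(heap, (d2, nxt))


def dcj_median(
    a: SignedBlockGenome,
    b: SignedBlockGenome,
    c: SignedBlockGenome,
    enumerate_all: bool = True,
    cap: int = 50_000,
    slack: float = 0.0,
    name: str = "median",
) -> MedianResult:
    """Exact DCJ median of three genomes on the same block set.

    With ``enumerate_all`` every distinct optimal median (canonical form) is
    returned, up to ``cap`` (the result is flagged truncated beyond it).
    ``slack`` controls how far below each component's optimum the per-
    component enumeration keeps alternatives; it is enlarged automatically in
    the (rare) event that every best-scoring assembly is circular.
    """
    blocks = sorted(adj.check_same_content(a, b) | adj.check_same_content(b, c))
    pms = [adj.partner_map(g) for g in (a, b, c)]
    n = len(blocks)
    comps = _union_components(pms, blocks)

    while True:
        per_comp = []
        best_total = 0.0
        any_truncated = False
        for verts in comps:
            best, options, truncated = _solve_component(
                verts, pms, slack, cap,
                first_only=not enumerate_all and slack == 0.0,
            )
            best_total += best
            any_truncated |= truncated
            per_comp.append(options)

        medians: list[SignedBlockGenome] = []
        seen: set = set()
        best_deficit: float | None = None
        truncated_out = any_truncated
        for deficit, choice in _assemblies_by_deficit(per_comp):
            if best_deficit is not None and deficit > best_deficit + 1e-9:
                break
            pm: dict[int, int] = {}
            for m in choice:
                for u, v in m:
                    pm[u] = v
                    pm[v] = u
            linear, circular = adj.chromosomes_from_matching(pm, blocks)
            if circular:
                continue
            if best_deficit is None:
                best_deficit = deficit
            g = SignedBlockGenome(name, linear).canonical()
            if g.chromosomes not in seen:
                seen.add(g.chromosomes)
                medians.append(g)
            if not enumerate_all:
                break
            if len(medians) >= cap:
                truncated_out = True
                break
        if best_deficit is None or best_deficit > slack + 1e-9:
            # every assembly within the slack was circular (or only a
            # deeper-than-slack linear assembly exists, whose optimality the
            # current window cannot certify); widen and retry
            slack += 2.0
            if slack > 8.0:
                raise RuntimeError("DCJ median search failed to find a linear median")
            logger.warning("no certified linear median in window; widening slack to %s", slack)
            continue
        total_score = round(3 * n - (best_total - best_deficit))
        rep = medians[0]
        dists = (dcj_distance(rep, a), dcj_distance(rep, b), dcj_distance(rep, c))
        assert sum(dists) == total_score
        lower = -(-(dcj_distance(a, b) + dcj_distance(a, c) + dcj_distance(b, c)) // 2)
        assert total_score >= lower, "median score below the pairwise lower bound"
        return MedianResult(
            medians=tuple(medians),
            total_score=total_score,
            distances=dists,
            truncated=truncated_out,
        )


# ---------------------------------------------------------------------------
# breakpoint median
# ---------------------------------------------------------------------------


def _breakpoint_matching(a, b, c):
    """Max-weight matching on extremities; returns (partner map, weight).

    Weight counts, per input genome, each realised adjacency at 1 and each
    realised telomere at 1/2 (cap vertices make telomere bonuses ordinary
    matching edges; internally doubled to keep the matching integral).
    """
    blocks = sorted(adj.check_same_content(a, b) | adj.check_same_content(b, c))
    graph = nx.Graph()
    weights: dict[frozenset, int] = {}
    tel_weight: dict[int, int] = {}
    for g in (a, b, c):
        for e in adj.adjacency_set(g):
            weights[e] = weights.get(e, 0) + 2
        for t in adj.telomere_set(g):
            tel_weight[t] = tel_weight.get(t, 0) + 1
    for e, w in weights.items():
        x, y = sorted(e)
        graph.add_edge(x, y, weight=w)
    for t, w in tel_weight.items():
        graph.add_edge(t, ("cap", t), weight=w)
    matching = nx.max_weight_matching(graph, maxcardinality=False)
    pm: dict[int, int] = {}
    total = 0
    for x, y in matching:
        total += graph[x][y]["weight"]
        if isinstance(x, tuple) or isinstance(y, tuple):
            continue
        pm[x] = y
        pm[y] = x
    return blocks, pm, weights, total / 2


def breakpoint_matching_weight(a, b, c) -> float:
    """Total agreement weight achieved by the breakpoint-median matching."""
    return _breakpoint_matching(a, b, c)[3]


def breakpoint_median(
    a: SignedBlockGenome,
    b: SignedBlockGenome,
    c: SignedBlockGenome,
    name: str = "median",
) -> SignedBlockGenome:
    """Breakpoint median via maximum-weight matching on block extremities.

    Candidate adjacencies are weighted by the number of input genomes
    containing them (telomeres at half weight, realised as edges to private
    cap vertices); a maximum-weight matching then minimises the summed
    breakpoint distance to the three inputs.  Should the matching force a
    circular chromosome, the cycle is broken at its lightest adjacency.
    """
    blocks, pm, weights, _ = _breakpoint_matching(a, b, c)
    linear, circular = adj.chromosomes_from_matching(pm, blocks)
    while circular:
        cyc = circular[0]
        ring = list(cyc)
        cands = []
        for i, x in enumerate(ring):
            nxt = ring[(i + 1) % len(ring)]
            e = frozenset((adj.right_ext(x), adj.left_ext(nxt)))
            cands.append((weights.get(e, 0), tuple(sorted(e))))
        w, e = min(cands)
        logger.warning("breakpoint median: breaking forced cycle at weight-%d adjacency %s", w // 2 if w else 0, e)
        x, y = e
        del pm[x]
        del pm[y]
        linear, circular = adj.chromosomes_from_matching(pm, blocks)
    return SignedBlockGenome(name, linear).canonical(name)


def matching_weight(
    a: SignedBlockGenome, b: SignedBlockGenome, c: SignedBlockGenome,
    median: SignedBlockGenome,
) -> float:
    """Total adjacency/telomere agreement weight of a median genome.

    Counts, over the three inputs, shared adjacencies at weight 1 and shared
    telomeres at weight 1/2 - the quantity the breakpoint median maximises.
    """
    w = 0.0
    madj = adj.adjacency_set(median)
    mtel = adj.telomere_set(median)
    for g in (a, b, c):
        w += len(madj & adj.adjacency_set(g))
        w += 0.5 * len(mtel & adj.telomere_set(g))
    return w


def median_distance_profile(
    result: MedianResult,
    a: SignedBlockGenome,
    b: SignedBlockGenome,
    c: SignedBlockGenome,
):
    """Per-median DCJ distance triples and their per-genome means."""
    import numpy as np

    triples = [
        (dcj_distance(m, a), dcj_distance(m, b), dcj_distance(m, c))
        for m in result.medians
    ]
    arr = np.asarray(triples, dtype=float)
    return triples, tuple(arr.mean(axis=0))
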